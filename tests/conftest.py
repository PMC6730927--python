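import json
from pathlib import Path

import numpy as np
import pytest

from asmob.pipeline import PipelineConfig, run_pipeline
from asmob.scoring import ScoringScheme
from asmob.synthetic import default_spec, generate_community


@pytest.fixture(scope="session")
def scheme() -> ScoringScheme:
    return ScoringScheme()


def random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=length))


@pytest.fixture(scope="session")
def community(tmp_path_factory) -> tuple[Path, dict]:
    """Default synthetic community (seed 1) written to a session tmp dir."""
    out = tmp_path_factory.mktemp("community")
    generate_community(default_spec(1), out)
    truth = json.loads((out / "truth.json").read_text())
    return out, truth


def pipeline_config(data_dir: Path, seed: int = 1) -> PipelineConfig:
    return PipelineConfig(
        proteins=str(data_dir / "proteins.faa"),
        contigs=str(data_dir / "contigs.fna"),
        genes=str(data_dir / "genes.tsv"),
        mags=str(data_dir / "mags.tsv"),
        refs=str(data_dir / "refs"),
        markers=str(data_dir / "markers.tsv"),
        sams={
            "S1": str(data_dir / "reads_S1.sam"),
            "S2": str(data_dir / "reads_S2.sam"),
        },
        annotations=str(data_dir / "annotations.tsv"),
        localization=str(data_dir / "localization.tsv"),
        seed=seed,
    )


@pytest.fixture(scope="session")
def pipeline_run(community):
    """One full pipeline run over the default community."""
    data_dir, truth = community
    config = pipeline_config(data_dir)
    report = run_pipeline(config, data_dir / "run")
    return data_dir, truth, config, report
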