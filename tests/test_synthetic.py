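import hashlib
import itertools
import json

import numpy as np
import pytest
from scipy import stats

from asmob.errors import DataError
from asmob.io import read_fasta, read_sam_lite
from asmob.mhc import scan_motifs
from asmob.records import ProteinRecord
from asmob.synthetic import (
    MagSpec,
    MhcPlant,
    SimulationSpec,
    default_spec,
    diverge,
    generate_community,
    generate_family,
    marker_counts_for,
    random_protein,
    sample_positions,
)


def _identity(a: str, b: str) -> float:
    return sum(x == y for x, y in zip(a, b)) / len(a)


class TestFamilyGeneration:
    def test_full_identity_members_equal_seed(self):
        rng = np.random.default_rng(1)
        rs, seed = generate_family(rng, "fam", "target", 3, 100.0, length=200)
        assert all(m.sequence == seed for m in rs.members)

    def test_target_identity_realized_within_band(self):
        rng = np.random.default_rng(2)
        rs, seed = generate_family(rng, "fam", "target", 5, 80.0, length=300)
        for m in rs.members:
            assert 0.78 <= _identity(m.sequence, seed) <= 0.82

    def test_independent_families_are_unrelated(self):
        rng = np.random.default_rng(3)
        pairs = []
        for _ in range(5):
            a = random_protein(rng, 300)
            b = random_protein(rng, 300)
            pairs.append(_identity(a, b))
        assert max(pairs) < 0.25

    def test_shared_ancestor_controls_between_family_identity(self):
        rng = np.random.default_rng(4)
        ancestor = random_protein(rng, 400)
        seed_a = diverge(rng, ancestor, 60.0)
        seed_b = diverge(rng, ancestor, 60.0)
        ident = _identity(seed_a, seed_b)
        assert 0.30 <= ident <= 0.50  # near 0.6^2 plus background


class TestMarkerFeasibility:
    def test_exact_counts_accepted(self):
        assert marker_counts_for(75.0, 2.5, 40) == (30, 1)

    def test_infeasible_pair_rejected_with_nearest(self):
        with pytest.raises(DataError, match="nearest feasible"):
            marker_counts_for(75.0, 2.0, 40)  # 2% of 40 = 0.8 copies


class TestReadPositions:
    def test_uniform_when_ptr_one(self):
        rng = np.random.default_rng(5)
        x = sample_positions(rng, 20_000, 1.0, 1_000_000) / 1_000_000
        assert stats.kstest(x, "uniform").pvalue > 0.01

    def test_origin_terminus_ratio_for_ptr_two(self):
        rng = np.random.default_rng(6)
        L = 1_000_000
        pos = sample_positions(rng, 1_000_000, 2.0, L)  # ~100x at 100 bp reads
        near_origin = np.sum(pos < L * 0.1)
        near_terminus = np.sum(pos >= L * 0.9)
        assert 1.8 <= near_origin / near_terminus <= 2.2

    def test_density_monotone_decreasing(self):
        rng = np.random.default_rng(7)
        pos = sample_positions(rng, 200_000, 1.5, 1_000_000)
        hist, _ = np.histogram(pos, bins=10)
        assert (np.diff(hist) < 0).mean() > 0.8


class TestGeneratedCommunity:
    def test_same_seed_byte_identical(self, tmp_path):
        a, b = tmp_path / "a", tmp_path / "b"
        generate_community(default_spec(123), a)
        generate_community(default_spec(123), b)
        for path in sorted(a.iterdir()):
            if path.is_dir():
                continue
            ha = hashlib.sha256(path.read_bytes()).hexdigest()
            hb = hashlib.sha256((b / path.name).read_bytes()).hexdigest()
            assert ha == hb, path.name

    def test_outputs_parse_and_match_truth(self, community):
        data_dir, truth = community
        proteins = read_fasta(data_dir / "proteins.faa", "protein")
        contigs = read_fasta(data_dir / "contigs.fna", "nucleotide")
        assert len({p.id for p in proteins}) == len(proteins)
        assert {c.id.rsplit("_", 1)[0] for c in contigs} == set(truth["mags"])
        sam = read_sam_lite(data_dir / "reads_S1.sam")
        assert sum(1 for r in sam if r.mapped) > 0

    def test_total_sam_records_match_request(self, community):
        data_dir, truth = community
        spec = default_spec(1)
        sam = read_sam_lite(data_dir / "reads_S1.sam")
        contig_len = sum(spec.mags[0].contig_lengths)
        expected_mapped = sum(
            int(round(m.depths["S1"] * sum(m.contig_lengths) / spec.read_length))
            for m in spec.mags
        )
        mapped = sum(1 for r in sam if r.mapped)
        assert mapped == expected_mapped
        assert sum(1 for r in sam if not r.mapped) == int(
            round(spec.unmapped_frac * mapped)
        )

    def test_planted_motif_counts_closed_loop(self, community):
        data_dir, truth = community
        by_id = {p.id: p for p in read_fasta(data_dir / "proteins.faa", "protein")}
        checked = 0
        for pid, info in truth["proteins"].items():
            if info["kind"] == "mhc":
                assert scan_motifs(by_id[pid]).motif_count == info["motifs"]
                checked += 1
        assert checked >= 5

    def test_planted_genes_translate_back_to_proteins(self, community):
        """Reverse-translated genes must decode to the planted protein."""
        from Bio.Seq import Seq

        data_dir, truth = community
        by_id = {p.id: p for p in read_fasta(data_dir / "proteins.faa", "protein")}
        contig = {c.id: c.sequence for c in read_fasta(data_dir / "contigs.fna", "nucleotide")}
        rows = (data_dir / "genes.tsv").read_text().splitlines()[1:]
        for row in rows[:20]:
            gene_id, cid, start, end = row.split("\t")
            nt = contig[cid][int(start) - 1 : int(end)]
            assert str(Seq(nt).translate(table=11)) == by_id[gene_id].sequence

    def test_infeasible_gene_packing_rejected(self, tmp_path):
        spec = SimulationSpec(
            seed=9,
            samples=("S1",),
            mags=(
                MagSpec(
                    mag_id="M1", contig_lengths=(600,),
                    functions=("arsB",), has_rps3=True,
                    depths={"S1": 5.0},
                ),
            ),
        )
        with pytest.raises(DataError, match="contig capacity"):
            generate_community(spec, tmp_path / "x")

    def test_truth_funnel_arithmetic(self, community):
        _, truth = community
        f = truth["funnel"]
        assert f["total"] >= f["medium_or_better"] >= f["with_rps3"] >= f["analysis"]
        assert f["analysis"] == len(truth["analysis_set"])
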