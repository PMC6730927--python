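"""End-to-end pipeline orchestration.

Stage order: screen-genes -> disambiguate (arrA/aioA only) -> screen-mhc
-> qc -> abundance -> irep -> report.  Every intermediate is written as
TSV under the run directory; the run report is JSON with a frozen config
hash, so a rerun with identical config and inputs is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .abundance import (
    DEFAULT_MOTIF_BINS,
    GeneInterval,
    count_reads_per_gene,
    function_rpkm_summary,
    rpkm,
)
from .errors import AsmobError, ConfigError, DataError
from .homology import ReferenceSet, load_reference_dir, screen_proteins
from .io import (
    read_annotation_table,
    read_fasta,
    read_gene_table,
    read_localization_table,
    read_mag_assignment,
    read_marker_table,
    read_sam_lite,
    write_tsv,
)
from .mag_qc import MagQuality, MarkerTable, analysis_set, function_profile, quality_from_markers
from .mhc import build_network, filter_candidates, mag_motif_profile, scan_motifs
from .msa import p_distance_matrix, progressive_align, trim_gap_columns
from .records import AnnotationTable, LocalizationTable, ProteinRecord
from .replication import (
    ReplicationConfig,
    eligible_mags,
    estimate_irep,
    window_coverage,
)
from .scoring import ScoringScheme
from .tree import assign_clades, nj_tree


@dataclass
class PipelineConfig:
    """Input paths and every screening threshold, serialized with outputs."""

    proteins: str
    contigs: str
    genes: str
    mags: str
    refs: str
    markers: str
    sams: dict[str, str] = field(default_factory=dict)  # sample -> SAM path
    annotations: str | None = None
    localization: str | None = None
    evalue_max: float = 1e-40
    max_gap_frac: float = 0.95
    min_motifs: int = 3
    score_cutoff: float = 67.0
    motif_flag_threshold: int = 50
    outgroup_family: str = "dmso"
    count_mode: str = "start_in"
    window_size: int = 5000
    step: int = 100
    trim_frac: float = 0.05
    min_r2: float = 0.90
    min_completeness: float = 75.0
    max_contamination: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.max_gap_frac <= 1):
            raise ConfigError("max_gap_frac must be in (0, 1]")
        if self.evalue_max <= 0:
            raise ConfigError("evalue_max must be positive")
        if self.min_motifs < 1:
            raise ConfigError("min_motifs must be >= 1")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        try:
            return cls(**raw)
        except TypeError as exc:
            raise ConfigError(f"{path}: {exc}") from None

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True).encode()
        ).hexdigest()


class PipelineStageError(DataError):
    def __init__(self, stage: str, exc: Exception):
        super().__init__(f"stage {stage!r} failed: {exc}")
        self.stage = stage


@dataclass
class RunReport:
    """Headline outputs of one run, mirrored to report.json."""

    funnel: list[dict]
    function_matrix: dict[str, dict[str, bool]]
    family_rpkm: list[dict]
    mhc_bin_rpkm: list[dict]
    irep_by_function: list[dict]
    mag_motif_profiles: list[dict]
    counts: dict[str, int]
    provenance: dict

    def to_json(self) -> str:
        payload = asdict(self)
        sizes = [
            self.counts.get("analysis_set", 0),
            self.counts.get("medium_or_better", 0),
            self.counts.get("total_mags", 0),
        ]
        if sorted(sizes) != sizes:
            raise DataError("report inconsistency: filter funnel not monotone")
        return json.dumps(payload, indent=1, sort_keys=True) + "\n"


def summarize_counts(
    total: int, medium: int, with_rps3: int, analysis: int
) -> list[dict]:
    """Filter funnel rows (input count, surviving count, rule applied)."""
    rows = [
        {"stage": "all_mags", "input": total, "surviving": total, "rule": "none"},
        {
            "stage": "quality",
            "input": total,
            "surviving": medium,
            "rule": "completeness >= 50% and contamination < 10%",
        },
        {
            "stage": "rps3",
            "input": medium,
            "surviving": with_rps3,
            "rule": "ribosomal protein S3 detected",
        },
        {
            "stage": "function",
            "input": with_rps3,
            "surviving": analysis,
            "rule": ">= 1 function of interest",
        },
    ]
    prev = None
    for row in rows:
        if prev is not None and row["surviving"] > prev:
            raise DataError("filter funnel is not monotone non-increasing")
        prev = row["surviving"]
    return rows


def _stage(name):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except AsmobError as exc:
                raise PipelineStageError(name, exc) from exc
        return wrapper
    return deco


def _disambiguate(
    proteins_by_id: dict[str, ProteinRecord],
    refs: list[ReferenceSet],
    queries: set[str],
    config: PipelineConfig,
    scheme: ScoringScheme,
):
    """Align queries with molybdopterin references, build NJ tree, test clades."""
    clade_families = {"arrA", "aioA"}
    tree_refs = [
        r for r in refs
        if r.family in clade_families or r.role in ("decoy", "outgroup")
    ]
    seqs = [proteins_by_id[q] for q in sorted(queries)]
    for r in tree_refs:
        seqs.extend(r.members)
    aln = progressive_align(seqs, scheme)
    aln = trim_gap_columns(aln, config.max_gap_frac)
    dm = p_distance_matrix(aln)
    tree = nj_tree(dm)
    decisions = assign_clades(tree, tree_refs, queries, config.outgroup_family)
    return decisions, tree


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> RunReport:
    """Execute every stage, writing intermediates and report.json to outdir."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    scheme = ScoringScheme()

    # ---- load inputs
    proteins = read_fasta(config.proteins, "protein")
    contigs = read_fasta(config.contigs, "nucleotide")
    genes_raw = read_gene_table(config.genes)
    mag_of_contig = read_mag_assignment(config.mags)
    refs = load_reference_dir(config.refs)
    markers_raw = read_marker_table(config.markers)
    annotations = (
        read_annotation_table(config.annotations)
        if config.annotations
        else AnnotationTable()
    )
    localizations = (
        read_localization_table(config.localization)
        if config.localization
        else LocalizationTable()
    )
    proteins_by_id = {p.id: p for p in proteins}
    contig_lengths = {c.id: len(c) for c in contigs}
    genes = [
        GeneInterval(g["gene_id"], g["contig_id"], g["start"], g["end"])
        for g in genes_raw
    ]
    mag_of_gene = {
        g.gene_id: mag_of_contig[g.contig_id]
        for g in genes
        if g.contig_id in mag_of_contig
    }
    all_mags = sorted(set(mag_of_contig.values()))

    # ---- stage: screen-genes
    hits = _stage("screen-genes")(screen_proteins)(
        proteins, refs, scheme, config.evalue_max
    )
    write_tsv(
        outdir / "hits.tsv",
        ["query", "family", "subject", "raw_score", "bitscore", "evalue",
         "query_span", "subject_span"],
        [
            (h.query_id, h.family, h.subject_id, h.raw_score,
             f"{h.bitscore:.2f}", f"{h.evalue:.3e}",
             f"{h.query_span[0]}-{h.query_span[1]}" if h.query_span else "",
             f"{h.subject_span[0]}-{h.subject_span[1]}" if h.subject_span else "")
            for h in sorted(hits, key=lambda h: (h.query_id, h.family))
        ],
    )

    # ---- stage: disambiguate
    molyb_queries = {h.query_id for h in hits if h.family in ("arrA", "aioA")}
    accepted: dict[str, set[str]] = {"arrA": set(), "aioA": set()}
    clade_rows = []
    if molyb_queries:
        decisions, tree = _stage("disambiguate")(_disambiguate)(
            proteins_by_id, refs, molyb_queries, config, scheme
        )
        tree.write(str(outdir / "molybdopterin_nj.nwk"))
        for d in decisions:
            clade_rows.append((d.query_id, d.family, int(d.accepted)))
            if d.accepted:
                accepted[d.family].add(d.query_id)
    write_tsv(outdir / "clades.tsv", ["query", "family", "accepted"], clade_rows)

    # ---- stage: screen-mhc
    inventories = [
        scan_motifs(p, config.min_motifs) for p in sorted(proteins, key=lambda p: p.id)
    ]
    candidates = [
        proteins_by_id[i.protein_id] for i in inventories if i.is_candidate
    ]
    network = None
    if candidates:
        network = _stage("screen-mhc")(build_network)(
            candidates, refs, scheme, config.score_cutoff
        )
        write_tsv(
            outdir / "mhc_network.tsv",
            ["source", "target", "score"],
            [
                (a, b, f"{d['score']:.2f}")
                for a, b, d in sorted(network.graph.edges(data=True))
            ],
        )
    mhc_candidates = _stage("screen-mhc")(filter_candidates)(
        inventories, network, annotations, localizations, min_motifs=config.min_motifs
    )
    write_tsv(
        outdir / "mhc.tsv",
        ["protein_id", "motif_count", "cluster", "localization", "status"],
        [
            (c.protein_id, c.motif_count,
             "" if c.cluster_id is None else c.cluster_id, c.localization, c.status)
            for c in mhc_candidates
        ],
    )
    retained = [c for c in mhc_candidates if c.status == "retained"]

    # ---- functions per MAG
    functions_by_mag: dict[str, set[str]] = {m: set() for m in all_mags}
    rps3_mags: set[str] = set()
    for h in hits:
        mag = mag_of_gene.get(h.query_id)
        if mag is None:
            continue
        if h.family in ("arsB", "arsC", "dsrD"):
            functions_by_mag[mag].add(h.family)
        elif h.family == "rps3":
            rps3_mags.add(mag)
    for fam, ids in accepted.items():
        for q in ids:
            mag = mag_of_gene.get(q)
            if mag is not None:
                functions_by_mag[mag].add(fam)
    for c in retained:
        mag = mag_of_gene.get(c.protein_id)
        if mag is not None:
            functions_by_mag[mag].add("MHC")

    # ---- stage: qc
    marker_table = MarkerTable.from_long(markers_raw)
    qualities: list[MagQuality] = _stage("qc")(quality_from_markers)(marker_table)
    for q in qualities:
        q.has_rps3 = q.mag_id in rps3_mags
        q.functions = functions_by_mag.get(q.mag_id, set())
    write_tsv(
        outdir / "qc.tsv",
        ["mag_id", "completeness", "contamination", "tier", "rps3", "functions"],
        [
            (q.mag_id, f"{q.completeness:.4f}", f"{q.contamination:.4f}", q.tier,
             int(q.has_rps3), ",".join(sorted(q.functions)))
            for q in qualities
        ],
    )
    selected = analysis_set(qualities, functions_by_mag, rps3_mags)
    matrix = function_profile(selected, functions_by_mag)
    matrix.to_csv(outdir / "function_matrix.tsv", sep="\t")

    # ---- stage: abundance
    rpkm_tables: dict[str, pd.DataFrame] = {}
    total_mapped: dict[str, int] = {}
    for sample in sorted(config.sams):
        sam = read_sam_lite(config.sams[sample])
        counts, total = _stage("abundance")(count_reads_per_gene)(
            sam, genes, config.count_mode, known_contigs=set(contig_lengths)
        )
        table = rpkm(counts, genes, total)
        rpkm_tables[sample] = table
        total_mapped[sample] = total
        table.to_csv(outdir / f"rpkm_{sample}.tsv", sep="\t", index=False)
    gene_families: dict[str, str] = {}
    for h in hits:
        if h.family in ("arsB", "arsC", "dsrD"):
            gene_families[h.query_id] = h.family
    for fam, ids in accepted.items():
        for q in ids:
            gene_families[q] = fam
    mhc_counts = {c.protein_id: c.motif_count for c in retained}
    panel_a, panel_b = function_rpkm_summary(
        rpkm_tables, gene_families, mhc_counts, DEFAULT_MOTIF_BINS
    )
    panel_a.to_csv(outdir / "fig1a_family_rpkm.tsv", sep="\t", index=False)
    panel_b.to_csv(outdir / "fig1b_mhc_rpkm.tsv", sep="\t", index=False)

    # ---- stage: irep
    rep_config = ReplicationConfig(
        window_size=config.window_size, step=config.step,
        trim_frac=config.trim_frac, min_r2=config.min_r2,
        min_completeness=config.min_completeness,
        max_contamination=config.max_contamination,
    )
    eligible = eligible_mags(qualities, rep_config)
    irep_rows = []
    fig2_frames = []
    for sample in sorted(config.sams):
        sam = read_sam_lite(config.sams[sample])
        elig_contigs = {
            c: m for c, m in mag_of_contig.items() if m in eligible
        }
        if not elig_contigs:
            continue
        profiles = _stage("irep")(window_coverage)(
            sam, contig_lengths, elig_contigs, rep_config
        )
        estimates = []
        for mag in sorted(profiles):
            est = _stage("irep")(estimate_irep)(profiles[mag], rep_config)
            estimates.append(est)
            irep_rows.append(
                (mag, sample, f"{est.irep:.4f}", f"{est.slope:.4f}",
                 f"{est.r2:.4f}", int(est.reliable), est.n_windows)
            )
        from .replication import irep_by_function as _ibf

        frame = _ibf(estimates, functions_by_mag)
        frame.insert(0, "sample", sample)
        fig2_frames.append(frame)
    write_tsv(
        outdir / "irep.tsv",
        ["mag_id", "sample", "irep", "slope", "r2", "reliable", "n_windows"],
        irep_rows,
    )
    fig2 = (
        pd.concat(fig2_frames, ignore_index=True)
        if fig2_frames
        else pd.DataFrame(
            columns=["sample", "function", "mag_id", "irep", "log_irep", "r2", "reliable"]
        )
    )
    fig2.to_csv(outdir / "fig2_irep_by_function.tsv", sep="\t", index=False)

    # ---- report
    profiles5 = mag_motif_profile(
        mhc_candidates, mag_of_gene, config.motif_flag_threshold
    )
    medium = [q.mag_id for q in qualities if q.tier != "low"]
    with_rps3 = [m for m in medium if m in rps3_mags]
    funnel = summarize_counts(
        len(qualities), len(medium), len(with_rps3), len(selected)
    )
    report = RunReport(
        funnel=funnel,
        function_matrix={
            mag: {fn: bool(v) for fn, v in row.items()}
            for mag, row in matrix.iterrows()
        },
        family_rpkm=panel_a.to_dict("records"),
        mhc_bin_rpkm=panel_b.to_dict("records"),
        irep_by_function=[
            {**rec, "log_base": "e"} for rec in fig2.to_dict("records")
        ],
        mag_motif_profiles=[
            {
                "mag_id": p.mag_id,
                "proteins": [list(t) for t in p.proteins],
                "total_motifs": p.total_motifs,
                "flagged": p.flagged,
            }
            for p in profiles5
            if p.total_motifs > 0
        ],
        counts={
            "total_mags": len(qualities),
            "medium_or_better": len(medium),
            "with_rps3": len(with_rps3),
            "analysis_set": len(selected),
            "homology_hits": len(hits),
            "mhc_candidates": sum(1 for c in mhc_candidates if c.status != "below_threshold"),
            "mhc_retained": len(retained),
            "irep_estimates": len(irep_rows),
            "eligible_irep": len(eligible),
        },
        provenance={
            "config_sha256": config.digest(),
            "seed": config.seed,
            "version": __version__,
            "total_mapped_reads": total_mapped,
        },
    )
    (outdir / "report.json").write_text(report.to_json())
    (outdir / "config.json").write_text(
        json.dumps(asdict(config), indent=1, sort_keys=True) + "\n"
    )
    return report
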