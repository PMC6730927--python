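"""RPKM gene-abundance computation from read mappings.

RPKM = reads mapped to gene / ((gene length / 1000) * (total mapped
reads / 1e6)); the total is all mapped reads in the sample, not only
reads falling in genes.  Two counting modes are provided: ``start_in``
(default; a read belongs to a gene iff its leftmost coordinate lies in
the gene) and ``overlap`` (any intersection counts).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigError, DataError
from .records import SamRecordLite


@dataclass(frozen=True)
class GeneInterval:
    """1-based inclusive gene interval on a contig."""

    gene_id: str
    contig_id: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise DataError(
                f"gene {self.gene_id!r}: invalid interval [{self.start}, {self.end}]"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def count_reads_per_gene(
    sam: list[SamRecordLite],
    genes: list[GeneInterval],
    mode: str = "start_in",
    known_contigs: set[str] | None = None,
) -> tuple[dict[str, int], int]:
    """Count mapped reads per gene; returns (counts, total_mapped_reads).

    Each mapped read is counted at most once per gene.  Reads on contigs
    without genes still count toward the mapped total; a read on a contig
    that is neither in the gene table nor in ``known_contigs`` triggers a
    warning (it still counts toward the total).
    """
    if mode not in ("start_in", "overlap"):
        raise ConfigError(f"unknown counting mode {mode!r}")
    by_contig: dict[str, list[GeneInterval]] = {}
    for g in genes:
        by_contig.setdefault(g.contig_id, []).append(g)

    pos_by_contig: dict[str, list[tuple[int, int]]] = {}
    total_mapped = 0
    unknown_contigs: set[str] = set()
    for rec in sam:
        if not rec.mapped:
            continue
        total_mapped += 1
        if rec.ref_id not in by_contig:
            if known_contigs is None or rec.ref_id not in known_contigs:
                unknown_contigs.add(rec.ref_id)
            continue
        pos_by_contig.setdefault(rec.ref_id, []).append((rec.pos, rec.read_len))
    if unknown_contigs:
        warnings.warn(
            f"reads on {len(unknown_contigs)} contig(s) without gene annotations "
            "counted toward the mapped total only"
        )

    counts = {g.gene_id: 0 for g in genes}
    for contig, reads in pos_by_contig.items():
        pos = np.array([p for p, _ in reads], dtype=np.int64)
        rlen = np.array([l for _, l in reads], dtype=np.int64)
        for g in by_contig[contig]:
            if mode == "start_in":
                n = int(np.count_nonzero((pos >= g.start) & (pos <= g.end)))
            else:
                n = int(np.count_nonzero((pos <= g.end) & (pos + rlen - 1 >= g.start)))
            counts[g.gene_id] += n
    return counts, total_mapped


def rpkm(
    counts: dict[str, int],
    genes: list[GeneInterval],
    total_mapped_reads: int,
) -> pd.DataFrame:
    """Per-gene RPKM table (gene_id, length, count, rpkm)."""
    if total_mapped_reads <= 0:
        raise DataError("rpkm: total_mapped_reads must be positive")
    rows = []
    for g in genes:
        c = counts.get(g.gene_id, 0)
        value = c / ((g.length / 1000.0) * (total_mapped_reads / 1e6))
        rows.append((g.gene_id, g.length, c, value))
    return pd.DataFrame(rows, columns=["gene_id", "length", "count", "rpkm"])


#: Default CXXCH-count bins for the cytochrome abundance panel.
DEFAULT_MOTIF_BINS = ((3, 5), (6, 10), (11, 20), (21, None))


def motif_bin_label(count: int, bins=DEFAULT_MOTIF_BINS) -> str | None:
    for lo, hi in bins:
        if count >= lo and (hi is None or count <= hi):
            return f"{lo}+" if hi is None else f"{lo}-{hi}"
    return None


def function_rpkm_summary(
    rpkm_tables: dict[str, pd.DataFrame],
    gene_families: dict[str, str],
    mhc_motif_counts: dict[str, int],
    motif_bins=DEFAULT_MOTIF_BINS,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-sample function abundances for the two report panels.

    Panel A: summed RPKM per marker family (gene -> family from the
    screens, arrA/aioA post-disambiguation).  Panel B: summed RPKM of
    retained MHC genes grouped into CXXCH-count bins.

    ``rpkm_tables`` maps sample id -> per-gene RPKM table;
    ``gene_families`` maps gene id -> family label;
    ``mhc_motif_counts`` maps retained MHC gene id -> motif count.
    """
    rows_a, rows_b = [], []
    for sample in sorted(rpkm_tables):
        table = rpkm_tables[sample].set_index("gene_id")["rpkm"]
        fam_sums: dict[str, float] = {}
        bin_sums: dict[str, float] = {}
        for gene, value in table.items():
            fam = gene_families.get(gene)
            if fam is not None:
                fam_sums[fam] = fam_sums.get(fam, 0.0) + float(value)
            k = mhc_motif_counts.get(gene)
            if k is not None:
                label = motif_bin_label(k, motif_bins)
                if label is not None:
                    bin_sums[label] = bin_sums.get(label, 0.0) + float(value)
        rows_a.extend((sample, f, v) for f, v in sorted(fam_sums.items()))
        rows_b.extend((sample, b, v) for b, v in sorted(bin_sums.items()))
    panel_a = pd.DataFrame(rows_a, columns=["sample", "family", "rpkm"])
    panel_b = pd.DataFrame(rows_b, columns=["sample", "motif_bin", "rpkm"])
    return panel_a, panel_b
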