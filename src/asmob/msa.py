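"""Progressive multiple alignment, gap-column trimming and p-distances.

A deliberately simple MUSCLE stand-in: a UPGMA guide tree on 3-mer
cosine distances drives profile-profile merges by global affine-gap
Needleman-Wunsch on column frequency profiles.  The alignment is used
downstream only as a distance source for clade classification, so
benchmark-grade accuracy is not the goal; determinism is.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import linkage
from skbio import DistanceMatrix

from ._dp import nw_profile
from .errors import ConfigError, DataError
from .records import ProteinRecord
from .scoring import ALPHABET, ScoringScheme

GAP = "-"


@dataclass
class MultipleAlignment:
    """Equal-length gapped rows keyed by sequence id (input order kept)."""

    ids: list[str]
    rows: dict[str, str]

    def __post_init__(self) -> None:
        lengths = {len(r) for r in self.rows.values()}
        if len(lengths) > 1:
            raise DataError("alignment rows have unequal lengths")
        if set(self.ids) != set(self.rows):
            raise DataError("alignment ids and rows disagree")

    @property
    def length(self) -> int:
        return len(next(iter(self.rows.values()))) if self.rows else 0

    @property
    def n_rows(self) -> int:
        return len(self.ids)

    def ungapped(self, seq_id: str) -> str:
        return self.rows[seq_id].replace(GAP, "")

    def column_gap_fractions(self) -> np.ndarray:
        arr = np.array([list(self.rows[i]) for i in self.ids])
        return (arr == GAP).mean(axis=0)


def _kmer_profile(seq: str, k: int = 3) -> dict[str, int]:
    prof: dict[str, int] = {}
    for i in range(len(seq) - k + 1):
        kmer = seq[i : i + k]
        prof[kmer] = prof.get(kmer, 0) + 1
    return prof


def _cosine_distance(a: dict[str, int], b: dict[str, int]) -> float:
    shared = set(a) & set(b)
    dot = sum(a[k] * b[k] for k in shared)
    na = np.sqrt(sum(v * v for v in a.values()))
    nb = np.sqrt(sum(v * v for v in b.values()))
    if na == 0 or nb == 0:
        return 1.0
    return 1.0 - dot / (na * nb)


def _profile_freqs(rows: list[str], scheme: ScoringScheme) -> np.ndarray:
    """Column residue frequencies (L x |ALPHABET|); gaps carry no weight."""
    n_res = len(ALPHABET)
    L = len(rows[0])
    freqs = np.zeros((L, n_res))
    for row in rows:
        enc = np.array([-1 if c == GAP else ALPHABET.index(c) for c in row])
        for j in range(L):
            if enc[j] >= 0:
                freqs[j, enc[j]] += 1.0
    return freqs / len(rows)


def _merge(
    rows_a: list[str], rows_b: list[str], scheme: ScoringScheme
) -> tuple[list[str], list[str]]:
    fa = _profile_freqs(rows_a, scheme)
    fb = _profile_freqs(rows_b, scheme)
    cell = fa @ scheme.matrix.astype(float) @ fb.T
    _, ops, k = nw_profile(cell, float(scheme.gap_open), float(scheme.gap_extend))
    ops = ops[:k][::-1]
    out_a = [[] for _ in rows_a]
    out_b = [[] for _ in rows_b]
    ia = ib = 0
    for op in ops:
        if op == 1:
            for r, row in zip(out_a, rows_a):
                r.append(row[ia])
            for r, row in zip(out_b, rows_b):
                r.append(row[ib])
            ia += 1
            ib += 1
        elif op == 2:  # column from A, gap in B
            for r, row in zip(out_a, rows_a):
                r.append(row[ia])
            for r in out_b:
                r.append(GAP)
            ia += 1
        else:
            for r in out_a:
                r.append(GAP)
            for r, row in zip(out_b, rows_b):
                r.append(row[ib])
            ib += 1
    return ["".join(r) for r in out_a], ["".join(r) for r in out_b]


def progressive_align(
    seqs: list[ProteinRecord], scheme: ScoringScheme | None = None
) -> MultipleAlignment:
    """Progressive profile alignment along a UPGMA guide tree.

    Deterministic given input order; a single sequence is returned as an
    identity alignment with a warning.
    """
    scheme = scheme or ScoringScheme()
    if not seqs:
        raise DataError("progressive_align: no sequences")
    ids = [s.id for s in seqs]
    if len(set(ids)) != len(ids):
        raise DataError("progressive_align: duplicate sequence ids")
    if len(seqs) == 1:
        warnings.warn("progressive_align: single sequence, identity alignment")
        return MultipleAlignment(ids=ids, rows={seqs[0].id: seqs[0].sequence})

    profiles = [_kmer_profile(s.sequence) for s in seqs]
    n = len(seqs)
    if n == 2:
        merges = [(0, 1)]
    else:
        cond = []
        for i in range(n):
            for j in range(i + 1, n):
                cond.append(_cosine_distance(profiles[i], profiles[j]))
        Z = linkage(np.array(cond), method="average")
        merges = [(int(a), int(b)) for a, b, _, _ in Z]

    # cluster index -> (member ids, gapped rows); leaves are 0..n-1
    clusters: dict[int, tuple[list[str], list[str]]] = {
        i: ([seqs[i].id], [seqs[i].sequence]) for i in range(n)
    }
    nxt = n
    for a, b in merges:
        ids_a, rows_a = clusters.pop(a)
        ids_b, rows_b = clusters.pop(b)
        new_a, new_b = _merge(rows_a, rows_b, scheme)
        clusters[nxt] = (ids_a + ids_b, new_a + new_b)
        nxt += 1
    (final_ids, final_rows), = clusters.values()
    rows = dict(zip(final_ids, final_rows))
    return MultipleAlignment(ids=ids, rows=rows)


def trim_gap_columns(
    aln: MultipleAlignment, max_gap_frac: float = 0.95
) -> MultipleAlignment:
    """Drop every column whose gap fraction is >= ``max_gap_frac``.

    Residues of minority rows in removed columns are deleted with the
    column (the usual behaviour of gap-threshold alignment trimmers).
    """
    if not (0 < max_gap_frac <= 1):
        raise ConfigError("max_gap_frac must be in (0, 1]")
    fracs = aln.column_gap_fractions()
    keep = fracs < max_gap_frac
    if not keep.any():
        raise DataError("alignment fully gapped at threshold")
    rows = {
        i: "".join(c for c, k in zip(aln.rows[i], keep) if k) for i in aln.ids
    }
    return MultipleAlignment(ids=list(aln.ids), rows=rows)


def p_distance_matrix(
    aln: MultipleAlignment, poisson_correct: bool = False
) -> DistanceMatrix:
    """Pairwise-deletion p-distance matrix over alignment rows.

    The distance for a pair is the mismatch proportion over columns where
    both rows are ungapped; ``poisson_correct`` applies -ln(1 - p).
    A pair sharing no ungapped column is an error naming the pair.
    """
    if aln.n_rows < 2:
        raise DataError("p_distance_matrix: need at least 2 rows")
    arr = np.array([list(aln.rows[i]) for i in aln.ids])
    gap = arr == GAP
    n = aln.n_rows
    dm = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = ~gap[i] & ~gap[j]
            shared = int(both.sum())
            if shared == 0:
                raise DataError(
                    f"no shared ungapped columns between {aln.ids[i]!r} and {aln.ids[j]!r}"
                )
            p = float((arr[i, both] != arr[j, both]).mean())
            if poisson_correct:
                if p >= 1.0:
                    raise DataError(
                        f"p-distance 1.0 between {aln.ids[i]!r} and {aln.ids[j]!r}: "
                        "Poisson correction undefined"
                    )
                p = -np.log(1.0 - p)
            dm[i, j] = dm[j, i] = p
    return DistanceMatrix(dm, ids=list(aln.ids))
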