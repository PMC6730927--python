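"""Substitution scoring and Karlin-Altschul statistics.

The screen converts raw Smith-Waterman scores S into E-values with

    E = K * m * n * exp(-lambda * S)

where m is the query length and n the total residue count of the searched
reference family.  For the default gapped scheme (BLOSUM62, gap open 11,
extend 1) the published gapped constants lambda = 0.267, K = 0.041 are
used; :func:`calibrate_lambda` solves the ungapped Karlin-Altschul
equation for arbitrary matrices.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from Bio.Align import substitution_matrices

from .errors import ConfigError

#: Residue order used for all score matrices (20 canonical + X).
ALPHABET = "ARNDCQEGHILKMFPSTWYVX"
_INDEX = {c: i for i, c in enumerate(ALPHABET)}

#: Published gapped Karlin-Altschul parameters for BLOSUM62 / 11 / 1.
GAPPED_LAMBDA = 0.267
GAPPED_K = 0.041

#: Robinson-Robinson amino-acid background frequencies, in ALPHABET order
#: (X excluded; used by lambda calibration for protein matrices).
ROBINSON_FREQS = {
    "A": 0.07805, "R": 0.05129, "N": 0.04487, "D": 0.05364, "C": 0.01925,
    "Q": 0.04264, "E": 0.06295, "G": 0.07377, "H": 0.02199, "I": 0.05142,
    "L": 0.09019, "K": 0.05744, "M": 0.02243, "F": 0.03856, "P": 0.05203,
    "S": 0.07120, "T": 0.05841, "W": 0.01330, "Y": 0.03216, "V": 0.06441,
}


def blosum62_matrix() -> np.ndarray:
    """BLOSUM62 as an int32 matrix over :data:`ALPHABET`; X scores 0."""
    bl = substitution_matrices.load("BLOSUM62")
    n = len(ALPHABET)
    mat = np.zeros((n, n), dtype=np.int32)
    for i, a in enumerate(ALPHABET[:-1]):
        for j, b in enumerate(ALPHABET[:-1]):
            mat[i, j] = int(bl[a][b])
    mat[_INDEX["X"], :] = 0
    mat[:, _INDEX["X"]] = 0
    return mat


@dataclass(frozen=True)
class ScoringScheme:
    """Affine-gap scoring scheme with Karlin-Altschul statistics.

    ``gap_open`` is the penalty for opening a gap; a gap of length g costs
    ``gap_open + g * gap_extend`` (open + extend charged on the first gap
    residue, the BLAST convention).
    """

    matrix: np.ndarray = field(default_factory=blosum62_matrix)
    gap_open: int = 11
    gap_extend: int = 1
    lam: float = GAPPED_LAMBDA
    k: float = GAPPED_K

    def __post_init__(self) -> None:
        if self.gap_open <= 0 or self.gap_extend <= 0:
            raise ConfigError("gap penalties must be positive")
        if self.lam <= 0 or self.k <= 0:
            raise ConfigError("lambda and K must be strictly positive")
        m = np.asarray(self.matrix)
        if m.shape != (len(ALPHABET), len(ALPHABET)):
            raise ConfigError(f"matrix must be {len(ALPHABET)}x{len(ALPHABET)}")
        if not np.array_equal(m, m.T):
            raise ConfigError("substitution matrix must be symmetric")

    def encode(self, sequence: str) -> np.ndarray:
        """Map a protein string onto matrix row indices (int8)."""
        try:
            return np.array([_INDEX[c] for c in sequence], dtype=np.int8)
        except KeyError as exc:
            raise ConfigError(f"residue {exc.args[0]!r} not in scoring alphabet") from None

    def evalue(self, raw_score: float, m: int, n: int) -> float:
        """Karlin-Altschul E-value for a raw score in an m x n search."""
        return self.k * m * n * math.exp(-self.lam * raw_score)

    def bitscore(self, raw_score: float) -> float:
        return (self.lam * raw_score - math.log(self.k)) / math.log(2)


def calibrate_lambda(
    matrix: np.ndarray,
    background_freqs: np.ndarray,
    tol: float = 1e-9,
) -> float:
    """Solve the ungapped Karlin-Altschul equation for lambda.

    Finds the unique positive root of ``sum_ij p_i p_j exp(lambda s_ij) = 1``
    by bisection to ``|f(lambda)| < tol``.  Requires a negative expected
    score and at least one positive score (else no positive root exists).
    """
    p = np.asarray(background_freqs, dtype=float)
    s = np.asarray(matrix, dtype=float)
    if s.shape[0] != s.shape[1] or s.shape[0] != p.size:
        raise ConfigError("matrix and background frequency sizes disagree")
    if abs(p.sum() - 1.0) > 1e-8:
        raise ConfigError("background frequencies must sum to 1")
    pp = np.outer(p, p)
    expected = float((pp * s).sum())
    if expected >= 0:
        raise ConfigError(
            f"expected score {expected:.4f} is non-negative; no valid lambda"
        )
    if s.max() <= 0:
        raise ConfigError("matrix has no positive score; no valid lambda")

    def f(lam: float) -> float:
        return float((pp * np.exp(lam * s)).sum()) - 1.0

    lo, hi = 0.0, 0.5
    while f(hi) < 0:
        hi *= 2.0
        if hi > 1e4:
            raise ConfigError("failed to bracket lambda")
    while True:
        mid = 0.5 * (lo + hi)
        val = f(mid)
        if abs(val) < tol:
            return mid
        if val < 0:
            lo = mid
        else:
            hi = mid


def robinson_background() -> np.ndarray:
    """Robinson-Robinson frequencies over the 20 canonical residues."""
    return np.array([ROBINSON_FREQS[c] for c in ALPHABET[:-1]], dtype=float)
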