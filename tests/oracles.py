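"""Independent brute-force oracles used only by the test suite.

Each function here is a deliberately naive re-derivation (plain Python,
no shared code paths with the package internals beyond the scoring
scheme's matrix) against which the optimized implementations are
checked.
"""

from __future__ import annotations

NEG = -(10**9)


def sw_score_oracle(query: str, subject: str, scheme) -> int:
    """Exhaustive three-matrix affine-gap local alignment DP (score only)."""
    q = [int(i) for i in scheme.encode(query)]
    s = [int(i) for i in scheme.encode(subject)]
    sub = scheme.matrix
    go = scheme.gap_open + scheme.gap_extend
    ge = scheme.gap_extend
    m, n = len(q), len(s)
    H = [[0] * (n + 1) for _ in range(m + 1)]
    E = [[NEG] * (n + 1) for _ in range(m + 1)]
    F = [[NEG] * (n + 1) for _ in range(m + 1)]
    best = 0
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            E[i][j] = max(H[i][j - 1] - go, E[i][j - 1] - ge)
            F[i][j] = max(H[i - 1][j] - go, F[i - 1][j] - ge)
            H[i][j] = max(
                0,
                H[i - 1][j - 1] + int(sub[q[i - 1], s[j - 1]]),
                E[i][j],
                F[i][j],
            )
            best = max(best, H[i][j])
    return best


def motif_count_oracle(sequence: str) -> tuple[int, list[int]]:
    """All CXXCH positions, then greedy left-to-right overlap resolution."""
    hits = []
    for i in range(len(sequence) - 4):
        if (
            sequence[i] == "C"
            and sequence[i + 3] == "C"
            and sequence[i + 4] == "H"
        ):
            hits.append(i + 1)  # 1-based
    chosen: list[int] = []
    for p in hits:
        if not chosen or p >= chosen[-1] + 5:
            chosen.append(p)
    return len(chosen), chosen


def p_distance_oracle(row_a: str, row_b: str) -> float:
    """Column-walk pairwise-deletion p-distance."""
    shared = mism = 0
    for a, b in zip(row_a, row_b):
        if a == "-" or b == "-":
            continue
        shared += 1
        if a != b:
            mism += 1
    if shared == 0:
        raise ValueError("no shared ungapped columns")
    return mism / shared


def window_means_oracle(
    contig_length: int,
    reads: list[tuple[int, int]],
    window_size: int,
    step: int,
) -> list[float]:
    """Per-base depth recomputation and explicit window averaging."""
    depth = [0] * contig_length
    for pos, read_len in reads:
        for t in range(pos - 1, min(pos - 1 + read_len, contig_length)):
            depth[t] += 1
    means = []
    start = 0
    while start + window_size <= contig_length:
        means.append(sum(depth[start : start + window_size]) / window_size)
        start += step
    return means


def read_count_oracle(
    reads: list[tuple[int, int]], start: int, end: int, mode: str
) -> int:
    """Interval-scan read counting for one gene."""
    n = 0
    for pos, read_len in reads:
        if mode == "start_in":
            if start <= pos <= end:
                n += 1
        else:
            if pos <= end and pos + read_len - 1 >= start:
                n += 1
    return n
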