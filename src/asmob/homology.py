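"""Protein homology screen against curated marker-gene families.

Each query protein is aligned (Smith-Waterman, affine gaps) to every
member of every target family; the best-scoring member per family is
converted to an E-value and gated (default 1e-40, the screen's match
threshold).  The decision is binary presence per family, so only the
best hit per (protein, family) pair is kept.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from ._dp import sw_align
from .errors import ConfigError, DataError
from .io import read_fasta
from .records import ProteinRecord
from .scoring import ScoringScheme

#: Valid reference-set roles.
ROLES = ("target", "decoy", "seed_metal", "seed_nonmetal", "outgroup")


@dataclass(frozen=True)
class ReferenceSet:
    """A named protein family used to drive a screen or clade test."""

    family: str
    role: str
    members: tuple[ProteinRecord, ...]

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ConfigError(f"reference set {self.family!r}: unknown role {self.role!r}")
        if not self.members:
            raise DataError(f"reference set {self.family!r}: no members")

    @property
    def total_residues(self) -> int:
        return sum(len(m) for m in self.members)

    def member_ids(self) -> set[str]:
        return {m.id for m in self.members}


@dataclass(frozen=True)
class HomologyHit:
    """Best alignment of a query protein against one reference family."""

    query_id: str
    subject_id: str
    family: str
    raw_score: int
    bitscore: float
    evalue: float
    query_span: tuple[int, int] | None
    subject_span: tuple[int, int] | None


def smith_waterman(
    query: str, subject: str, scheme: ScoringScheme
) -> tuple[int, tuple[int, int] | None, tuple[int, int] | None]:
    """Optimal local alignment score and 1-based inclusive spans.

    Returns ``(raw_score, query_span, subject_span)``; spans are ``None``
    when the optimal score is 0 (empty local alignment).
    """
    if not query or not subject:
        raise DataError("smith_waterman: empty sequence")
    q = scheme.encode(query)
    s = scheme.encode(subject)
    score, ops, k, qend, send = sw_align(
        q, s, scheme.matrix, scheme.gap_open, scheme.gap_extend
    )
    if score <= 0:
        return 0, None, None
    nq = int(np.sum(ops[:k] != 3))
    ns = int(np.sum(ops[:k] != 2))
    return int(score), (qend - nq + 1, qend), (send - ns + 1, send)


def aligned_columns(
    query: str, subject: str, scheme: ScoringScheme
) -> list[tuple[int, int]]:
    """Traceback columns of the optimal local alignment.

    Each element is ``(qpos, spos)`` 1-based, with 0 marking a gap.
    Used by the re-scoring invariant check; empty when the score is 0.
    """
    q = scheme.encode(query)
    s = scheme.encode(subject)
    score, ops, k, qend, send = sw_align(
        q, s, scheme.matrix, scheme.gap_open, scheme.gap_extend
    )
    if score <= 0:
        return []
    cols: list[tuple[int, int]] = []
    qi, sj = qend, send
    for t in range(k):
        op = ops[t]
        if op == 1:
            cols.append((qi, sj))
            qi -= 1
            sj -= 1
        elif op == 2:
            cols.append((qi, 0))
            qi -= 1
        else:
            cols.append((0, sj))
            sj -= 1
    cols.reverse()
    return cols


def screen_proteins(
    proteins: list[ProteinRecord],
    refs: list[ReferenceSet],
    scheme: ScoringScheme | None = None,
    evalue_max: float = 1e-40,
) -> list[HomologyHit]:
    """Screen proteins against all target families; keep hits passing the gate.

    For each (protein, family) pair the best-scoring member alignment is
    computed; E-values use m = query length and n = total residue count
    of the family.  At most one hit per pair is returned.
    """
    scheme = scheme or ScoringScheme()
    targets = [r for r in refs if r.role == "target"]
    if not targets:
        raise DataError("screen_proteins: no target reference sets")
    hits: list[HomologyHit] = []
    enc_refs = {
        r.family: [(m, scheme.encode(m.sequence)) for m in r.members] for r in targets
    }
    for prot in proteins:
        q = scheme.encode(prot.sequence)
        for ref in targets:
            best_score = -1
            best_member = None
            for member, s in enc_refs[ref.family]:
                score, _, _, _, _ = sw_align(
                    q, s, scheme.matrix, scheme.gap_open, scheme.gap_extend
                )
                if score > best_score:
                    best_score = int(score)
                    best_member = member
            if best_member is None or best_score <= 0:
                continue
            ev = scheme.evalue(best_score, len(prot), ref.total_residues)
            if ev <= evalue_max:
                raw, qspan, sspan = smith_waterman(
                    prot.sequence, best_member.sequence, scheme
                )
                hits.append(
                    HomologyHit(
                        query_id=prot.id,
                        subject_id=best_member.id,
                        family=ref.family,
                        raw_score=raw,
                        bitscore=scheme.bitscore(raw),
                        evalue=ev,
                        query_span=qspan,
                        subject_span=sspan,
                    )
                )
    return hits


def load_reference_dir(path: str | Path) -> list[ReferenceSet]:
    """Load reference sets from a directory of ``<family>__<role>.faa`` files."""
    path = Path(path)
    refs: list[ReferenceSet] = []
    seen: set[str] = set()
    for fasta in sorted(path.glob("*.faa")):
        stem = fasta.stem
        if "__" not in stem:
            raise ConfigError(
                f"{fasta}: reference file name must be <family>__<role>.faa"
            )
        family, role = stem.rsplit("__", 1)
        if family in seen:
            raise ConfigError(f"duplicate reference family {family!r}")
        seen.add(family)
        members = tuple(read_fasta(fasta, "protein"))
        refs.append(ReferenceSet(family=family, role=role, members=members))
    if not refs:
        raise ConfigError(f"{path}: no reference sets found")
    return refs
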