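"""Multiheme c-type cytochrome (MHC) inventory.

Hemes attach covalently at CXXCH (Cys-X-X-Cys-His) motifs; proteins with
at least ``min_motifs`` (default 3) motifs are MHC candidates.  Putative
non-metal-active cytochromes are then removed in a fixed order: known
non-metal annotation, similarity-network co-clustering with non-metal
seed references (score cutoff 67 bits), and cytoplasm-only localization.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import networkx as nx

from ._dp import sw_align
from .errors import DataError
from .homology import ReferenceSet
from .records import AnnotationTable, LocalizationTable, ProteinRecord
from .scoring import ScoringScheme

_MOTIF_GREEDY = re.compile(r"C..CH")
_MOTIF_ALL = re.compile(r"(?=(C..CH))")

#: Candidate statuses, in the order the filters fire.
STATUSES = (
    "below_threshold",
    "removed_annotation",
    "removed_cluster",
    "removed_cytoplasmic",
    "retained",
)

#: Default annotation labels treated as known non-metal cytochrome functions.
DEFAULT_DENYLIST = frozenset({"NapC/NirT", "NrfA", "HAO"})


@dataclass(frozen=True)
class MotifInventory:
    """CXXCH motif count and 1-based start positions for one protein."""

    protein_id: str
    motif_count: int
    motif_positions: tuple[int, ...]
    is_candidate: bool


@dataclass(frozen=True)
class MhcCandidate:
    protein_id: str
    motif_count: int
    cluster_id: int | None
    localization: str
    status: str


@dataclass
class SimilarityNetwork:
    """All-vs-all alignment-score network over candidates and seeds.

    Edges connect pairs whose Smith-Waterman bitscore meets the cutoff;
    clusters are connected components, numbered by smallest member id.
    """

    graph: nx.Graph
    cluster_of: dict[str, int] = field(default_factory=dict)
    clusters: list[frozenset[str]] = field(default_factory=list)
    node_roles: dict[str, str] = field(default_factory=dict)

    def cluster_has_role(self, cluster_id: int, role: str) -> bool:
        return any(self.node_roles.get(n) == role for n in self.clusters[cluster_id])


def scan_motifs(
    protein: ProteinRecord, min_motifs: int = 3, overlapping: bool = False
) -> MotifInventory:
    """Scan one protein for CXXCH motifs.

    The default left-to-right greedy scan counts non-overlapping motifs
    only (successive starts differ by >= 5), so no cysteine is counted
    toward two hemes; ``overlapping=True`` counts every match position.
    """
    pattern = _MOTIF_ALL if overlapping else _MOTIF_GREEDY
    positions = tuple(m.start() + 1 for m in pattern.finditer(protein.sequence))
    return MotifInventory(
        protein_id=protein.id,
        motif_count=len(positions),
        motif_positions=positions,
        is_candidate=len(positions) >= min_motifs,
    )


def build_network(
    candidates: list[ProteinRecord],
    seeds: list[ReferenceSet],
    scheme: ScoringScheme | None = None,
    score_cutoff: float = 67.0,
) -> SimilarityNetwork:
    """All-vs-all similarity network over candidates plus seed references."""
    if not candidates:
        raise DataError("build_network: no candidate proteins")
    scheme = scheme or ScoringScheme()
    node_roles: dict[str, str] = {c.id: "candidate" for c in candidates}
    seqs: list[ProteinRecord] = list(candidates)
    for ref in seeds:
        if ref.role not in ("seed_metal", "seed_nonmetal"):
            continue
        for m in ref.members:
            if m.id in node_roles:
                raise DataError(f"network node id collision: {m.id!r}")
            node_roles[m.id] = ref.role
            seqs.append(m)
    graph = nx.Graph()
    graph.add_nodes_from(node_roles)
    enc = [(p.id, scheme.encode(p.sequence)) for p in seqs]
    for i in range(len(enc)):
        for j in range(i + 1, len(enc)):
            score, _, _, _, _ = sw_align(
                enc[i][1], enc[j][1], scheme.matrix, scheme.gap_open, scheme.gap_extend
            )
            bits = scheme.bitscore(int(score))
            if bits >= score_cutoff:
                graph.add_edge(enc[i][0], enc[j][0], score=bits)
    comps = sorted(
        (frozenset(c) for c in nx.connected_components(graph)), key=min
    )
    cluster_of = {n: ci for ci, comp in enumerate(comps) for n in comp}
    return SimilarityNetwork(
        graph=graph, cluster_of=cluster_of, clusters=list(comps), node_roles=node_roles
    )


def filter_candidates(
    inventories: list[MotifInventory],
    network: SimilarityNetwork | None,
    annotations: AnnotationTable,
    localizations: LocalizationTable,
    denylist: frozenset[str] | set[str] = DEFAULT_DENYLIST,
    min_motifs: int = 3,
) -> list[MhcCandidate]:
    """Apply the three-step non-metal filter in fixed order.

    Order: below_threshold -> removed_annotation -> removed_cluster
    (component holds >= 1 non-metal seed and no metal seed) ->
    removed_cytoplasmic -> retained.  Missing annotation means no label;
    missing or Unknown localization retains.
    """
    out: list[MhcCandidate] = []
    for inv in inventories:
        loc = localizations.get(inv.protein_id)
        cluster = network.cluster_of.get(inv.protein_id) if network else None
        if inv.motif_count < min_motifs:
            status = "below_threshold"
        elif (annotations.get(inv.protein_id) or "") in denylist:
            status = "removed_annotation"
        elif (
            cluster is not None
            and network.cluster_has_role(cluster, "seed_nonmetal")
            and not network.cluster_has_role(cluster, "seed_metal")
        ):
            status = "removed_cluster"
        elif loc == "Cytoplasmic":
            status = "removed_cytoplasmic"
        else:
            status = "retained"
        out.append(
            MhcCandidate(
                protein_id=inv.protein_id,
                motif_count=inv.motif_count,
                cluster_id=cluster,
                localization=loc,
                status=status,
            )
        )
    return out


@dataclass(frozen=True)
class MagMotifProfile:
    """Retained-MHC motif inventory of one MAG (Fig-5-style report row)."""

    mag_id: str
    proteins: tuple[tuple[str, int], ...]  # (protein_id, motif_count)
    total_motifs: int
    flagged: bool  # total strictly greater than the report threshold


def mag_motif_profile(
    candidates: list[MhcCandidate],
    mag_assignment: dict[str, str],
    flag_threshold: int = 50,
) -> list[MagMotifProfile]:
    """Per-MAG motif totals over retained MHCs; flag MAGs above threshold.

    A MAG is flagged for the high-motif report iff its summed motif count
    strictly exceeds ``flag_threshold`` motifs per genome.
    """
    per_mag: dict[str, list[tuple[str, int]]] = {}
    for mag in sorted(set(mag_assignment.values())):
        per_mag[mag] = []
    for cand in candidates:
        if cand.status != "retained":
            continue
        mag = mag_assignment.get(cand.protein_id)
        if mag is None:
            continue
        per_mag.setdefault(mag, []).append((cand.protein_id, cand.motif_count))
    profiles = []
    for mag, prots in sorted(per_mag.items()):
        total = sum(c for _, c in prots)
        profiles.append(
            MagMotifProfile(
                mag_id=mag,
                proteins=tuple(sorted(prots)),
                total_motifs=total,
                flagged=total > flag_threshold,
            )
        )
    return profiles
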