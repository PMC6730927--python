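"""Seeded synthetic-community generator with a machine-readable truth table.

Every input the pipeline consumes is produced here: reference families
(targets, molybdopterin decoys, MHC seeds), MAG contigs with planted
genes, annotation/localization/marker tables, and pre-mapped reads whose
start density follows an origin-to-terminus exponential gradient for a
chosen peak-to-trough ratio (PTR).  Reads are emitted as SAM directly
from ground-truth coordinates, so coverage tests are exact and no
external mapper is required.

All reference sequences are synthetic stand-ins generated by controlled
divergence from random seed proteins, not database sequences; the
molybdopterin families (arrA, aioA, NapA decoy, DMSO-reductase outgroup)
are derived from a shared ancestor so that between-family identity is
~40% while within-family identity is high, reproducing the
cross-reactivity that makes clade disambiguation necessary.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio.Data import CodonTable

from .errors import ConfigError, DataError
from .homology import ReferenceSet
from .io import write_fasta, write_sam_lite, write_tsv
from .mag_qc import BACTERIAL_MARKERS_43
from .mhc import scan_motifs
from .records import ContigRecord, ProteinRecord

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_AA_ARR = np.frombuffer(AMINO_ACIDS.encode(), dtype=np.uint8)
NUCLEOTIDES = "ACGT"

# Residues safe to use around planted CXXCH motifs (no C or H, so planted
# motifs are the only motifs).
SAFE_RESIDUES = "ADEFGIKLMNPQRSTVWY"

_table = CodonTable.unambiguous_dna_by_id[11].forward_table
AA_TO_CODONS: dict[str, tuple[str, ...]] = {}
for codon, aa in sorted(_table.items()):
    AA_TO_CODONS.setdefault(aa, tuple())
    AA_TO_CODONS[aa] = AA_TO_CODONS[aa] + (codon,)


# ---------------------------------------------------------------------------
# sequence-level primitives


def random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(AMINO_ACIDS), size=length))


def random_nucleotides(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(NUCLEOTIDES), size=length))


def diverge(
    rng: np.random.Generator,
    sequence: str,
    target_identity: float,
    protected: frozenset[int] = frozenset(),
) -> str:
    """Mutate a protein to an exact target percent identity.

    Exactly round((1 - identity/100) * L) positions are substituted with
    a uniformly chosen *different* residue, so realized identity matches
    the target up to rounding (well within the +-2% contract).
    Positions in ``protected`` (0-based) are never touched.
    """
    if not (0 < target_identity <= 100):
        raise ConfigError("target identity must be in (0, 100]")
    L = len(sequence)
    n_mut = int(round((1.0 - target_identity / 100.0) * L))
    eligible = np.array([i for i in range(L) if i not in protected])
    if n_mut > eligible.size:
        raise ConfigError("too many protected positions for requested identity")
    sites = rng.choice(eligible, size=n_mut, replace=False)
    seq = list(sequence)
    for i in sites:
        choices = [a for a in AMINO_ACIDS if a != seq[i]]
        seq[i] = choices[rng.integers(len(choices))]
    return "".join(seq)


def strip_motifs(rng: np.random.Generator, sequence: str) -> str:
    """Destroy every CXXCH occurrence by replacing its leading cysteine."""
    seq = list(sequence)
    changed = True
    while changed:
        changed = False
        for i in range(len(seq) - 4):
            if seq[i] == "C" and seq[i + 3] == "C" and seq[i + 4] == "H":
                seq[i] = SAFE_RESIDUES[rng.integers(len(SAFE_RESIDUES))]
                changed = True
    return "".join(seq)


def motif_block(rng: np.random.Generator, k: int) -> str:
    """A tail with exactly k non-overlapping CXXCH motifs.

    Spacers between motifs have random length (8-20) and composition, so
    motif regions of unrelated proteins cannot align in phase without
    paying gap and mismatch penalties per motif; that keeps the shared
    CXXCH pattern itself from bridging unrelated families in the
    similarity network, as in real cytochromes where only the
    heme-binding residues are conserved across families.
    """
    parts = []
    for _ in range(k):
        spacer_len = int(rng.integers(8, 21))
        parts.append("".join(rng.choice(list(SAFE_RESIDUES), size=spacer_len)))
        x = rng.choice(list(SAFE_RESIDUES), size=2)
        parts.append(f"C{x[0]}{x[1]}CH")
    return "".join(parts)


def make_mhc_protein(
    rng: np.random.Generator, core_seed: str, identity: float, k_motifs: int
) -> str:
    """A motif-free diverged core plus a tail with exactly k motifs."""
    core = strip_motifs(rng, diverge(rng, core_seed, identity))
    return core + "GSG" + motif_block(rng, k_motifs)


def generate_family(
    rng: np.random.Generator,
    family: str,
    role: str,
    n_members: int,
    target_identity: float,
    seed_protein: str | None = None,
    length: int | None = None,
    id_prefix: str | None = None,
) -> tuple[ReferenceSet, str]:
    """A reference family diverged from a seed at controlled identity.

    Returns the set and the seed protein (for planting related queries).
    """
    if seed_protein is None:
        if length is None:
            raise ConfigError("need seed_protein or length")
        seed_protein = random_protein(rng, length)
    prefix = id_prefix or family
    members = tuple(
        ProteinRecord(
            id=f"{prefix}_ref{i + 1}",
            sequence=diverge(rng, seed_protein, target_identity),
        )
        for i in range(n_members)
    )
    return ReferenceSet(family=family, role=role, members=members), seed_protein


# ---------------------------------------------------------------------------
# community specification


@dataclass(frozen=True)
class MhcPlant:
    """One planted cytochrome: kind controls which filter should fire.

    kind: ``metal`` (retained), ``nonmetal`` (removed by clustering),
    ``cytoplasmic`` (metal-like but localized to the cytoplasm),
    ``annot_denied`` (non-metal annotation label), ``lowmotif``
    (below the 3-motif threshold).
    """

    kind: str
    motifs: int


@dataclass(frozen=True)
class MagSpec:
    mag_id: str
    contig_lengths: tuple[int, ...]
    functions: tuple[str, ...] = ()  # families among arsB/arsC/arrA/aioA/dsrD/napA
    has_rps3: bool = True
    mhc: tuple[MhcPlant, ...] = ()
    n_filler: int = 2
    completeness: float = 100.0  # percent over the marker universe
    contamination: float = 0.0
    ptr: float = 1.0
    depths: dict[str, float] = field(default_factory=dict)  # sample -> mean depth


@dataclass(frozen=True)
class SimulationSpec:
    """Everything the generator needs, plus the study conditions.

    ``ref_identity`` is the percent identity of reference members to
    their family seed (the radiation of the known family);
    ``member_identity`` is the identity of planted environmental genes
    to the reference member they descend from, so planted queries nest
    inside the reference clade; ``family_identity`` is the identity of
    each molybdopterin family seed to the shared ancestor, which sets
    between-family identity near its square.
    """

    seed: int
    mags: tuple[MagSpec, ...]
    samples: tuple[str, ...] = ("S1",)
    read_length: int = 100
    error_rate: float = 0.01
    unmapped_frac: float = 0.02
    ref_identity: float = 80.0
    member_identity: float = 90.0
    family_identity: float = 60.0
    mhc_core_identity: float = 80.0
    n_ref_members: int = 4
    marker_universe: tuple[str, ...] = BACTERIAL_MARKERS_43

    def __post_init__(self) -> None:
        if not self.mags:
            raise ConfigError("no MAGs in simulation spec")
        for m in self.mags:
            if m.ptr < 1:
                raise ConfigError(f"MAG {m.mag_id!r}: PTR must be >= 1")
            for s, d in m.depths.items():
                if d <= 0:
                    raise ConfigError(f"MAG {m.mag_id!r}, sample {s!r}: depth <= 0")


#: Family lengths (aa) used for the synthetic reference seeds.
FAMILY_LENGTHS = {
    "arsB": 430,
    "arsC": 140,
    "dsrD": 100,
    "rps3": 220,
    "molybdopterin": 400,
    "mhc_core": 300,
}


def generate_reference_sets(
    spec: SimulationSpec, rng: np.random.Generator
) -> tuple[list[ReferenceSet], dict[str, str]]:
    """All reference families; returns (sets, family -> seed protein)."""
    refs: list[ReferenceSet] = []
    seeds: dict[str, str] = {}
    for fam in ("arsB", "arsC", "dsrD", "rps3"):
        rs, seed = generate_family(
            rng, fam, "target", spec.n_ref_members, spec.ref_identity,
            length=FAMILY_LENGTHS[fam],
        )
        refs.append(rs)
        seeds[fam] = seed
    ancestor = random_protein(rng, FAMILY_LENGTHS["molybdopterin"])
    for fam, role in (
        ("arrA", "target"),
        ("aioA", "target"),
        ("napA", "decoy"),
        ("dmso", "outgroup"),
    ):
        fam_seed = diverge(rng, ancestor, spec.family_identity)
        n = spec.n_ref_members if role != "outgroup" else max(2, spec.n_ref_members - 1)
        rs, _ = generate_family(
            rng, fam, role, n, spec.ref_identity, seed_protein=fam_seed
        )
        refs.append(rs)
        seeds[fam] = fam_seed
    for fam, role, k in (("mhc_metal", "seed_metal", 10), ("mhc_nonmetal", "seed_nonmetal", 4)):
        core = strip_motifs(rng, random_protein(rng, FAMILY_LENGTHS["mhc_core"]))
        members = tuple(
            ProteinRecord(
                id=f"{fam}_ref{i + 1}",
                sequence=make_mhc_protein(rng, core, spec.member_identity, k),
            )
            for i in range(2)
        )
        refs.append(ReferenceSet(family=fam, role=role, members=members))
        seeds[fam] = core
    return refs, seeds


def marker_counts_for(
    completeness: float, contamination: float, n_markers: int
) -> tuple[int, int]:
    """Translate percent completeness/contamination into marker counts.

    Both must be exactly representable over the universe; infeasible
    requests raise :class:`DataError` naming the nearest feasible pair.
    """
    present_f = completeness * n_markers / 100.0
    extra_f = contamination * n_markers / 100.0
    present, extra = round(present_f), round(extra_f)
    if abs(present_f - present) > 1e-6 or abs(extra_f - extra) > 1e-6:
        near_c = 100.0 * present / n_markers
        near_x = 100.0 * extra / n_markers
        raise DataError(
            f"completeness/contamination ({completeness}, {contamination}) not "
            f"representable over {n_markers} markers; nearest feasible pair is "
            f"({near_c:.4f}, {near_x:.4f})"
        )
    if not (0 <= present <= n_markers):
        raise DataError("completeness out of range")
    if extra > 0 and present == 0:
        raise DataError("contamination requires at least one present marker")
    return present, extra


_LOCALIZATION_CYCLE = ("Periplasmic", "OuterMembrane", "Extracellular", "Unknown")


@dataclass
class GeneratedCommunity:
    """In-memory result of :func:`generate_mags` (also written to disk)."""

    refs: list[ReferenceSet]
    proteins: list[ProteinRecord]
    contigs: list[ContigRecord]
    genes: list[dict]
    mag_of_contig: dict[str, str]
    annotations: dict[str, str]
    localizations: dict[str, str]
    markers: dict[str, dict[str, int]]
    truth: dict


def generate_mags(spec: SimulationSpec, rng: np.random.Generator) -> GeneratedCommunity:
    """Build proteins, contigs, gene intervals, tables and the truth record."""
    refs, seeds = generate_reference_sets(spec, rng)
    ref_members = {r.family: [m.sequence for m in r.members] for r in refs}
    proteins: list[ProteinRecord] = []
    contigs: list[ContigRecord] = []
    genes: list[dict] = []
    mag_of_contig: dict[str, str] = {}
    annotations: dict[str, str] = {}
    localizations: dict[str, str] = {}
    markers: dict[str, dict[str, int]] = {}
    truth_mags: dict[str, dict] = {}
    truth_proteins: dict[str, dict] = {}

    n_markers = len(spec.marker_universe)
    for mag in spec.mags:
        gidx = 0
        mag_prots: list[tuple[str, str]] = []  # (protein_id, sequence)

        def new_id() -> str:
            nonlocal gidx
            gidx += 1
            return f"{mag.mag_id}_g{gidx:03d}"

        functions: set[str] = set()
        loc_cycle = 0
        def plant_gene(fam: str) -> str:
            # environmental genes descend from one known reference member,
            # so tree placement nests them inside the reference clade
            parents = ref_members[fam]
            parent = parents[int(rng.integers(len(parents)))]
            return diverge(rng, parent, spec.member_identity)

        for fam in mag.functions:
            pid = new_id()
            seq = plant_gene(fam)
            if fam in ("arsB", "arsC", "arrA", "aioA", "dsrD"):
                functions.add(fam)
            mag_prots.append((pid, seq))
            truth_proteins[pid] = {"kind": "family", "family": fam}
        if mag.has_rps3:
            pid = new_id()
            mag_prots.append((pid, plant_gene("rps3")))
            truth_proteins[pid] = {"kind": "family", "family": "rps3"}

        retained_mhc: dict[str, int] = {}
        mhc_status: dict[str, str] = {}
        for plant in mag.mhc:
            pid = new_id()
            if plant.kind in ("metal", "cytoplasmic"):
                seq = make_mhc_protein(
                    rng, seeds["mhc_metal"], spec.mhc_core_identity, plant.motifs
                )
            elif plant.kind in ("nonmetal", "annot_denied"):
                seq = make_mhc_protein(
                    rng, seeds["mhc_nonmetal"], spec.mhc_core_identity, plant.motifs
                )
            elif plant.kind == "lowmotif":
                backbone = strip_motifs(rng, random_protein(rng, 250))
                seq = backbone + "GSG" + motif_block(rng, plant.motifs)
            else:
                raise ConfigError(f"unknown MHC plant kind {plant.kind!r}")
            inv = scan_motifs(ProteinRecord(id=pid, sequence=seq))
            if inv.motif_count != plant.motifs:
                raise DataError(
                    f"{pid}: planted {plant.motifs} motifs, scan found {inv.motif_count}"
                )
            if plant.kind == "metal":
                localizations[pid] = _LOCALIZATION_CYCLE[loc_cycle % 3]
                loc_cycle += 1
                annotations[pid] = "hypothetical protein"
                retained_mhc[pid] = plant.motifs
                status = "retained"
            elif plant.kind == "cytoplasmic":
                localizations[pid] = "Cytoplasmic"
                status = "removed_cytoplasmic"
            elif plant.kind == "annot_denied":
                annotations[pid] = "NrfA"
                localizations[pid] = "Periplasmic"
                status = "removed_annotation"
            elif plant.kind == "nonmetal":
                localizations[pid] = "Periplasmic"
                annotations[pid] = "hypothetical protein"
                status = "removed_cluster"
            else:
                status = "below_threshold"
            mhc_status[pid] = status
            mag_prots.append((pid, seq))
            truth_proteins[pid] = {
                "kind": "mhc", "mhc_kind": plant.kind,
                "motifs": plant.motifs, "status": status,
            }
        if retained_mhc:
            functions.add("MHC")

        for _ in range(mag.n_filler):
            pid = new_id()
            mag_prots.append((pid, strip_motifs(rng, random_protein(rng, 250))))
            truth_proteins[pid] = {"kind": "filler"}

        # --- pack genes onto contigs (reverse translation, forward strand)
        contig_seqs = []
        for ci, clen in enumerate(mag.contig_lengths, 1):
            contig_seqs.append([f"{mag.mag_id}_c{ci}", clen, []])  # id, len, genes
        ci = 0
        cursor = int(rng.integers(50, 150))
        for pid, prot in mag_prots:
            nt = "".join(
                AA_TO_CODONS[aa][rng.integers(len(AA_TO_CODONS[aa]))] for aa in prot
            )
            placed = False
            while ci < len(contig_seqs):
                cid, clen, placed_genes = contig_seqs[ci]
                if cursor + len(nt) - 1 <= clen:
                    placed_genes.append((pid, cursor, nt))
                    cursor += len(nt) + int(rng.integers(50, 150))
                    placed = True
                    break
                ci += 1
                cursor = int(rng.integers(50, 150))
            if not placed:
                raise DataError(
                    f"MAG {mag.mag_id!r}: genes exceed contig capacity "
                    f"(could not place {pid})"
                )
            proteins.append(ProteinRecord(id=pid, sequence=prot, source_mag=mag.mag_id))

        for cid, clen, placed_genes in contig_seqs:
            seq = list(random_nucleotides(rng, clen))
            for pid, start, nt in placed_genes:
                seq[start - 1 : start - 1 + len(nt)] = list(nt)
                genes.append(
                    {"gene_id": pid, "contig_id": cid, "start": start,
                     "end": start + len(nt) - 1}
                )
            contigs.append(
                ContigRecord(id=cid, sequence="".join(seq), source_mag=mag.mag_id)
            )
            mag_of_contig[cid] = mag.mag_id

        # --- marker table
        present, extra = marker_counts_for(
            mag.completeness, mag.contamination, n_markers
        )
        chosen = rng.choice(n_markers, size=present, replace=False)
        row = {spec.marker_universe[i]: 1 for i in sorted(chosen)}
        if extra:
            dups = rng.choice(sorted(chosen), size=extra, replace=True)
            for i in dups:
                row[spec.marker_universe[i]] += 1
        markers[mag.mag_id] = row

        comp = 100.0 * present / n_markers
        cont = 100.0 * extra / n_markers
        if comp > 90 and cont < 5:
            tier = "high"
        elif comp >= 50 and cont < 10:
            tier = "medium"
        else:
            tier = "low"
        truth_mags[mag.mag_id] = {
            "functions": sorted(functions),
            "has_rps3": mag.has_rps3,
            "completeness": comp,
            "contamination": cont,
            "tier": tier,
            "ptr": mag.ptr,
            "retained_mhc": dict(sorted(retained_mhc.items())),
            "mhc_total_motifs": sum(retained_mhc.values()),
            "fig5_flagged": sum(retained_mhc.values()) > 50,
            "eligible_irep": comp >= 75.0 and cont < 3.0,
        }

    medium = [m for m, t in truth_mags.items() if t["tier"] != "low"]
    with_rps3 = [m for m in medium if truth_mags[m]["has_rps3"]]
    analysis = [m for m in with_rps3 if truth_mags[m]["functions"]]
    truth = {
        "seed": spec.seed,
        "samples": list(spec.samples),
        "mags": truth_mags,
        "proteins": truth_proteins,
        "funnel": {
            "total": len(spec.mags),
            "medium_or_better": len(medium),
            "with_rps3": len(with_rps3),
            "analysis": len(analysis),
        },
        "analysis_set": sorted(analysis),
        "eligible_irep": sorted(
            m for m, t in truth_mags.items() if t["eligible_irep"]
        ),
    }
    return GeneratedCommunity(
        refs=refs, proteins=proteins, contigs=contigs, genes=genes,
        mag_of_contig=mag_of_contig, annotations=annotations,
        localizations=localizations, markers=markers, truth=truth,
    )


# ---------------------------------------------------------------------------
# read simulation


def sample_positions(
    rng: np.random.Generator, n: int, ptr: float, total_len: int
) -> np.ndarray:
    """0-based concatenated start coordinates under the PTR gradient.

    Density is proportional to ptr**(1 - x) for normalized position
    x in [0, 1] (origin at x = 0); ptr = 1 gives the uniform law.
    """
    u = rng.random(n)
    if ptr == 1.0:
        x = u
    else:
        # inverse CDF of p^(1-x): F(x) = p (1 - p^-x) / (p - 1)
        x = -np.log(1.0 - u * (ptr - 1.0) / ptr) / np.log(ptr)
    return np.minimum((x * total_len).astype(np.int64), total_len - 1)


def simulate_reads(
    spec: SimulationSpec,
    community: GeneratedCommunity,
    rng: np.random.Generator,
) -> dict[str, list[tuple[str, str, int, str, bool]]]:
    """Pre-mapped reads per sample: (read_id, contig, pos, seq, mapped)."""
    by_mag: dict[str, list[ContigRecord]] = {}
    for c in community.contigs:
        by_mag.setdefault(c.source_mag, []).append(c)
    out: dict[str, list] = {}
    L = spec.read_length
    nts = np.array(list(NUCLEOTIDES))
    for sample in spec.samples:
        records: list[tuple[str, str, int, str, bool]] = []
        ridx = 0
        for mag in spec.mags:
            depth = mag.depths.get(sample, 0.0)
            if depth <= 0:
                continue
            contigs = by_mag[mag.mag_id]
            lengths = np.array([len(c) for c in contigs])
            offsets = np.concatenate(([0], np.cumsum(lengths)))
            total = int(offsets[-1])
            n_reads = int(round(depth * total / L))
            starts = sample_positions(rng, n_reads, mag.ptr, total)
            which = np.searchsorted(offsets, starts, side="right") - 1
            local = starts - offsets[which]
            local = np.minimum(local, lengths[which] - L)
            local = np.maximum(local, 0)
            for t in range(n_reads):
                c = contigs[which[t]]
                pos = int(local[t]) + 1
                seq = c.sequence[pos - 1 : pos - 1 + L]
                err = rng.random(L) < spec.error_rate
                if err.any():
                    arr = np.array(list(seq))
                    arr[err] = nts[rng.integers(0, 4, size=int(err.sum()))]
                    seq = "".join(arr)
                ridx += 1
                records.append((f"{sample}_r{ridx:07d}", c.id, pos, seq, True))
        n_unmapped = int(round(spec.unmapped_frac * len(records)))
        for t in range(n_unmapped):
            records.append(
                (f"{sample}_u{t + 1:06d}", "", 0, random_nucleotides(rng, L), False)
            )
        out[sample] = records
    return out


# ---------------------------------------------------------------------------
# top level


def generate_community(spec: SimulationSpec, outdir: str | Path) -> GeneratedCommunity:
    """Generate and write a full synthetic community under ``outdir``.

    Layout: refs/<family>__<role>.faa, proteins.faa, contigs.fna,
    genes.tsv, mags.tsv, annotations.tsv, localization.tsv, markers.tsv,
    reads_<sample>.sam, truth.json.  Same seed, same bytes.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed)
    community = generate_mags(spec, rng)

    refdir = outdir / "refs"
    refdir.mkdir(exist_ok=True)
    for rs in community.refs:
        write_fasta(refdir / f"{rs.family}__{rs.role}.faa", rs.members)
    write_fasta(outdir / "proteins.faa", community.proteins)
    write_fasta(outdir / "contigs.fna", community.contigs)
    write_tsv(
        outdir / "genes.tsv",
        ["gene_id", "contig", "start", "end"],
        [(g["gene_id"], g["contig_id"], g["start"], g["end"]) for g in community.genes],
    )
    write_tsv(
        outdir / "mags.tsv",
        ["contig_id", "mag_id"],
        sorted(community.mag_of_contig.items()),
    )
    write_tsv(
        outdir / "annotations.tsv",
        ["protein_id", "annotation"],
        sorted(community.annotations.items()),
    )
    write_tsv(
        outdir / "localization.tsv",
        ["protein_id", "localization"],
        sorted(community.localizations.items()),
    )
    write_tsv(
        outdir / "markers.tsv",
        ["mag_id", "marker_id", "copies"],
        [
            (mag, marker, copies)
            for mag in sorted(community.markers)
            for marker, copies in sorted(community.markers[mag].items())
        ],
    )
    reads = simulate_reads(spec, community, rng)
    contig_lengths = {c.id: len(c) for c in community.contigs}
    for sample, records in reads.items():
        write_sam_lite(outdir / f"reads_{sample}.sam", records, contig_lengths)
    with open(outdir / "truth.json", "w") as fh:
        json.dump(community.truth, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return community


def default_spec(seed: int = 20190901) -> SimulationSpec:
    """The package's default synthetic community.

    Six MAGs over two samples exercising every filter: a high-quality
    arsenate reducer rich in multiheme cytochromes, an arsenite oxidizer,
    a sulfate reducer with mixed cytochromes, a NapA-decoy carrier
    without rps3, a function-free MAG, and a low-quality bin.
    """
    contigs = (14000, 8000)
    return SimulationSpec(
        seed=seed,
        samples=("S1", "S2"),
        mags=(
            MagSpec(
                mag_id="MAG1", contig_lengths=contigs,
                functions=("arsB", "arsC", "arrA"), has_rps3=True,
                mhc=(MhcPlant("metal", 18), MhcPlant("metal", 20), MhcPlant("metal", 15)),
                completeness=100.0 * 39 / 43, contamination=100.0 * 1 / 43,
                ptr=2.0, depths={"S1": 30.0, "S2": 15.0},
            ),
            MagSpec(
                mag_id="MAG2", contig_lengths=contigs,
                functions=("arsC", "aioA"), has_rps3=True,
                mhc=(MhcPlant("cytoplasmic", 8), MhcPlant("lowmotif", 2)),
                completeness=100.0 * 36 / 43, contamination=0.0,
                ptr=1.5, depths={"S1": 30.0, "S2": 10.0},
            ),
            MagSpec(
                mag_id="MAG3", contig_lengths=contigs,
                functions=("dsrD",), has_rps3=True,
                mhc=(MhcPlant("metal", 9), MhcPlant("nonmetal", 6), MhcPlant("annot_denied", 5)),
                completeness=100.0 * 33 / 43, contamination=100.0 * 2 / 43,
                ptr=1.8, depths={"S1": 25.0, "S2": 20.0},
            ),
            MagSpec(
                mag_id="MAG4", contig_lengths=contigs,
                functions=("arsB", "napA"), has_rps3=False,
                completeness=100.0 * 40 / 43, contamination=0.0,
                ptr=1.0, depths={"S1": 30.0, "S2": 15.0},
            ),
            MagSpec(
                mag_id="MAG5", contig_lengths=contigs,
                functions=(), has_rps3=True,
                completeness=100.0 * 22 / 43, contamination=100.0 * 3 / 43,
                ptr=1.2, depths={"S1": 20.0, "S2": 20.0},
            ),
            MagSpec(
                mag_id="MAG6", contig_lengths=contigs,
                functions=("arrA",), has_rps3=True,
                completeness=100.0 * 18 / 43, contamination=0.0,
                ptr=1.3, depths={"S1": 15.0, "S2": 15.0},
            ),
        ),
    )
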