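"""Core record types shared by every pipeline stage.

All coordinates in the package are 1-based inclusive on the forward strand,
matching the SAM convention of the only external alignment format consumed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import DataError, TableError

PROTEIN_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYX")
NUCLEOTIDE_ALPHABET = set("ACGTN")

#: PSORTb-style subcellular localization vocabulary.
LOCALIZATIONS = frozenset(
    {
        "Cytoplasmic",
        "CytoplasmicMembrane",
        "Periplasmic",
        "OuterMembrane",
        "Extracellular",
        "Unknown",
    }
)


@dataclass(frozen=True)
class ProteinRecord:
    """A predicted protein, optionally linked to its source MAG and sample.

    The sequence is uppercase over the 20 canonical residues plus ``X``
    (unknown).  Selenocysteine (U) and pyrrolysine (O) are normalised to
    C and K at read time.
    """

    id: str
    sequence: str
    source_mag: str = ""
    source_sample: str = ""

    def __post_init__(self) -> None:
        if not self.sequence:
            raise DataError(f"protein {self.id!r}: empty sequence")
        bad = set(self.sequence) - PROTEIN_ALPHABET
        if bad:
            pos = next(
                i for i, c in enumerate(self.sequence, 1) if c in bad
            )
            raise DataError(
                f"protein {self.id!r}: illegal residue {self.sequence[pos - 1]!r} "
                f"at position {pos}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class ContigRecord:
    """An assembled contig (or MAG scaffold)."""

    id: str
    sequence: str
    source_mag: str = ""

    def __post_init__(self) -> None:
        if not self.sequence:
            raise DataError(f"contig {self.id!r}: empty sequence")
        bad = set(self.sequence) - NUCLEOTIDE_ALPHABET
        if bad:
            pos = next(i for i, c in enumerate(self.sequence, 1) if c in bad)
            raise DataError(
                f"contig {self.id!r}: illegal base {self.sequence[pos - 1]!r} "
                f"at position {pos}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class SamRecordLite:
    """Minimal view of one SAM alignment line.

    Only the fields the pipeline consumes are retained: query name,
    mapped/unmapped state (FLAG bit 0x4), reference contig, 1-based
    leftmost position and read length (taken from SEQ; CIGAR is ignored).
    ``pos`` and ``ref_id`` are undefined for unmapped records.
    """

    read_id: str
    ref_id: str
    pos: int
    read_len: int
    mapped: bool

    def __post_init__(self) -> None:
        if self.mapped and self.pos < 1:
            raise DataError(f"read {self.read_id!r}: mapped with POS {self.pos} < 1")
        if self.read_len <= 0:
            raise DataError(f"read {self.read_id!r}: non-positive read length")


@dataclass
class AnnotationTable:
    """protein id -> free-text functional annotation label."""

    labels: dict[str, str] = field(default_factory=dict)

    def get(self, protein_id: str) -> str | None:
        return self.labels.get(protein_id)

    def __len__(self) -> int:
        return len(self.labels)


@dataclass
class LocalizationTable:
    """protein id -> subcellular localization (PSORTb vocabulary)."""

    localizations: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for pid, loc in self.localizations.items():
            if loc not in LOCALIZATIONS:
                raise TableError(
                    f"protein {pid!r}: unknown localization token {loc!r}"
                )

    def get(self, protein_id: str) -> str:
        return self.localizations.get(protein_id, "Unknown")

    def __len__(self) -> int:
        return len(self.localizations)
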