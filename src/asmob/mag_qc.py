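"""MAG quality estimation from single-copy marker tables.

A light-weight CheckM stand-in: completeness is the percentage of the
marker universe present at least once, contamination the percentage of
extra copies.  Tiers follow MIMAG convention (high: >90% complete and
<5% contaminated; medium: >=50% and <10%).  The analysis set mirrors the
study filter: medium-or-better MAGs with a ribosomal protein S3 (rps3)
hit and at least one function of interest.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .errors import DataError

#: Bundled 43-gene bacterial single-copy marker set (ribosomal proteins
#: and universal housekeeping genes) used when no CheckM table is supplied.
BACTERIAL_MARKERS_43 = (
    "rpl1", "rpl2", "rpl3", "rpl4", "rpl5", "rpl6", "rpl10", "rpl11",
    "rpl13", "rpl14", "rpl15", "rpl16", "rpl18", "rpl22", "rpl24",
    "rps2", "rps3", "rps4", "rps5", "rps7", "rps8", "rps9", "rps10",
    "rps11", "rps12", "rps13", "rps15", "rps17", "rps19",
    "rpoA", "rpoB", "rpoC", "secY", "ffh", "ftsY", "infB", "nusA",
    "pgk", "pheS", "rplS", "serS", "smpB", "tsf",
)

#: Function labels recognised by the analysis-set filter.
FUNCTIONS_OF_INTEREST = ("arsB", "arsC", "arrA", "aioA", "dsrD", "MHC")


@dataclass
class MarkerTable:
    """Per-MAG copy counts over a shared single-copy marker universe."""

    universe: tuple[str, ...]
    copies: dict[str, dict[str, int]]

    def __post_init__(self) -> None:
        if not self.universe:
            raise DataError("marker universe is empty")
        uni = set(self.universe)
        for mag, row in self.copies.items():
            extra = set(row) - uni
            if extra:
                raise DataError(
                    f"MAG {mag!r}: markers {sorted(extra)} outside the universe"
                )

    @classmethod
    def from_long(cls, table: dict[str, dict[str, int]], universe=None) -> "MarkerTable":
        if universe is None:
            universe = tuple(sorted({m for row in table.values() for m in row}))
        return cls(universe=tuple(universe), copies=table)


@dataclass
class MagQuality:
    mag_id: str
    completeness: float
    contamination: float
    tier: str
    has_rps3: bool = False
    functions: set[str] = field(default_factory=set)


def _tier(completeness: float, contamination: float) -> str:
    if completeness > 90.0 and contamination < 5.0:
        return "high"
    if completeness >= 50.0 and contamination < 10.0:
        return "medium"
    return "low"


def quality_from_markers(table: MarkerTable) -> list[MagQuality]:
    """Completeness/contamination/tier per MAG from marker copy counts.

    completeness = 100 * |markers with copy >= 1| / |universe|;
    contamination = 100 * sum(max(0, copy - 1)) / |universe|.
    """
    n = len(table.universe)
    out = []
    for mag in sorted(table.copies):
        row = table.copies[mag]
        present = sum(1 for m in table.universe if row.get(m, 0) >= 1)
        extra = sum(max(0, row.get(m, 0) - 1) for m in table.universe)
        comp = 100.0 * present / n
        cont = 100.0 * extra / n
        out.append(
            MagQuality(
                mag_id=mag, completeness=comp, contamination=cont, tier=_tier(comp, cont)
            )
        )
    return out


def analysis_set(
    qualities: list[MagQuality],
    functions_by_mag: dict[str, set[str]],
    rps3_mags: set[str],
) -> set[str]:
    """MAGs analysed further: tier >= medium, rps3 present, >= 1 function."""
    out = set()
    for q in qualities:
        if q.tier == "low":
            continue
        if q.mag_id not in rps3_mags:
            continue
        if not functions_by_mag.get(q.mag_id):
            continue
        out.add(q.mag_id)
    return out


def function_profile(
    mag_ids: set[str] | list[str],
    functions_by_mag: dict[str, set[str]],
    lineages: dict[str, str] | None = None,
) -> pd.DataFrame:
    """MAG x function boolean matrix (optionally with a lineage column)."""
    mags = sorted(mag_ids)
    data = {
        fn: [fn in functions_by_mag.get(m, set()) for m in mags]
        for fn in FUNCTIONS_OF_INTEREST
    }
    df = pd.DataFrame(data, index=pd.Index(mags, name="mag_id"))
    if lineages:
        df.insert(0, "lineage", [lineages.get(m, "") for m in mags])
    return df
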