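"""Readers and writers for the formats the pipeline touches.

FASTA goes through Biopython; SAM uses a minimal text parser that keeps
only the fields :class:`~asmob.records.SamRecordLite` defines (the files
written here carry proper ``@SQ`` headers, so samtools/pysam read them
too).  Tables are plain TSV with a header row.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Iterable

from Bio import SeqIO

from .errors import FastaError, SamError, TableError
from .records import (
    AnnotationTable,
    ContigRecord,
    LocalizationTable,
    ProteinRecord,
    SamRecordLite,
)

# Residue normalisation applied on read: selenocysteine/pyrrolysine to
# their nearest canonical residue, '*' (stop) stripped at the end only.
_PROTEIN_FIXUPS = str.maketrans({"U": "C", "O": "K"})


def read_fasta(path: str | Path, alphabet: str) -> list[ProteinRecord] | list[ContigRecord]:
    """Read a FASTA file into protein or contig records.

    Parameters
    ----------
    path:
        FASTA file path.
    alphabet:
        ``"protein"`` or ``"nucleotide"``.

    The id is the header token before the first whitespace; sequences are
    uppercased and line wraps joined.  Duplicate ids and illegal characters
    raise :class:`FastaError`.
    """
    if alphabet not in ("protein", "nucleotide"):
        raise ValueError(f"unknown alphabet {alphabet!r}")
    records: list = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FastaError(f"{path}: duplicate sequence id {rec.id!r}")
        seen.add(rec.id)
        seq = str(rec.seq).upper()
        try:
            if alphabet == "protein":
                seq = seq.translate(_PROTEIN_FIXUPS)
                if seq.endswith("*"):
                    seq = seq[:-1]
                records.append(ProteinRecord(id=rec.id, sequence=seq))
            else:
                records.append(ContigRecord(id=rec.id, sequence=seq))
        except Exception as exc:  # re-raise with file context
            raise FastaError(f"{path}: {exc}") from exc
    return records


def write_fasta(path: str | Path, records: Iterable[ProteinRecord | ContigRecord], width: int = 80) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


def read_sam_lite(path: str | Path) -> list[SamRecordLite]:
    """Parse a SAM text file into :class:`SamRecordLite` records.

    Header lines (``@``) are skipped.  FLAG bit 0x4 marks a record
    unmapped; read length is the SEQ field length.  Malformed alignment
    lines raise :class:`SamError` with the offending line number.
    """
    out: list[SamRecordLite] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("@"):
                continue
            fields = line.split("\t")
            if len(fields) < 11:
                raise SamError(
                    f"{path}:{lineno}: alignment line has {len(fields)} fields, expected >= 11"
                )
            qname, flag_s, rname, pos_s = fields[0], fields[1], fields[2], fields[3]
            seq = fields[9]
            try:
                flag = int(flag_s)
                pos = int(pos_s)
            except ValueError:
                raise SamError(f"{path}:{lineno}: non-integer FLAG/POS") from None
            mapped = not (flag & 0x4)
            read_len = len(seq) if seq != "*" else 0
            if read_len == 0:
                raise SamError(f"{path}:{lineno}: SEQ field absent; read length unknown")
            try:
                out.append(
                    SamRecordLite(
                        read_id=qname,
                        ref_id=rname if mapped else "",
                        pos=pos if mapped else 0,
                        read_len=read_len,
                        mapped=mapped,
                    )
                )
            except Exception as exc:
                raise SamError(f"{path}:{lineno}: {exc}") from exc
    return out


def write_sam_lite(
    path: str | Path,
    records: Iterable[tuple[str, str, int, str, bool]],
    contig_lengths: dict[str, int],
) -> None:
    """Write alignment records as standard SAM with ``@SQ`` headers.

    ``records`` yields ``(read_id, ref_id, pos, seq, mapped)`` tuples.
    """
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unsorted\n")
        for cid, length in contig_lengths.items():
            fh.write(f"@SQ\tSN:{cid}\tLN:{length}\n")
        for read_id, ref_id, pos, seq, mapped in records:
            if mapped:
                fh.write(
                    f"{read_id}\t0\t{ref_id}\t{pos}\t60\t{len(seq)}M\t*\t0\t0\t{seq}\t*\n"
                )
            else:
                fh.write(f"{read_id}\t4\t*\t0\t0\t*\t*\t0\t0\t{seq}\t*\n")


def _read_tsv_rows(path: str | Path) -> tuple[list[str], list[list[str]]]:
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        rows = [row for row in reader if row]
    if not rows:
        raise TableError(f"{path}: empty table (missing header)")
    return rows[0], rows[1:]


def read_annotation_table(path: str | Path) -> AnnotationTable:
    """TSV with header; columns: protein_id, annotation."""
    _, body = _read_tsv_rows(path)
    labels: dict[str, str] = {}
    for i, row in enumerate(body, 2):
        if len(row) < 2:
            raise TableError(f"{path}: row {i}: expected 2 columns")
        pid = row[0]
        if pid in labels:
            raise TableError(f"{path}: row {i}: duplicate protein id {pid!r}")
        labels[pid] = row[1]
    return AnnotationTable(labels=labels)


def read_localization_table(path: str | Path) -> LocalizationTable:
    """TSV with header; columns: protein_id, localization (PSORTb vocabulary)."""
    _, body = _read_tsv_rows(path)
    locs: dict[str, str] = {}
    for i, row in enumerate(body, 2):
        if len(row) < 2:
            raise TableError(f"{path}: row {i}: expected 2 columns")
        pid, loc = row[0], row[1]
        if pid in locs:
            raise TableError(f"{path}: row {i}: duplicate protein id {pid!r}")
        try:
            LocalizationTable({pid: loc})
        except TableError:
            raise TableError(
                f"{path}: row {i}: unknown localization token {loc!r}"
            ) from None
        locs[pid] = loc
    return LocalizationTable(localizations=locs)


def read_marker_table(path: str | Path) -> dict[str, dict[str, int]]:
    """Long-form marker copy table: mag_id, marker_id, copies."""
    _, body = _read_tsv_rows(path)
    table: dict[str, dict[str, int]] = {}
    for i, row in enumerate(body, 2):
        if len(row) < 3:
            raise TableError(f"{path}: row {i}: expected 3 columns")
        mag, marker, copies_s = row[0], row[1], row[2]
        try:
            copies = int(copies_s)
        except ValueError:
            raise TableError(f"{path}: row {i}: non-integer copy count") from None
        if copies < 0:
            raise TableError(f"{path}: row {i}: negative copy count")
        table.setdefault(mag, {})[marker] = copies
    return table


def read_mag_assignment(path: str | Path) -> dict[str, str]:
    """Contig-to-MAG assignment table: contig_id, mag_id."""
    _, body = _read_tsv_rows(path)
    out: dict[str, str] = {}
    for i, row in enumerate(body, 2):
        if len(row) < 2:
            raise TableError(f"{path}: row {i}: expected 2 columns")
        if row[0] in out:
            raise TableError(f"{path}: row {i}: duplicate contig id {row[0]!r}")
        out[row[0]] = row[1]
    return out


def read_gene_table(path: str | Path) -> list[dict]:
    """Gene interval table: gene_id, contig, start, end (1-based inclusive)."""
    _, body = _read_tsv_rows(path)
    genes = []
    for i, row in enumerate(body, 2):
        if len(row) < 4:
            raise TableError(f"{path}: row {i}: expected 4 columns")
        try:
            start, end = int(row[2]), int(row[3])
        except ValueError:
            raise TableError(f"{path}: row {i}: non-integer coordinates") from None
        genes.append({"gene_id": row[0], "contig_id": row[1], "start": start, "end": end})
    return genes


def write_tsv(path: str | Path, header: list[str], rows: Iterable[Iterable]) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(header)
        for row in rows:
            writer.writerow(list(row))
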