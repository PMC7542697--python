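"""Sequence-file input and the xlsx antibody-tracking database.

The tracking database is a single-sheet .xlsx file in which each row is
one single cell with a unique ``mab_id``.  Users may add metadata columns
in any order; those columns survive a read/write cycle byte-for-byte.
Annotation and verification results are written into additional columns,
and the expression verdict is rendered both as text and as a cell fill
(green / red / brown).
"""

from __future__ import annotations

import fnmatch
import re
from pathlib import Path

import openpyxl
from Bio import SeqIO
from openpyxl.styles import PatternFill

from igkit.config import ColorConfig
from igkit.model import AntibodyRecord, DatabaseError, SangerRead

MAB_ID_COLUMN = "mab_id"
COMMENT_COLUMN = "comment"
VERDICT_COLUMN = "verdict"


def _read_from_record(record, with_quality: bool) -> SangerRead:
    qualities = None
    if with_quality:
        qualities = list(record.letter_annotations["phred_quality"])
    return SangerRead(read_id=record.id, nucleotides=str(record.seq), qualities=qualities)


def read_sequence_file(path: str | Path) -> list[SangerRead]:
    """Read one FASTA or FASTQ file (format sniffed from the first byte)."""
    path = Path(path)
    with open(path) as fh:
        first = fh.read(1)
    if first == "@":
        fmt, with_quality = "fastq", True
    elif first == ">":
        fmt, with_quality = "fasta", False
    else:
        raise ValueError(f"{path}: not FASTA or FASTQ")
    return [_read_from_record(r, with_quality) for r in SeqIO.parse(str(path), fmt)]


def read_sequences(
    directory: str | Path, pattern: str = "*"
) -> tuple[list[SangerRead], list[tuple[Path, str]]]:
    """Read every FASTA/FASTQ record under ``directory`` matching ``pattern``.

    Unparseable files do not abort the batch: they are reported in the
    second return value as (path, error message) and the remaining files
    are still loaded.
    """
    directory = Path(directory)
    if not directory.is_dir():
        raise FileNotFoundError(f"not a directory: {directory}")
    reads: list[SangerRead] = []
    errors: list[tuple[Path, str]] = []
    for path in sorted(directory.iterdir()):
        if not path.is_file() or not fnmatch.fnmatch(path.name, pattern):
            continue
        try:
            reads.extend(read_sequence_file(path))
        except Exception as exc:  # per-file isolation is the contract
            errors.append((path, str(exc)))
    return reads, errors


def match_reads_to_records(
    directory: str | Path, filename_regex: str
) -> tuple[dict[tuple[str, str], Path], list[tuple[Path, str]]]:
    """Map (mab_id, chain) -> sequence file using the filename convention.

    The default convention is ``<mab_id>_<chain>*`` with chain one of
    heavy/kappa/lambda; the regex is configurable and must expose named
    groups ``mab_id`` and ``chain``.
    """
    directory = Path(directory)
    rx = re.compile(filename_regex)
    mapping: dict[tuple[str, str], Path] = {}
    unmatched: list[tuple[Path, str]] = []
    for path in sorted(directory.iterdir()):
        if not path.is_file():
            continue
        m = rx.match(path.name)
        if not m:
            unmatched.append((path, "filename does not match convention"))
            continue
        key = (m.group("mab_id"), m.group("chain"))
        if key in mapping:
            unmatched.append((path, f"second file for {key}"))
            continue
        mapping[key] = path
    return mapping, unmatched


def read_database(path: str | Path) -> tuple[list[AntibodyRecord], list[str]]:
    """Load the tracking database; returns (records, column order).

    The column list includes every column present in the sheet, in sheet
    order, so that :func:`write_database` can reproduce it exactly.
    """
    wb = openpyxl.load_workbook(str(path))
    ws = wb.active
    rows = ws.iter_rows(values_only=True)
    try:
        header = [str(c) if c is not None else "" for c in next(rows)]
    except StopIteration:
        raise DatabaseError(f"{path}: empty sheet") from None
    if MAB_ID_COLUMN not in header:
        raise DatabaseError(f"{path}: missing required column {MAB_ID_COLUMN!r}")
    id_idx = header.index(MAB_ID_COLUMN)
    records: list[AntibodyRecord] = []
    seen: dict[str, int] = {}
    for row in rows:
        if row is None or all(c is None for c in row):
            continue
        values = ["" if c is None else str(c) for c in row]
        values += [""] * (len(header) - len(values))
        mab_id = values[id_idx]
        seen[mab_id] = seen.get(mab_id, 0) + 1
        metadata = {col: values[i] for i, col in enumerate(header) if col != MAB_ID_COLUMN}
        verdict_color = metadata.pop("verdict_color", "") or None
        comment = metadata.get(COMMENT_COLUMN, "")
        records.append(
            AntibodyRecord(
                mab_id=mab_id, metadata=metadata, comment=comment, verdict_color=verdict_color
            )
        )
    duplicates = sorted(mab_id for mab_id, n in seen.items() if n > 1)
    if duplicates:
        raise DatabaseError(f"duplicate mab_id value(s): {', '.join(duplicates)}")
    wb.close()
    return records, header


def write_database(
    records: list[AntibodyRecord],
    path: str | Path,
    columns: list[str] | None = None,
    colors: ColorConfig | None = None,
) -> None:
    """Write records to .xlsx, preserving column order and applying verdict fills.

    ``columns`` fixes the output order (typically the order returned by
    :func:`read_database`); columns present in any record but absent from
    the list are appended at the end, so annotation columns added by the
    pipeline show up after the user's own columns.
    """
    colors = colors or ColorConfig()
    ordered: list[str] = list(columns) if columns else [MAB_ID_COLUMN]
    if MAB_ID_COLUMN not in ordered:
        raise DatabaseError(f"column list lacks {MAB_ID_COLUMN!r}")
    for record in records:
        for col in record.metadata:
            if col not in ordered:
                ordered.append(col)
        if record.comment and COMMENT_COLUMN not in ordered:
            ordered.append(COMMENT_COLUMN)
        if record.verdict_color and "verdict_color" not in ordered:
            ordered.append("verdict_color")

    fills = {
        "green": PatternFill(start_color=colors.green, end_color=colors.green, fill_type="solid"),
        "red": PatternFill(start_color=colors.red, end_color=colors.red, fill_type="solid"),
        "brown": PatternFill(start_color=colors.brown, end_color=colors.brown, fill_type="solid"),
    }

    wb = openpyxl.Workbook()
    ws = wb.active
    ws.title = "records"
    for j, col in enumerate(ordered, start=1):
        if col != "":
            cell = ws.cell(row=1, column=j)
            cell.value = col
            cell.data_type = "s"
    for i, record in enumerate(records, start=2):
        for j, col in enumerate(ordered, start=1):
            if col == MAB_ID_COLUMN:
                value = record.mab_id
            elif col == COMMENT_COLUMN:
                value = record.metadata.get(col, "") or record.comment
            elif col == "verdict_color":
                value = record.verdict_color or ""
            else:
                value = record.metadata.get(col, "")
            cell = ws.cell(row=i, column=j)
            if value != "":
                # Explicit string type: user metadata must round-trip verbatim,
                # never be reinterpreted as a number, date or formula.
                cell.value = value
                cell.data_type = "s"
            if col in (VERDICT_COLUMN, "verdict_color") and record.verdict_color:
                cell.fill = fills[record.verdict_color]
    wb.save(str(path))
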