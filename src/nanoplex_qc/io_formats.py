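"""Readers and writers for the external formats the pipeline touches.

Internal coordinates are uniformly 0-based half-open.  PAF query intervals are
already in that convention and are kept as-is; Tandem Repeats Finder ``.dat``
rows are 1-based inclusive and are shifted on ingest.  A single convention
everywhere prevents off-by-one errors in downstream interval merging.

Supported formats:

* ONT ``sequencing_summary.txt`` dialect (tab-separated; columns ``read_id``,
  ``channel``, ``sequence_length_template``, ``mean_qscore_template``, and
  optionally ``passes_filtering`` and ``barcode_arrangement``);
* PAF as emitted by minimap2 (12 mandatory columns plus optional SAM-style
  tags such as ``tp:A:P``);
* TRF ``.dat`` reports (``Sequence:`` headers followed by whitespace-separated
  repeat rows starting ``start end period copy_number``);
* plain FASTA/FASTQ writing for the synthetic-run generator.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from .errors import DataError, FormatError

#: Sentinel barcode label for reads the demultiplexer could not classify.
UNCLASSIFIED = "unclassified"

#: Mean per-read Phred-like quality separating pass from fail reads.
PASS_QSCORE_THRESHOLD = 7.0

#: Number of sensing channels on a MinION flow cell.
DEFAULT_N_CHANNELS = 512

# Canonical ONT summary column names.
_COL_READ_ID = "read_id"
_COL_CHANNEL = "channel"
_COL_LENGTH = "sequence_length_template"
_COL_QSCORE = "mean_qscore_template"
_COL_PASS = "passes_filtering"
_COL_BARCODE = "barcode_arrangement"

_MANDATORY_SUMMARY_COLS = (_COL_READ_ID, _COL_CHANNEL, _COL_LENGTH, _COL_QSCORE)


@dataclass(frozen=True)
class ReadRecord:
    """Per-read metadata from a sequencing summary.

    ``barcode`` is either a barcode label (``barcode01`` ...) or the
    :data:`UNCLASSIFIED` sentinel.  ``extra`` preserves unknown summary columns
    as opaque strings; they are re-emitted on write but never interpreted.
    """

    read_id: str
    length: int
    mean_qscore: float
    channel: int
    passes_filtering: bool
    barcode: str = UNCLASSIFIED
    library: str = ""
    extra: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.length < 0:
            raise DataError(f"read {self.read_id}: negative length {self.length}")
        if self.channel < 1:
            raise DataError(f"read {self.read_id}: channel {self.channel} < 1")


@dataclass(frozen=True)
class AlignmentRecord:
    """One PAF row: a read-vs-replicon alignment.

    ``q_start``/``q_end`` are the query interval (0-based half-open);
    ``matched_bases`` is the PAF residue-matches column and ``block_length``
    the alignment-block-length column, so ``matched_bases / block_length`` is
    the alignment's identity.
    """

    read_id: str
    read_length: int
    q_start: int
    q_end: int
    target_id: str
    matched_bases: int
    block_length: int
    mapq: int
    is_primary: bool = True

    def __post_init__(self) -> None:
        if not (0 <= self.q_start < self.q_end <= self.read_length):
            raise FormatError(
                f"alignment {self.read_id}: bad query interval "
                f"[{self.q_start}, {self.q_end}) on length {self.read_length}"
            )
        if self.matched_bases > self.block_length:
            raise FormatError(
                f"alignment {self.read_id}: matched_bases {self.matched_bases} "
                f"> block_length {self.block_length}"
            )
        if not (0 <= self.mapq <= 255):
            raise FormatError(f"alignment {self.read_id}: mapq {self.mapq} out of range")


@dataclass(frozen=True)
class TandemInterval:
    """One detected tandem stretch on a read, 0-based half-open."""

    read_id: str
    start: int
    end: int
    period: int
    copy_number: float

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise FormatError(
                f"tandem on {self.read_id}: bad interval [{self.start}, {self.end})"
            )
        if self.end - self.start < self.period:
            raise FormatError(
                f"tandem on {self.read_id}: span {self.end - self.start} "
                f"shorter than period {self.period}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start


_TRUE_STRINGS = {"true", "t", "1", "yes", "pass"}
_FALSE_STRINGS = {"false", "f", "0", "no", "fail"}


def _parse_bool(text: str, line_no: int) -> bool:
    low = text.strip().lower()
    if low in _TRUE_STRINGS:
        return True
    if low in _FALSE_STRINGS:
        return False
    raise FormatError(f"line {line_no}: cannot parse boolean value {text!r}")


def read_sequencing_summary(
    path: str | Path,
    library: str = "",
    n_channels: int = DEFAULT_N_CHANNELS,
) -> list[ReadRecord]:
    """Parse an ONT sequencing-summary TSV into :class:`ReadRecord` objects.

    A missing ``barcode_arrangement`` column marks every read as
    :data:`UNCLASSIFIED` (the run was not multiplexed).  A missing
    ``passes_filtering`` column is recomputed as
    ``mean_qscore >= PASS_QSCORE_THRESHOLD``; when the column is present the
    file's own flag wins, as the basecaller's classification is authoritative.
    """
    path = Path(path)
    records: list[ReadRecord] = []
    with path.open(newline="") as handle:
        reader = csv.reader(handle, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise FormatError(f"{path}: empty file, no header") from None
        index = {name: i for i, name in enumerate(header)}
        for col in _MANDATORY_SUMMARY_COLS:
            if col not in index:
                raise FormatError(f"{path}: missing mandatory column {col!r}")
        known = {_COL_READ_ID, _COL_CHANNEL, _COL_LENGTH, _COL_QSCORE, _COL_PASS, _COL_BARCODE}
        extra_cols = [c for c in header if c not in known]
        for line_no, row in enumerate(reader, start=2):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) < len(header):
                raise FormatError(f"{path}: line {line_no}: expected {len(header)} fields")
            try:
                length = int(row[index[_COL_LENGTH]])
            except ValueError:
                raise FormatError(
                    f"{path}: line {line_no}: non-numeric length "
                    f"{row[index[_COL_LENGTH]]!r}"
                ) from None
            try:
                qscore = float(row[index[_COL_QSCORE]])
            except ValueError:
                raise FormatError(
                    f"{path}: line {line_no}: non-numeric mean quality "
                    f"{row[index[_COL_QSCORE]]!r}"
                ) from None
            try:
                channel = int(row[index[_COL_CHANNEL]])
            except ValueError:
                raise FormatError(
                    f"{path}: line {line_no}: non-numeric channel "
                    f"{row[index[_COL_CHANNEL]]!r}"
                ) from None
            if not (1 <= channel <= n_channels):
                raise DataError(
                    f"{path}: line {line_no}: channel {channel} outside [1, {n_channels}]"
                )
            if _COL_PASS in index:
                passes = _parse_bool(row[index[_COL_PASS]], line_no)
            else:
                passes = qscore >= PASS_QSCORE_THRESHOLD
            barcode = row[index[_COL_BARCODE]] if _COL_BARCODE in index else UNCLASSIFIED
            extra = {c: row[index[c]] for c in extra_cols}
            records.append(
                ReadRecord(
                    read_id=row[index[_COL_READ_ID]],
                    length=length,
                    mean_qscore=qscore,
                    channel=channel,
                    passes_filtering=passes,
                    barcode=barcode or UNCLASSIFIED,
                    library=library,
                    extra=extra,
                )
            )
    return records


def write_sequencing_summary(records: Iterable[ReadRecord], path: str | Path) -> None:
    """Write records back to the summary TSV dialect (round-trip safe)."""
    records = list(records)
    extra_cols: list[str] = []
    for rec in records:
        for c in rec.extra:
            if c not in extra_cols:
                extra_cols.append(c)
    header = [_COL_READ_ID, _COL_CHANNEL, _COL_LENGTH, _COL_QSCORE, _COL_PASS, _COL_BARCODE]
    header += extra_cols
    with Path(path).open("w", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(header)
        for rec in records:
            row = [
                rec.read_id,
                str(rec.channel),
                str(rec.length),
                repr(rec.mean_qscore),
                "TRUE" if rec.passes_filtering else "FALSE",
                rec.barcode,
            ]
            row += [rec.extra.get(c, "") for c in extra_cols]
            writer.writerow(row)


def read_paf(path: str | Path) -> list[AlignmentRecord]:
    """Parse a PAF file (12+ mandatory columns) into alignment records.

    An alignment is primary when a ``tp:A:P`` tag is present or when no
    ``tp`` tag exists at all (bare 12-column PAF).
    """
    path = Path(path)
    records: list[AlignmentRecord] = []
    with path.open() as handle:
        for line_no, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            cols = line.split("\t")
            if len(cols) < 12:
                raise FormatError(
                    f"{path}: line {line_no}: PAF needs >= 12 columns, got {len(cols)}"
                )
            try:
                read_length = int(cols[1])
                q_start = int(cols[2])
                q_end = int(cols[3])
                matched = int(cols[9])
                block = int(cols[10])
                mapq = int(cols[11])
            except ValueError:
                raise FormatError(f"{path}: line {line_no}: non-numeric PAF field") from None
            if q_end < q_start:
                raise FormatError(
                    f"{path}: line {line_no}: query end {q_end} < start {q_start}"
                )
            is_primary = True
            for tag in cols[12:]:
                if tag.startswith("tp:A:"):
                    is_primary = tag == "tp:A:P"
                    break
            try:
                rec = AlignmentRecord(
                    read_id=cols[0],
                    read_length=read_length,
                    q_start=q_start,
                    q_end=q_end,
                    target_id=cols[5],
                    matched_bases=matched,
                    block_length=block,
                    mapq=mapq,
                    is_primary=is_primary,
                )
            except FormatError as exc:
                raise FormatError(f"{path}: line {line_no}: {exc}") from None
            records.append(rec)
    return records


def write_paf(records: Iterable[AlignmentRecord], path: str | Path) -> None:
    """Write alignment records as minimal PAF (strand '+', dummy target span)."""
    with Path(path).open("w") as handle:
        for rec in records:
            span = rec.q_end - rec.q_start
            tag = "tp:A:P" if rec.is_primary else "tp:A:S"
            handle.write(
                "\t".join(
                    [
                        rec.read_id,
                        str(rec.read_length),
                        str(rec.q_start),
                        str(rec.q_end),
                        "+",
                        rec.target_id,
                        str(span),
                        "0",
                        str(span),
                        str(rec.matched_bases),
                        str(rec.block_length),
                        str(rec.mapq),
                        tag,
                    ]
                )
                + "\n"
            )


def _looks_like_repeat_row(tokens: list[str]) -> bool:
    if len(tokens) < 4:
        return False
    try:
        int(tokens[0])
        int(tokens[1])
        int(tokens[2])
        float(tokens[3])
    except ValueError:
        return False
    return True


def read_trf_dat(path: str | Path) -> list[TandemInterval]:
    """Parse a Tandem Repeats Finder ``.dat`` report.

    Repeat rows are 1-based inclusive; they are converted to 0-based
    half-open on ingest, so ``end - start`` equals the inclusive row length
    ``end1 - start1 + 1``.  Non-numeric preamble lines (program banner,
    parameter echo) are ignored; a numeric repeat row appearing before any
    ``Sequence:`` header is a format error.
    """
    path = Path(path)
    intervals: list[TandemInterval] = []
    current_id: str | None = None
    with path.open() as handle:
        for line_no, line in enumerate(handle, start=1):
            stripped = line.strip()
            if not stripped:
                continue
            if stripped.startswith("Sequence:"):
                current_id = stripped[len("Sequence:") :].strip().split()[0]
                continue
            tokens = stripped.split()
            if not _looks_like_repeat_row(tokens):
                continue  # banner / parameter line
            if current_id is None:
                raise FormatError(
                    f"{path}: line {line_no}: repeat row before any 'Sequence:' header"
                )
            start1 = int(tokens[0])
            end1 = int(tokens[1])
            period = int(tokens[2])
            copies = float(tokens[3])
            intervals.append(
                TandemInterval(
                    read_id=current_id,
                    start=start1 - 1,
                    end=end1,
                    period=period,
                    copy_number=copies,
                )
            )
    return intervals


def write_fasta(sequences: Iterable[tuple[str, str]], path: str | Path, width: int = 80) -> None:
    with Path(path).open("w") as handle:
        for name, seq in sequences:
            handle.write(f">{name}\n")
            for i in range(0, len(seq), width):
                handle.write(seq[i : i + width] + "\n")


def write_fastq(reads: Iterable[tuple[str, str, str]], path: str | Path) -> None:
    with Path(path).open("w") as handle:
        for name, seq, qual in reads:
            handle.write(f"@{name}\n{seq}\n+\n{qual}\n")
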