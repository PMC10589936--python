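"""Planted fixtures reproducing published run-table cells at desk scale.

The flow-cell-scale statistics this pipeline reports were established on runs
of millions of reads.  To exercise the summary operations against those
printed numbers without any download, this module builds minimal synthetic
:class:`~nanoplex_qc.classify.ReadAttributes` collections whose category
counts and cumulative lengths equal a registered table's cells after a stated
down-scaling (default 1 fixture read = 10,000 real reads).  Applying the
summary operations and multiplying back by the scale reproduces the printed
cells exactly under the M/Gbp rounding contract.

Registered tables:

* ``table3`` — flow-cell output and tandem content per library strategy
  (mapped / unmapped / all read counts in M, cumulative read and tandem
  lengths in Gbp);
* ``table6`` — classified-read content (correct / leaked / unmapped counts
  in M and cumulative lengths in Gbp).
"""

from __future__ import annotations

from dataclasses import dataclass

from .classify import Assignment, ReadAttributes
from .errors import ConfigError
from .io_formats import DEFAULT_N_CHANNELS

__all__ = ["plant_table_fixture", "TABLE3", "TABLE6", "DEFAULT_SCALE"]

#: Real reads represented by one fixture read.
DEFAULT_SCALE = 10_000


@dataclass(frozen=True)
class _Table3Row:
    # read counts in M, lengths in Gbp
    mapped_reads: float
    unmapped_reads: float
    mapped_bp: float
    unmapped_bp: float
    tandem_mapped_reads: float
    tandem_unmapped_reads: float
    tandem_mapped_bp: float
    tandem_unmapped_bp: float


@dataclass(frozen=True)
class _Table6Row:
    correct_reads: float
    leaked_reads: float
    unmapped_reads: float
    correct_bp: float
    leaked_bp: float
    unmapped_bp: float


TABLE3: dict[str, _Table3Row] = {
    "LIG": _Table3Row(6.06, 0.46, 33.62, 1.52, 1.09, 0.14, 0.29, 0.03),
    "PCR": _Table3Row(1.57, 5.34, 4.79, 2.47, 0.54, 3.79, 0.22, 1.41),
    "TAG": _Table3Row(1.88, 0.27, 11.72, 0.68, 0.51, 0.09, 0.20, 0.08),
}

TABLE6: dict[str, _Table6Row] = {
    "PCR": _Table6Row(1.13, 0.07, 4.27, 3.16, 0.26, 1.48),
    "TAG": _Table6Row(1.61, 0.02, 0.07, 9.98, 0.07, 0.02),
}


def _scaled_count(reads_in_m: float, scale: int) -> int:
    return int(round(reads_in_m * 1e6 / scale))


def _scaled_bp(gbp: float, scale: int) -> int:
    return int(round(gbp * 1e9 / scale))


def _distribute(total: int, n: int) -> list[int]:
    """Split ``total`` into ``n`` near-equal non-negative integers."""
    if n <= 0:
        return []
    base, rem = divmod(total, n)
    return [base + (1 if i < rem else 0) for i in range(n)]


def _make_rows(
    library: str,
    n: int,
    total_bp: int,
    n_tandem: int,
    tandem_bp: int,
    mapped: bool,
    assignment: Assignment,
    barcode: str,
    target: str | None,
    start_index: int,
) -> list[ReadAttributes]:
    lengths = _distribute(total_bp, n)
    tandems = _distribute(tandem_bp, n_tandem) + [0] * (n - n_tandem)
    rows = []
    for i, (length, tandem) in enumerate(zip(lengths, tandems)):
        if tandem > length:
            raise ConfigError(
                f"planted fixture {library}: tandem {tandem} exceeds read length {length}"
            )
        idx = start_index + i
        rows.append(
            ReadAttributes(
                read_id=f"{library}_planted_{idx:06d}",
                length=length,
                mean_qscore=10.0,
                channel=(idx % DEFAULT_N_CHANNELS) + 1,
                passes_filtering=True,
                barcode=barcode,
                library=library,
                mapped=mapped,
                mapped_target=target if mapped else None,
                matched_length=length if mapped else 0,
                percent_identity=100.0 if mapped else None,
                query_coverage=100.0 if mapped else None,
                assignment=assignment,
                total_tandem_length=tandem,
            )
        )
    return rows


def plant_table_fixture(
    table: str,
    library: str,
    scale: int = DEFAULT_SCALE,
) -> list[ReadAttributes]:
    """Build synthesis rows whose aggregate equals a registered table row.

    ``scale`` is the number of real reads (and bp) one fixture read stands
    for; cells are converted with round-to-nearest, so a large enough scale
    yields an empty collection.  Summary operations applied to the result and
    multiplied back by ``scale`` reproduce the printed cells after M/Gbp
    rounding.
    """
    if table == "table3":
        try:
            cells = TABLE3[library]
        except KeyError:
            raise ConfigError(f"no table3 row registered for library {library!r}") from None
        rows = _make_rows(
            library,
            _scaled_count(cells.mapped_reads, scale),
            _scaled_bp(cells.mapped_bp, scale),
            _scaled_count(cells.tandem_mapped_reads, scale),
            _scaled_bp(cells.tandem_mapped_bp, scale),
            mapped=True,
            assignment=Assignment.CORRECT,
            barcode="barcode01",
            target="genome01",
            start_index=0,
        )
        rows += _make_rows(
            library,
            _scaled_count(cells.unmapped_reads, scale),
            _scaled_bp(cells.unmapped_bp, scale),
            _scaled_count(cells.tandem_unmapped_reads, scale),
            _scaled_bp(cells.tandem_unmapped_bp, scale),
            mapped=False,
            assignment=Assignment.UNMAPPED,
            barcode="barcode01",
            target=None,
            start_index=len(rows),
        )
        return rows
    if table == "table6":
        try:
            cells6 = TABLE6[library]
        except KeyError:
            raise ConfigError(f"no table6 row registered for library {library!r}") from None
        rows = _make_rows(
            library,
            _scaled_count(cells6.correct_reads, scale),
            _scaled_bp(cells6.correct_bp, scale),
            0,
            0,
            mapped=True,
            assignment=Assignment.CORRECT,
            barcode="barcode01",
            target="genome01",
            start_index=0,
        )
        rows += _make_rows(
            library,
            _scaled_count(cells6.leaked_reads, scale),
            _scaled_bp(cells6.leaked_bp, scale),
            0,
            0,
            mapped=True,
            assignment=Assignment.LEAKED,
            barcode="barcode01",
            target="genome02",
            start_index=len(rows),
        )
        rows += _make_rows(
            library,
            _scaled_count(cells6.unmapped_reads, scale),
            _scaled_bp(cells6.unmapped_bp, scale),
            0,
            0,
            mapped=False,
            assignment=Assignment.UNMAPPED,
            barcode="barcode01",
            target=None,
            start_index=len(rows),
        )
        return rows
    raise ConfigError(f"unknown planted table {table!r} (expected 'table3' or 'table6')")
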