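"""Mapping-based read categorisation and barcode-leakage calls.

Each read of a multiplexed run carries two independent labels: the barcode the
demultiplexer called (or the ``unclassified`` sentinel) and the genome its
best alignment hits (or none).  Crossing the two yields the run's read
categories:

* ``CORRECT`` — classified, and the barcode's genome matches the mapped genome;
* ``LEAKED`` — classified, but mapped to a different sample's genome
  (barcode leakage / index hopping);
* ``UNMAPPED`` — classified but aligning to no reference (noise proxy);
* ``UNCLASSIFIED_MAPPED`` / ``UNCLASSIFIED_UNMAPPED`` — no barcode called.

One alignment defines a read's taxonomy: the best primary alignment by matched
bases, with deterministic tie-breaks, mirroring a one-taxonomy-per-read
summary step.  A stringent sorting filter (length / identity / query-coverage
thresholds) selects high-confidence mapped reads for reassembly use.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, ContractError, DataError, ValidationError
from .io_formats import UNCLASSIFIED, AlignmentRecord, ReadRecord

__all__ = [
    "Assignment",
    "BarcodeGenomeMap",
    "ReadAttributes",
    "select_best_alignment",
    "percent_identity",
    "query_coverage",
    "classify_read",
    "stringent_filter",
    "build_synthesis",
    "synthesis_frame",
    "ambiguous_reads",
]


class Assignment(str, Enum):
    """Read category from crossing barcode identity with mapped taxonomy."""

    CORRECT = "CORRECT"
    LEAKED = "LEAKED"
    UNMAPPED = "UNMAPPED"
    UNCLASSIFIED_MAPPED = "UNCLASSIFIED_MAPPED"
    UNCLASSIFIED_UNMAPPED = "UNCLASSIFIED_UNMAPPED"

    def __str__(self) -> str:  # plain value in TSV output
        return self.value


@dataclass(frozen=True)
class BarcodeGenomeMap:
    """Mapping from barcode label to the genome/strain it tags."""

    entries: Mapping[str, str]

    def __post_init__(self) -> None:
        if UNCLASSIFIED in self.entries:
            raise ConfigError(f"{UNCLASSIFIED!r} cannot be a barcode map key")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "BarcodeGenomeMap":
        """Read a 2-column barcode<TAB>genome table (no header required)."""
        entries: dict[str, str] = {}
        with Path(path).open(newline="") as handle:
            for line_no, row in enumerate(csv.reader(handle, delimiter="\t"), start=1):
                if not row or row[0].startswith("#"):
                    continue
                if row[0] == "barcode" and line_no == 1:
                    continue  # optional header
                if len(row) < 2:
                    raise ConfigError(f"{path}: line {line_no}: need 2 columns")
                if row[0] in entries:
                    raise ConfigError(f"{path}: duplicate barcode {row[0]!r}")
                entries[row[0]] = row[1]
        return cls(entries=entries)

    def to_tsv(self, path: str | Path) -> None:
        with Path(path).open("w") as handle:
            for barcode, genome in self.entries.items():
                handle.write(f"{barcode}\t{genome}\n")

    def genome_for(self, barcode: str) -> str:
        try:
            return self.entries[barcode]
        except KeyError:
            raise ConfigError(f"barcode {barcode!r} absent from barcode->genome map") from None

    def barcode_for(self, genome: str) -> str:
        for barcode, g in self.entries.items():
            if g == genome:
                return barcode
        raise ConfigError(f"genome {genome!r} has no barcode in the map")


@dataclass(frozen=True)
class ReadAttributes:
    """The joined per-read synthesis row: metadata plus category labels."""

    read_id: str
    length: int
    mean_qscore: float
    channel: int
    passes_filtering: bool
    barcode: str
    library: str
    mapped: bool
    mapped_target: str | None
    matched_length: int
    percent_identity: float | None
    query_coverage: float | None
    assignment: Assignment
    total_tandem_length: int = 0

    def __post_init__(self) -> None:
        if not self.mapped and (self.matched_length != 0 or self.mapped_target is not None):
            raise DataError(f"read {self.read_id}: unmapped but carries alignment fields")

    @property
    def classified(self) -> bool:
        return self.barcode != UNCLASSIFIED


def percent_identity(a: AlignmentRecord) -> float:
    """Alignment identity: 100 * matched_bases / block_length (BLAST-like)."""
    if a.block_length <= 0:
        raise DataError(f"alignment {a.read_id}: zero block length, identity undefined")
    return 100.0 * a.matched_bases / a.block_length


def query_coverage(a: AlignmentRecord) -> float:
    """Fraction of the read covered by the alignment's query span, in %."""
    if a.read_length <= 0:
        raise DataError(f"alignment {a.read_id}: zero read length, coverage undefined")
    return 100.0 * (a.q_end - a.q_start) / a.read_length


def select_best_alignment(
    alignments: Sequence[AlignmentRecord],
) -> AlignmentRecord | None:
    """Pick the single alignment that defines a read's taxonomy.

    Primary alignments are preferred over secondary ones; among candidates the
    maximal ``matched_bases`` wins, ties broken by higher identity, then by
    lexicographically smallest target — a total order, so the result is
    invariant under permutation of the input.
    """
    if not alignments:
        return None
    ids = {a.read_id for a in alignments}
    if len(ids) > 1:
        raise ContractError(f"alignments from multiple reads: {sorted(ids)}")
    return min(
        alignments,
        key=lambda a: (
            not a.is_primary,
            -a.matched_bases,
            -percent_identity(a) if a.block_length > 0 else 0.0,
            a.target_id,
        ),
    )


def classify_read(
    record: ReadRecord,
    best: AlignmentRecord | None,
    barcode_map: BarcodeGenomeMap,
    total_tandem_length: int = 0,
) -> ReadAttributes:
    """Assign the category label crossing barcode identity and mapped taxonomy."""
    if best is not None and best.read_id != record.read_id:
        raise ContractError(
            f"alignment {best.read_id!r} does not belong to read {record.read_id!r}"
        )
    mapped = best is not None
    if not mapped:
        target = None
        matched = 0
        identity = None
        coverage = None
        assignment = (
            Assignment.UNCLASSIFIED_UNMAPPED
            if record.barcode == UNCLASSIFIED
            else Assignment.UNMAPPED
        )
    else:
        assert best is not None
        target = best.target_id
        matched = best.matched_bases
        identity = percent_identity(best)
        coverage = query_coverage(best)
        if record.barcode == UNCLASSIFIED:
            assignment = Assignment.UNCLASSIFIED_MAPPED
        else:
            expected = barcode_map.genome_for(record.barcode)
            assignment = Assignment.CORRECT if expected == target else Assignment.LEAKED
    return ReadAttributes(
        read_id=record.read_id,
        length=record.length,
        mean_qscore=record.mean_qscore,
        channel=record.channel,
        passes_filtering=record.passes_filtering,
        barcode=record.barcode,
        library=record.library,
        mapped=mapped,
        mapped_target=target,
        matched_length=matched,
        percent_identity=identity,
        query_coverage=coverage,
        assignment=assignment,
        total_tandem_length=total_tandem_length,
    )


def stringent_filter(
    rows: Iterable[ReadAttributes],
    min_len: int = 5000,
    min_identity: float = 95.0,
    min_cover: float = 80.0,
) -> list[ReadAttributes]:
    """Stringent read sorting: long, high-identity, well-covered mapped reads.

    Thresholds are inclusive (>=), matching the flag semantics of the
    filtering tools this mirrors.  Unmapped reads are always dropped.
    """
    kept: list[ReadAttributes] = []
    for row in rows:
        if not row.mapped:
            continue
        if row.percent_identity is None or row.query_coverage is None:
            continue
        if (
            row.length >= min_len
            and row.percent_identity >= min_identity
            and row.query_coverage >= min_cover
        ):
            kept.append(row)
    return kept


def build_synthesis(
    reads: Sequence[ReadRecord],
    alignments: Iterable[AlignmentRecord],
    barcode_map: BarcodeGenomeMap,
    tandem_lengths: Mapping[str, int] | None = None,
) -> list[ReadAttributes]:
    """Join summary records, alignments and tandem totals into synthesis rows.

    The sequencing summary defines the read universe: an alignment whose read
    id is absent from the summary is a cross-file inconsistency and raises a
    :class:`ValidationError`; a summary read with no alignment is simply
    unmapped.
    """
    tandem_lengths = tandem_lengths or {}
    known = {r.read_id for r in reads}
    by_read: dict[str, list[AlignmentRecord]] = {}
    unknown: list[str] = []
    for aln in alignments:
        if aln.read_id not in known:
            if aln.read_id not in unknown:
                unknown.append(aln.read_id)
            continue
        by_read.setdefault(aln.read_id, []).append(aln)
    if unknown:
        sample = ", ".join(unknown[:5])
        raise ValidationError(
            f"{len(unknown)} aligned read id(s) absent from the sequencing summary "
            f"(e.g. {sample})"
        )
    rows = []
    for rec in reads:
        best = select_best_alignment(by_read.get(rec.read_id, []))
        rows.append(
            classify_read(rec, best, barcode_map, tandem_lengths.get(rec.read_id, 0))
        )
    return rows


def synthesis_frame(rows: Iterable[ReadAttributes]) -> pd.DataFrame:
    """Tabular view of synthesis rows (one row per read)."""
    frame = pd.DataFrame(
        {
            "read_id": r.read_id,
            "library": r.library,
            "length": r.length,
            "mean_qscore": r.mean_qscore,
            "channel": r.channel,
            "passes_filtering": r.passes_filtering,
            "barcode": r.barcode,
            "mapped": r.mapped,
            "mapped_target": r.mapped_target if r.mapped_target is not None else "",
            "matched_length": r.matched_length,
            "percent_identity": r.percent_identity,
            "query_coverage": r.query_coverage,
            "assignment": str(r.assignment),
            "total_tandem_length": r.total_tandem_length,
        }
        for r in rows
    )
    # unmapped reads leave identity/coverage undefined; keep columns numeric
    for col in ("percent_identity", "query_coverage"):
        if col in frame:
            frame[col] = pd.to_numeric(frame[col].where(frame[col].notna(), np.nan))
    return frame


def ambiguous_reads(
    alignments: Iterable[AlignmentRecord],
    margin: int = 0,
) -> list[tuple[str, str, str, int]]:
    """Reads whose top two targets differ by less than ``margin`` matched bases.

    Surfaces near-tie taxonomy calls (e.g. two closely related strains whose
    chromosomes share most of their identity); with the default margin 0 the
    report is empty.  Returns tuples ``(read_id, best_target, runner_up,
    matched_difference)``.
    """
    by_read: dict[str, list[AlignmentRecord]] = {}
    for aln in alignments:
        by_read.setdefault(aln.read_id, []).append(aln)
    report = []
    for read_id, alns in sorted(by_read.items()):
        best_per_target: dict[str, int] = {}
        for a in alns:
            prev = best_per_target.get(a.target_id)
            if prev is None or a.matched_bases > prev:
                best_per_target[a.target_id] = a.matched_bases
        if len(best_per_target) < 2:
            continue
        ranked = sorted(best_per_target.items(), key=lambda kv: (-kv[1], kv[0]))
        diff = ranked[0][1] - ranked[1][1]
        if diff < margin:
            report.append((read_id, ranked[0][0], ranked[1][0], diff))
    return report
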