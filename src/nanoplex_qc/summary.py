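"""Aggregate per-read synthesis rows into run-level reporting tables.

Four views are produced:

* flow-cell totals per library — read counts and cumulative lengths split by
  mapped/unmapped, plus tandem content (reads carrying tandems and cumulative
  tandem length);
* per-channel output — the same totals per sensing channel, summarised as
  mean +/- standard deviation over active channels to gauge run homogeneity;
* read-property distributions — mean and maximum of read length, matched
  length (mapped reads only), tandem length and mean Qscore;
* classified-read content — correctly assigned vs leaked vs unmapped among
  reads with a called barcode.

Reporting units: M = 1e6 reads, Gbp = 1e9 bp, rounded half-up to 2 decimals;
percentages rounded half-up to 1 decimal, always computed from full-precision
counts and rounded once.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .classify import Assignment, ReadAttributes
from .errors import ContractError, DataError
from .io_formats import DEFAULT_N_CHANNELS

__all__ = [
    "GroupTotals",
    "LibrarySummary",
    "ChannelSummary",
    "ClassifiedSummary",
    "library_summary",
    "channel_summary",
    "length_quality_stats",
    "classified_summary",
    "round_half_up",
    "to_millions",
    "to_gbp",
    "percent",
]


def round_half_up(value: float, decimals: int = 2) -> float:
    """Decimal round-half-up (0.005 -> 0.01), unlike banker's rounding."""
    quantum = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(value)).quantize(quantum, rounding=ROUND_HALF_UP))


def to_millions(count: float, decimals: int = 2) -> float:
    """Reads expressed in millions (M), rounded half-up."""
    return round_half_up(count / 1e6, decimals)


def to_gbp(bp: float, decimals: int = 2) -> float:
    """Base pairs expressed in Gbp, rounded half-up."""
    return round_half_up(bp / 1e9, decimals)


def percent(numerator: float, denominator: float, decimals: int = 1) -> float:
    """Percentage from full-precision counts, rounded half-up once."""
    if denominator == 0:
        return 0.0
    return round_half_up(100.0 * numerator / denominator, decimals)


@dataclass(frozen=True)
class GroupTotals:
    """Totals over one read partition (mapped, unmapped, or all)."""

    read_count: int = 0
    cum_read_length: int = 0
    tandem_read_count: int = 0
    cum_tandem_length: int = 0

    def __add__(self, other: "GroupTotals") -> "GroupTotals":
        return GroupTotals(
            self.read_count + other.read_count,
            self.cum_read_length + other.cum_read_length,
            self.tandem_read_count + other.tandem_read_count,
            self.cum_tandem_length + other.cum_tandem_length,
        )


@dataclass(frozen=True)
class LibrarySummary:
    """Flow-cell output and tandem content for one library strategy."""

    library: str
    mapped: GroupTotals
    unmapped: GroupTotals
    all: GroupTotals


@dataclass(frozen=True)
class ClassifiedSummary:
    """Content of classified (barcoded) reads for one library."""

    library: str
    correct_reads: int
    correct_bp: int
    leaked_reads: int
    leaked_bp: int
    unmapped_reads: int
    unmapped_bp: int
    all_reads: int
    all_bp: int
    unclassified_fraction: float  # of the whole run, in [0, 1]


@dataclass
class ChannelSummary:
    """Per-channel output totals and their mean/SD over active channels.

    ``per_channel`` is indexed by channel number (active channels only, i.e.
    channels that produced at least one read) with one column per
    (partition, metric) pair.  ``ddof`` records the SD convention used
    (0 = population SD, the default).
    """

    library: str
    per_channel: pd.DataFrame
    ddof: int = 0

    _METRICS = ("read_count", "cum_read_length", "tandem_read_count", "cum_tandem_length")

    def mean(self, partition: str, metric: str) -> float:
        return float(self.per_channel[f"{partition}_{metric}"].mean()) if len(
            self.per_channel
        ) else 0.0

    def sd(self, partition: str, metric: str) -> float:
        if len(self.per_channel) <= self.ddof:
            return 0.0
        return float(self.per_channel[f"{partition}_{metric}"].std(ddof=self.ddof))

    def total(self, partition: str, metric: str) -> int:
        return int(self.per_channel[f"{partition}_{metric}"].sum()) if len(
            self.per_channel
        ) else 0


def _check_single_library(rows: Sequence[ReadAttributes]) -> str:
    libraries = {r.library for r in rows}
    if len(libraries) > 1:
        raise ContractError(f"rows from multiple libraries: {sorted(libraries)}")
    return libraries.pop() if libraries else ""


def _totals(rows: Iterable[ReadAttributes]) -> GroupTotals:
    n = bp = ntand = tand_bp = 0
    for r in rows:
        n += 1
        bp += r.length
        if r.total_tandem_length > 0:
            ntand += 1
        tand_bp += r.total_tandem_length
    return GroupTotals(n, bp, ntand, tand_bp)


def library_summary(rows: Sequence[ReadAttributes], library: str | None = None) -> LibrarySummary:
    """Flow-cell totals split by mapped/unmapped status.

    A read counts toward tandem content when its merged total tandem length
    is positive.
    """
    lib = _check_single_library(rows)
    mapped = _totals(r for r in rows if r.mapped)
    unmapped = _totals(r for r in rows if not r.mapped)
    return LibrarySummary(
        library=library if library is not None else lib,
        mapped=mapped,
        unmapped=unmapped,
        all=mapped + unmapped,
    )


def channel_summary(
    rows: Sequence[ReadAttributes],
    n_channels: int = DEFAULT_N_CHANNELS,
    ddof: int = 0,
) -> ChannelSummary:
    """Per-channel totals with mean and SD over active channels.

    Channels that produced zero reads are excluded from the mean/SD (they are
    indistinguishable from dead pores).  ``ddof=0`` gives the population SD;
    pass ``ddof=1`` for the sample SD.
    """
    lib = _check_single_library(rows)
    for r in rows:
        if not (1 <= r.channel <= n_channels):
            raise DataError(f"read {r.read_id}: channel {r.channel} outside [1, {n_channels}]")
    if not rows:
        cols = [
            f"{part}_{metric}"
            for part in ("mapped", "unmapped", "all")
            for metric in ChannelSummary._METRICS
        ]
        return ChannelSummary(lib, pd.DataFrame(columns=cols), ddof=ddof)

    frame = pd.DataFrame(
        {
            "channel": r.channel,
            "mapped": r.mapped,
            "length": r.length,
            "has_tandem": r.total_tandem_length > 0,
            "tandem": r.total_tandem_length,
        }
        for r in rows
    )
    out = {}
    for part in ("mapped", "unmapped", "all"):
        if part == "all":
            sub = frame
        elif part == "mapped":
            sub = frame[frame["mapped"]]
        else:
            sub = frame[~frame["mapped"]]
        grouped = sub.groupby("channel")
        out[f"{part}_read_count"] = grouped.size()
        out[f"{part}_cum_read_length"] = grouped["length"].sum()
        out[f"{part}_tandem_read_count"] = grouped["has_tandem"].sum()
        out[f"{part}_cum_tandem_length"] = grouped["tandem"].sum()
    # reindex on active channels (>= 1 read overall) so a channel with only
    # unmapped reads still contributes zeros to the mapped columns
    active = sorted(frame["channel"].unique())
    per_channel = pd.DataFrame(out).reindex(active).fillna(0).astype(np.int64)
    per_channel.index.name = "channel"
    return ChannelSummary(library=lib, per_channel=per_channel, ddof=ddof)


def length_quality_stats(rows: Sequence[ReadAttributes]) -> pd.DataFrame:
    """Mean and maximum of read length, matched length, tandem length, Qscore.

    Indexed by partition (mapped / unmapped / all); matched length is only
    defined for mapped reads (no alignment exists otherwise), so those cells
    are NaN for the unmapped partition.
    """
    if not rows:
        raise ContractError("length_quality_stats requires at least one row")
    frame = pd.DataFrame(
        {
            "mapped": r.mapped,
            "length": r.length,
            "matched": r.matched_length if r.mapped else np.nan,
            "tandem": r.total_tandem_length,
            "qscore": r.mean_qscore,
        }
        for r in rows
    )
    parts = {
        "mapped": frame[frame["mapped"]],
        "unmapped": frame[~frame["mapped"]],
        "all": frame,
    }
    records = {}
    for name, sub in parts.items():
        if len(sub) == 0:
            records[name] = {c: np.nan for c in (
                "read_length_mean", "read_length_max", "matched_length_mean",
                "matched_length_max", "tandem_length_mean", "tandem_length_max",
                "mean_qscore_mean", "mean_qscore_max",
            )}
            continue
        records[name] = {
            "read_length_mean": sub["length"].mean(),
            "read_length_max": sub["length"].max(),
            "matched_length_mean": sub["matched"].mean(),
            "matched_length_max": sub["matched"].max(),
            "tandem_length_mean": sub["tandem"].mean(),
            "tandem_length_max": sub["tandem"].max(),
            "mean_qscore_mean": sub["qscore"].mean(),
            "mean_qscore_max": sub["qscore"].max(),
        }
    return pd.DataFrame.from_dict(records, orient="index")


def classified_summary(rows: Sequence[ReadAttributes], library: str | None = None) -> ClassifiedSummary:
    """Partition classified reads into correct / leaked / unmapped content."""
    lib = _check_single_library(rows)
    counts = {a: 0 for a in (Assignment.CORRECT, Assignment.LEAKED, Assignment.UNMAPPED)}
    bps = {a: 0 for a in counts}
    n_classified = 0
    bp_classified = 0
    for r in rows:
        if not r.classified:
            continue
        n_classified += 1
        bp_classified += r.length
        counts[r.assignment] += 1
        bps[r.assignment] += r.length
    n_all = len(rows)
    unclassified_fraction = 1.0 - n_classified / n_all if n_all else 1.0
    return ClassifiedSummary(
        library=library if library is not None else lib,
        correct_reads=counts[Assignment.CORRECT],
        correct_bp=bps[Assignment.CORRECT],
        leaked_reads=counts[Assignment.LEAKED],
        leaked_bp=bps[Assignment.LEAKED],
        unmapped_reads=counts[Assignment.UNMAPPED],
        unmapped_bp=bps[Assignment.UNMAPPED],
        all_reads=n_classified,
        all_bp=bp_classified,
        unclassified_fraction=unclassified_fraction,
    )
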