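"""Tandem-repeat overlap parsing and read-edge profiling.

Nanopore reads can carry artifactual tandem-repeat stretches that are not
present in the sequenced genome.  A repeat finder reports one row per
(period, span) candidate, so the same artifact is typically reported several
times with overlapping coordinates.  This module merges overlapping intervals
per read, computes the total tandem length each read carries, and profiles
where tandem bases sit relative to the read's 5' and 3' ends — artifacts
concentrate within the first few hundred to few thousand bases of each end,
i.e. the pore entry and exit sides of the molecule.

A naive exact detector is included so tests and examples need no external
repeat-finder binary; the production path ingests TRF ``.dat`` reports via
:func:`nanoplex_qc.io_formats.read_trf_dat`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .errors import ContractError, DataError, ParameterError
from .io_formats import TandemInterval

__all__ = [
    "MergedTandemProfile",
    "EdgeProfile",
    "merge_tandem_intervals",
    "merge_by_read",
    "edge_profile",
    "detect_tandems_naive",
]


@dataclass(frozen=True)
class MergedTandemProfile:
    """Disjoint tandem intervals of one read after union of overlaps."""

    read_id: str
    merged_intervals: tuple[tuple[int, int], ...]
    total_tandem_length: int


@dataclass
class EdgeProfile:
    """Tandem-base counts binned by distance from each read end.

    ``counts_5p[b]`` is the number of merged tandem bases whose distance from
    the 5' end falls in ``[b*bin_width, (b+1)*bin_width)``; ``counts_3p`` is
    the symmetric view from the 3' end.  A base on a read shorter than twice
    the window may legitimately count on both sides — the two panels are
    independent views.
    """

    bin_width: int
    window: int
    counts_5p: np.ndarray
    counts_3p: np.ndarray

    @property
    def n_bins(self) -> int:
        return self.window // self.bin_width

    def bin_starts(self) -> np.ndarray:
        return np.arange(self.n_bins) * self.bin_width


def merge_tandem_intervals(
    intervals: Sequence[TandemInterval],
    read_id: str | None = None,
) -> MergedTandemProfile:
    """Union overlapping tandem intervals of a single read.

    Strictly overlapping intervals (``next.start < current.end``) are joined;
    abutting intervals (``next.start == current.end``) are kept separate —
    the total tandem length is invariant to that choice.
    """
    ids = {iv.read_id for iv in intervals}
    if len(ids) > 1:
        raise ContractError(f"intervals from multiple reads: {sorted(ids)}")
    if read_id is None:
        read_id = next(iter(ids)) if ids else ""
    elif ids and ids != {read_id}:
        raise ContractError(f"intervals belong to {ids.pop()!r}, not {read_id!r}")

    merged: list[list[int]] = []
    for iv in sorted(intervals, key=lambda iv: (iv.start, iv.end)):
        if merged and iv.start < merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], iv.end)
        else:
            merged.append([iv.start, iv.end])
    total = sum(e - s for s, e in merged)
    return MergedTandemProfile(
        read_id=read_id,
        merged_intervals=tuple((s, e) for s, e in merged),
        total_tandem_length=total,
    )


def merge_by_read(intervals: Iterable[TandemInterval]) -> dict[str, MergedTandemProfile]:
    """Group raw intervals by read and merge each group."""
    groups: dict[str, list[TandemInterval]] = {}
    for iv in intervals:
        groups.setdefault(iv.read_id, []).append(iv)
    return {rid: merge_tandem_intervals(ivs, rid) for rid, ivs in groups.items()}


def _accumulate(counts: np.ndarray, lo: int, hi: int, bin_width: int, window: int) -> None:
    # add the overlap of distance range [lo, hi) with each bin of [0, window)
    lo = max(lo, 0)
    hi = min(hi, window)
    if hi <= lo:
        return
    first = lo // bin_width
    last = (hi - 1) // bin_width
    for b in range(first, last + 1):
        b_lo = b * bin_width
        b_hi = b_lo + bin_width
        counts[b] += min(hi, b_hi) - max(lo, b_lo)


def edge_profile(
    profiles: Iterable[MergedTandemProfile],
    read_lengths: Mapping[str, int],
    bin_width: int = 500,
    window: int = 15_000,
) -> EdgeProfile:
    """Bin merged tandem bases by their distance from each read end.

    A tandem base at 0-based position ``p`` on a read of length ``L`` lies at
    distance ``p`` from the 5' end and ``L - 1 - p`` from the 3' end; each
    distance below ``window`` increments the corresponding bin.  Counting
    bases (rather than interval midpoints) makes the profile a density of
    tandem content, unambiguous for long intervals spanning several bins.
    """
    if bin_width <= 0:
        raise ParameterError(f"bin_width must be positive, got {bin_width}")
    if window <= 0 or window % bin_width != 0:
        raise ParameterError(
            f"window ({window}) must be a positive multiple of bin_width ({bin_width})"
        )
    n_bins = window // bin_width
    c5 = np.zeros(n_bins, dtype=np.int64)
    c3 = np.zeros(n_bins, dtype=np.int64)
    for prof in profiles:
        try:
            length = read_lengths[prof.read_id]
        except KeyError:
            raise DataError(f"no read length known for {prof.read_id!r}") from None
        for start, end in prof.merged_intervals:
            if end > length:
                raise DataError(
                    f"tandem interval [{start}, {end}) exceeds read "
                    f"{prof.read_id!r} length {length}"
                )
            # 5' distances are the positions themselves
            _accumulate(c5, start, end, bin_width, window)
            # 3' distances of [start, end) are [length - end, length - start)
            _accumulate(c3, length - end, length - start, bin_width, window)
    return EdgeProfile(bin_width=bin_width, window=window, counts_5p=c5, counts_3p=c3)


_N_BYTE = ord("N")


def detect_tandems_naive(
    sequence: str,
    min_period: int = 1,
    max_period: int = 2000,
    min_total_length: int = 24,
    read_id: str = "",
) -> list[TandemInterval]:
    """Exact tandem detection by self-shift comparison.

    For each period ``p`` the detector finds maximal runs of positions where
    ``s[i] == s[i - p]`` (positions containing ``N`` never match).  A run of
    matches over absolute positions ``[a, b)`` corresponds to the tandem
    interval ``[a - p, b)``; it is reported when its span reaches
    ``min_total_length`` and at least two unit copies (span >= 2p).  The same
    artifact may be reported at several periods; merging overlaps is
    :func:`merge_tandem_intervals`'s job.

    This is a deliberately simple exact scheme: it finds perfect repeats only
    and makes no attempt at the alignment-scored, mismatch-tolerant detection
    of a dedicated repeat finder.
    """
    if not (1 <= min_period <= max_period):
        raise ParameterError(f"need 1 <= min_period <= max_period, got {min_period}..{max_period}")
    n = len(sequence)
    if n == 0:
        return []
    arr = np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)
    results: list[TandemInterval] = []
    for period in range(min_period, min(max_period, n - 1) + 1):
        shifted_ok = (arr[period:] == arr[:-period]) & (arr[period:] != _N_BYTE) & (
            arr[:-period] != _N_BYTE
        )
        if not shifted_ok.any():
            continue
        # run boundaries over the match vector (index k <-> position k + period)
        padded = np.concatenate(([False], shifted_ok, [False]))
        edges = np.flatnonzero(padded[1:] != padded[:-1])
        for run_start, run_end in zip(edges[::2], edges[1::2]):
            start = int(run_start)  # == (run_start + period) - period
            end = int(run_end) + period
            span = end - start
            if span >= min_total_length and span >= 2 * period:
                results.append(
                    TandemInterval(
                        read_id=read_id,
                        start=start,
                        end=end,
                        period=period,
                        copy_number=round(span / period, 2),
                    )
                )
    return results
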