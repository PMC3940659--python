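"""Interval arithmetic and per-protein region metrics.

All coordinates are 1-based and inclusive at both ends, so an interval
(97, 112) has length 16.  Same-kind overlapping intervals are merged before
any residue counting, which keeps content percentages <= 100 and counts every
residue once; abutting intervals are deliberately kept distinct so region
*counts* are preserved.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Optional


@dataclass(frozen=True, order=True)
class Interval:
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"interval start {self.start} > end {self.end}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class RegionSet:
    """All regions of one kind (AR or LCR) on one protein, sorted by start."""

    protein_id: str
    kind: str
    intervals: tuple[Interval, ...]
    peak_scores: Optional[tuple[float, ...]] = None

    def __post_init__(self) -> None:
        ivs = tuple(sorted(self.intervals))
        object.__setattr__(self, "intervals", ivs)

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self):
        return iter(self.intervals)


@dataclass(frozen=True)
class OverlapRecord:
    """A single AR x LCR intersection on one protein."""

    protein_id: str
    ar: Interval
    lcr: Interval
    overlap: Interval

    @property
    def overlap_length(self) -> int:
        return self.overlap.length


def region_set(
    protein_id: str, kind: str, intervals: Iterable[tuple[int, int] | Interval]
) -> RegionSet:
    """Convenience constructor accepting (start, end) pairs."""
    ivs = tuple(
        iv if isinstance(iv, Interval) else Interval(*iv) for iv in intervals
    )
    return RegionSet(protein_id=protein_id, kind=kind, intervals=ivs)


def interval_length(iv: Interval) -> int:
    return iv.length


def intersect(a: Interval, b: Interval) -> Optional[Interval]:
    """Intersection of two closed intervals, or None when disjoint."""
    lo, hi = max(a.start, b.start), min(a.end, b.end)
    if lo > hi:
        return None
    return Interval(lo, hi)


def merge_intervals(intervals: Iterable[Interval]) -> tuple[Interval, ...]:
    """Merge strictly overlapping intervals; abutting ones stay separate."""
    ivs = sorted(intervals)
    merged: list[Interval] = []
    for iv in ivs:
        if merged and iv.start <= merged[-1].end:
            if iv.end > merged[-1].end:
                merged[-1] = Interval(merged[-1].start, iv.end)
        else:
            merged.append(iv)
    return tuple(merged)


def merge_regions(rs: RegionSet) -> RegionSet:
    return replace(rs, intervals=merge_intervals(rs.intervals), peak_scores=None)


def covered_residues(rs: RegionSet) -> int:
    return sum(iv.length for iv in merge_intervals(rs.intervals))


def content_percent(rs: RegionSet, protein_length: int) -> float:
    """Percentage of the protein covered by the (merged) regions.

    Returned at full precision; presentation rounding is done by
    :func:`format_percent`.
    """
    if protein_length <= 0:
        raise ValueError("protein_length must be positive")
    for iv in rs.intervals:
        if iv.start < 1 or iv.end > protein_length:
            raise ValueError(
                f"{rs.protein_id}: interval ({iv.start},{iv.end}) outside "
                f"protein of length {protein_length}"
            )
    return 100.0 * covered_residues(rs) / protein_length


def format_percent(value: float, decimals: int = 0) -> float:
    """Half-up presentation rounding (2.5 -> 3 at 0 decimals)."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def terminal_counts(
    rs: RegionSet, protein_length: int, margin: int = 15
) -> tuple[int, int]:
    """Regions touching the N- and C-terminal windows of ``margin`` residues.

    A region counts for a terminus when any of its residues lies within the
    first (N) or last (C) ``margin`` positions.
    """
    if margin >= protein_length:
        warnings.warn(
            f"{rs.protein_id}: terminal margin {margin} >= protein length "
            f"{protein_length}; both windows cover the whole protein",
            stacklevel=2,
        )
    n_window = Interval(1, min(margin, protein_length))
    c_window = Interval(max(1, protein_length - margin + 1), protein_length)
    n_count = sum(1 for iv in rs.intervals if intersect(iv, n_window) is not None)
    c_count = sum(1 for iv in rs.intervals if intersect(iv, c_window) is not None)
    return n_count, c_count


def overlap_catalog(ars: RegionSet, lcrs: RegionSet) -> list[OverlapRecord]:
    """One record per (AR, LCR) pair with a non-empty intersection."""
    if ars.protein_id != lcrs.protein_id:
        raise ValueError(
            f"region sets belong to different proteins: "
            f"{ars.protein_id!r} vs {lcrs.protein_id!r}"
        )
    records = []
    for ar in ars.intervals:
        for lcr in lcrs.intervals:
            ov = intersect(ar, lcr)
            if ov is not None:
                records.append(
                    OverlapRecord(
                        protein_id=ars.protein_id, ar=ar, lcr=lcr, overlap=ov
                    )
                )
    return records
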