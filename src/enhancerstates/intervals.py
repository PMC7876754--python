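"""Genomic interval algebra.

All coordinates follow the BED convention: 0-based, half-open
``[start, end)``.  These primitives underpin every overlap rule in the
pipeline — fractional-overlap peak merging, presence calls against a
reference region, coverage by conserved blocks, and nearest-TSS
distances.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass
from typing import Iterable, Iterator, Literal, Sequence

__all__ = [
    "GenomicInterval",
    "IntervalSet",
    "NoNeighborError",
    "overlap_bp",
    "overlap_fraction",
    "merge_by_fraction",
    "coverage_fraction",
    "nearest_point_distance",
]


class NoNeighborError(ValueError):
    """Raised when a nearest-point query finds no point on the chromosome."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A half-open region ``[start, end)`` on a named chromosome."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start: {self!r}")
        if self.end <= self.start:
            raise ValueError(
                f"zero- or negative-width interval: {self.chrom}:{self.start}-{self.end}"
            )

    @property
    def width(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.chrom}:{self.start}-{self.end}"


class IntervalSet:
    """An immutable, canonically sorted collection of :class:`GenomicInterval`.

    Duplicates are permitted on input (peak files can contain them) but
    are never produced by :func:`merge_by_fraction`.
    """

    __slots__ = ("_intervals", "_by_chrom")

    def __init__(self, intervals: Iterable[GenomicInterval] = ()):
        self._intervals: tuple[GenomicInterval, ...] = tuple(
            sorted(intervals, key=lambda iv: (iv.chrom, iv.start, iv.end))
        )
        self._by_chrom: dict[str, list[GenomicInterval]] | None = None

    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter(self._intervals)

    def __len__(self) -> int:
        return len(self._intervals)

    def __getitem__(self, i: int) -> GenomicInterval:
        return self._intervals[i]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, IntervalSet):
            return NotImplemented
        return self._intervals == other._intervals

    def __hash__(self) -> int:
        return hash(self._intervals)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"IntervalSet({len(self)} intervals)"

    def by_chrom(self) -> dict[str, list[GenomicInterval]]:
        if self._by_chrom is None:
            d: dict[str, list[GenomicInterval]] = {}
            for iv in self._intervals:
                d.setdefault(iv.chrom, []).append(iv)
            self._by_chrom = d
        return self._by_chrom

    def chroms(self) -> list[str]:
        return sorted(self.by_chrom())

    def overlappers(self, region: GenomicInterval) -> list[GenomicInterval]:
        """All intervals with ≥1 bp overlap with ``region``.

        Uses a sorted sweep with a prefix-maximum of ends, so long
        intervals starting far upstream are still found.
        """
        ivs = self.by_chrom().get(region.chrom)
        if not ivs:
            return []
        # candidates: start < region.end
        starts = [iv.start for iv in ivs]
        hi = bisect.bisect_left(starts, region.end)
        return [iv for iv in ivs[:hi] if iv.end > region.start]


Denominator = Literal["of_a", "of_b", "of_smaller"]


def overlap_bp(a: GenomicInterval, b: GenomicInterval) -> int:
    """Number of shared bases between two intervals (0 across chromosomes)."""
    if a.chrom != b.chrom:
        return 0
    return max(0, min(a.end, b.end) - max(a.start, b.start))


def overlap_fraction(
    a: GenomicInterval, b: GenomicInterval, denominator: Denominator
) -> float:
    """Shared bases as a fraction of the designated interval's width.

    ``denominator`` must be stated explicitly by every caller: the
    pipeline's overlap rules differ in which side the percentage refers
    to (the reference region, the sample peak, or whichever is smaller).
    """
    ov = overlap_bp(a, b)
    if denominator == "of_a":
        return ov / a.width
    if denominator == "of_b":
        return ov / b.width
    if denominator == "of_smaller":
        return ov / min(a.width, b.width)
    raise ValueError(f"unknown denominator: {denominator!r}")


def _qualifies(s1: int, e1: int, s2: int, e2: int, min_frac: float) -> bool:
    ov = min(e1, e2) - max(s1, s2)
    return ov > 0 and ov >= min_frac * min(e1 - s1, e2 - s2)


def _merge_pass(
    items: list[tuple[int, int]], min_frac: float
) -> tuple[list[tuple[int, int]], bool]:
    items.sort()
    out: list[tuple[int, int]] = []
    pmax: list[int] = []  # prefix maximum of ends, aligned with out
    changed = False
    for s, e in items:
        k = len(out) - 1
        merged = False
        while k >= 0 and pmax[k] > s:
            os_, oe = out[k]
            if _qualifies(os_, oe, s, e, min_frac):
                out[k] = (min(os_, s), max(oe, e))
                for j in range(k, len(out)):
                    pmax[j] = max(pmax[j - 1] if j else out[j][1], out[j][1])
                changed = True
                merged = True
                break
            k -= 1
        if not merged:
            out.append((s, e))
            pmax.append(max(e, pmax[-1]) if pmax else e)
    return out, changed


def merge_by_fraction(
    sets: IntervalSet | Sequence[IntervalSet], min_frac: float
) -> IntervalSet:
    """Fractional-overlap consensus merge of one or more interval sets.

    Two intervals merge when their overlap is at least ``min_frac`` of
    *either* of them (equivalently, of the smaller); the merged interval
    spans the union of the pair.  Merging is iterated to a fixpoint: the
    result contains no qualifying pair.  The procedure sorts its pooled
    input first, so it is independent of input order.

    Duplicated intervals always qualify (overlap equals both widths) and
    therefore collapse.
    """
    if not 0 < min_frac <= 1:
        raise ValueError(f"min_frac must be in (0, 1], got {min_frac}")
    if isinstance(sets, IntervalSet):
        sets = [sets]
    pooled: dict[str, list[tuple[int, int]]] = {}
    for iset in sets:
        for iv in iset:
            pooled.setdefault(iv.chrom, []).append((iv.start, iv.end))
    merged: list[GenomicInterval] = []
    for chrom in sorted(pooled):
        items = pooled[chrom]
        changed = True
        while changed:
            items, changed = _merge_pass(items, min_frac)
        merged.extend(GenomicInterval(chrom, s, e) for s, e in items)
    return IntervalSet(merged)


def coverage_fraction(region: GenomicInterval, blocks: IntervalSet) -> float:
    """Fraction of ``region``'s bases covered by the union of ``blocks``.

    Overlapping blocks are counted once.
    """
    covered = 0
    cur_s = cur_e = None
    for b in blocks.overlappers(region):
        s = max(b.start, region.start)
        e = min(b.end, region.end)
        if cur_e is None:
            cur_s, cur_e = s, e
        elif s <= cur_e:
            cur_e = max(cur_e, e)
        else:
            covered += cur_e - cur_s
            cur_s, cur_e = s, e
    if cur_e is not None:
        covered += cur_e - cur_s
    return covered / region.width


def nearest_point_distance(
    region: GenomicInterval, points: Sequence[tuple[str, int]]
) -> tuple[tuple[str, int], int]:
    """Nearest point to the region midpoint, with its unsigned distance.

    Distance is ``|midpoint − position|`` minimised over points on the
    region's chromosome; ties break to the lower position.  Raises
    :class:`NoNeighborError` when the chromosome has no point — never a
    silent zero.
    """
    mid = region.midpoint
    best: tuple[int, int] | None = None  # (distance, position)
    for chrom, pos in points:
        if chrom != region.chrom:
            continue
        d = abs(mid - pos)
        if best is None or (d, pos) < best:
            best = (d, pos)
    if best is None:
        raise NoNeighborError(
            f"no point on chromosome {region.chrom!r} for region {region}"
        )
    return (region.chrom, best[1]), best[0]
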