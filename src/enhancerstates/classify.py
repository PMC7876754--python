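"""Consensus reference regions, region×sample presence matrix, and
chromatin-state classification of putative enhancers.

The reference region set ("putative enhancers") is built by
fractional-overlap merging of H3K4me1 peaks — the ES replicates pooled
with any external-context H3K4me1 sets — then filtered against promoter
windows.  Each reference region is scored for presence of each sample's
peaks (a sample is present when one of its peaks covers at least
``merge_frac`` of the *reference region*), and the per-mark presence
counts decide the state:

* active — H3K4me1 and H3K27ac each in ≥ presence_min samples, H3K27me3
  in ≤ absence_max samples;
* bivalent — H3K4me1 and H3K27me3 each in ≥ presence_min samples,
  H3K27ac in ≤ absence_max;
* h3k4me1_only / h3k27ac_only / h3k27me3_only — the named mark in
  ≥ presence_min samples, the other two in ≤ absence_max;
* unclassified — anything else.

With the default presence_min=3 and absence_max=0 over 4 replicates per
mark, active and bivalent are mutually exclusive by construction.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .intervals import GenomicInterval, IntervalSet, merge_by_fraction, overlap_bp
from .io import Mark, PeakSet, TSSTable, Thresholds
from .states import State

__all__ = [
    "RegionSampleMatrix",
    "StateCall",
    "build_reference_regions",
    "filter_promoter_regions",
    "build_matrix",
    "classify_counts",
    "classify_region",
    "classify_all",
    "presence_curve",
]

MARK_ORDER = (Mark.H3K4ME1, Mark.H3K27AC, Mark.H3K27ME3)


@dataclass
class RegionSampleMatrix:
    """Binary presence of each sample's peaks over the reference regions."""

    regions: IntervalSet
    samples: list[tuple[str, Mark]]  # (sample_id, mark), column order
    presence: np.ndarray  # shape (n_regions, n_samples), values {0,1}

    def __post_init__(self) -> None:
        if self.presence.shape != (len(self.regions), len(self.samples)):
            raise ValueError("presence matrix shape does not match regions × samples")
        if not np.isin(self.presence, (0, 1)).all():
            raise ValueError("presence entries must be 0/1")

    def mark_counts(self) -> np.ndarray:
        """Per-region presence counts for (H3K4me1, H3K27ac, H3K27me3)."""
        cols = {m: [] for m in MARK_ORDER}
        for j, (_, mark) in enumerate(self.samples):
            if mark in cols:
                cols[mark].append(j)
        out = np.zeros((len(self.regions), 3), dtype=int)
        for i, m in enumerate(MARK_ORDER):
            if cols[m]:
                out[:, i] = self.presence[:, cols[m]].sum(axis=1)
        return out

    def mark_totals(self) -> tuple[int, int, int]:
        c = Counter(mark for _, mark in self.samples)
        return tuple(c.get(m, 0) for m in MARK_ORDER)  # type: ignore[return-value]


@dataclass(frozen=True)
class StateCall:
    region: GenomicInterval
    state: State
    n_k4me1: int
    n_k27ac: int
    n_k27me3: int


def build_reference_regions(
    h3k4me1_sets: Sequence[PeakSet | IntervalSet], merge_frac: float = 0.25
) -> IntervalSet:
    """Merge pooled H3K4me1 peaks into the reference "putative enhancer" set.

    ``h3k4me1_sets`` may mix ES replicates with external-context peak
    sets; all are pooled before merging.
    """
    pools = [
        ps.intervals if isinstance(ps, PeakSet) else ps for ps in h3k4me1_sets
    ]
    if not pools or all(len(p) == 0 for p in pools):
        raise ValueError("no H3K4me1 peaks supplied to build the reference")
    return merge_by_fraction(pools, merge_frac)


def filter_promoter_regions(
    regions: IntervalSet, tss: TSSTable, promoter_halfwidth: int = 500
) -> tuple[IntervalSet, int]:
    """Drop every region touching a promoter window (TSS ± halfwidth).

    Any single base of overlap removes the region.  Returns the
    survivors and the number removed.
    """
    if promoter_halfwidth <= 0:
        raise ValueError("promoter_halfwidth must be positive")
    windows = tss.promoter_windows(promoter_halfwidth)
    kept = [r for r in regions if not windows.overlappers(r)]
    return IntervalSet(kept), len(regions) - len(kept)


def build_matrix(
    regions: IntervalSet, peaksets: Sequence[PeakSet], min_frac: float = 0.25
) -> RegionSampleMatrix:
    """Score each reference region for presence in each sample.

    Entry (r, s) is 1 when some peak of sample s overlaps at least
    ``min_frac`` of region r's width (denominator: the reference
    region; threshold inclusive).  Several peaks hitting one region
    still yield a single 1.
    """
    presence = np.zeros((len(regions), len(peaksets)), dtype=np.uint8)
    for j, ps in enumerate(peaksets):
        for i, region in enumerate(regions):
            need = min_frac * region.width
            for peak in ps.intervals.overlappers(region):
                if overlap_bp(region, peak) >= need:
                    presence[i, j] = 1
                    break
    return RegionSampleMatrix(
        regions=regions,
        samples=[(ps.sample_id, ps.mark) for ps in peaksets],
        presence=presence,
    )


def classify_counts(
    counts: tuple[int, int, int],
    presence_mins: tuple[int, int, int],
    absence_max: int,
    latent_when_empty: bool = False,
) -> State:
    """State from per-mark presence counts with per-mark presence thresholds.

    ``latent_when_empty`` maps an all-zero row to LATENT instead of
    UNCLASSIFIED (used when re-classifying the reference regions in a
    different tissue context, where "no mark at all" is a meaningful
    outcome).
    """
    n1, n2, n3 = counts
    p1, p2, p3 = presence_mins
    a = absence_max
    if latent_when_empty and n1 == 0 and n2 == 0 and n3 == 0:
        return State.LATENT
    if n1 >= p1 and n2 >= p2 and n3 <= a:
        return State.ACTIVE
    if n1 >= p1 and n3 >= p3 and n2 <= a:
        return State.BIVALENT
    if n1 >= p1 and n2 <= a and n3 <= a:
        return State.K4ME1_ONLY
    if n2 >= p2 and n1 <= a and n3 <= a:
        return State.K27AC_ONLY
    if n3 >= p3 and n1 <= a and n2 <= a:
        return State.K27ME3_ONLY
    return State.UNCLASSIFIED


def classify_region(
    counts: tuple[int, int, int],
    totals: tuple[int, int, int],
    presence_min: int = 3,
    absence_max: int = 0,
) -> State:
    """Assign one of the five states (or unclassified) from presence counts.

    ``counts`` and ``totals`` are per-mark (H3K4me1, H3K27ac, H3K27me3)
    sample counts.  Configuration errors (thresholds incompatible with
    the sample design) raise at call time.
    """
    if absence_max >= presence_min:
        raise ValueError("absence_max must be < presence_min")
    for n, t in zip(counts, totals):
        if n > t:
            raise ValueError(f"count {n} exceeds total {t}")
        if t and presence_min > t:
            raise ValueError(f"presence_min={presence_min} exceeds {t} samples of a mark")
    return classify_counts(counts, (presence_min,) * 3, absence_max)


def classify_all(
    matrix: RegionSampleMatrix, thresholds: Thresholds | None = None
) -> tuple[list[StateCall], dict[State, int]]:
    """Row-wise classification of the whole matrix, with per-state counts.

    The states partition the region set; unclassified is an explicit
    label, never dropped.
    """
    thr = thresholds or Thresholds()
    totals = matrix.mark_totals()
    counts = matrix.mark_counts()
    calls = []
    for region, (n1, n2, n3) in zip(matrix.regions, counts):
        state = classify_region((int(n1), int(n2), int(n3)), totals,
                                thr.presence_min, thr.absence_max)
        calls.append(StateCall(region, state, int(n1), int(n2), int(n3)))
    tally: dict[State, int] = {s: 0 for s in State if s is not State.LATENT}
    for c in calls:
        tally[c.state] += 1
    return calls, tally


def presence_curve(
    peaksets: Sequence[PeakSet], merge_frac: float = 0.25
) -> list[int]:
    """Consensus regions present in ≥N samples, for N = 1..n_samples.

    Peaks of the given mark are merged into consensus regions; each
    region's sample support is the number of samples with a qualifying
    (≥ merge_frac of the region) peak.  The returned sequence is
    monotone non-increasing.
    """
    if not peaksets:
        raise ValueError("need at least one sample")
    regions = merge_by_fraction([ps.intervals for ps in peaksets], merge_frac)
    m = build_matrix(regions, peaksets, merge_frac)
    support = m.presence.sum(axis=1)
    return [int((support >= n).sum()) for n in range(1, len(peaksets) + 1)]
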