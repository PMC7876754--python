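"""Factor-occupancy calls and hypergeometric enrichment of factors at
enhancer states, plus fractional-overlap comparisons against external
region sets (2i-culture enhancers, super-enhancers, conserved elements,
tissue peak catalogues ...).

The occupancy rule follows the broad-domain/point-source asymmetry of
the data: histone-mark consensus regions are typically several kb wide
while transcription-factor peaks are a few hundred bases, so a factor
is called bound when *more than half of the factor peak* falls inside
the region (the denominator is switchable for users who prefer the
region side).

Enrichment per (factor, state) is an exact hypergeometric upper tail on
the universe of all promoter-filtered reference regions, Bonferroni-
corrected over the batch of tests actually performed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .intervals import GenomicInterval, IntervalSet, coverage_fraction, overlap_bp
from .states import NAMED_STATES, State

__all__ = [
    "EnrichmentRecord",
    "occupancy",
    "factor_count_per_region",
    "hypergeom_tail",
    "enrich_factors",
    "overlap_fraction_with_set",
]


@dataclass(frozen=True)
class EnrichmentRecord:
    """One (factor, state) over-representation test.

    k of the K regions in the state are bound by the factor, which
    binds n of the N regions in the universe overall.
    """

    factor_id: str
    state: State
    k: int
    K: int
    n: int
    N: int
    p_value: float
    p_adjusted: float

    @property
    def fraction_bound(self) -> float:
        return self.k / self.K if self.K else float("nan")


def occupancy(
    regions: Sequence[GenomicInterval],
    factor_peaks: IntervalSet,
    occupancy_frac: float = 0.5,
    denominator: Literal["factor_peak", "region"] = "factor_peak",
) -> list[bool]:
    """Per-region bound/unbound call for one factor.

    With the default denominator, a region is bound when some factor
    peak has strictly more than ``occupancy_frac`` of its own width
    inside the region.  ``denominator="region"`` instead requires the
    peak(s) to cover that fraction of the region.
    """
    if not 0 < occupancy_frac <= 1:
        raise ValueError("occupancy_frac must be in (0, 1]")
    out = []
    for region in regions:
        if denominator == "region":
            out.append(coverage_fraction(region, factor_peaks) > occupancy_frac)
            continue
        bound = False
        for peak in factor_peaks.overlappers(region):
            if overlap_bp(region, peak) > occupancy_frac * peak.width:
                bound = True
                break
        out.append(bound)
    return out


def factor_count_per_region(
    regions: Sequence[GenomicInterval],
    factor_peaksets: Mapping[str, IntervalSet],
    occupancy_frac: float = 0.5,
) -> np.ndarray:
    """Number of distinct factors bound at each region."""
    if not factor_peaksets:
        raise ValueError("need at least one factor peak set")
    counts = np.zeros(len(regions), dtype=int)
    for peaks in factor_peaksets.values():
        counts += np.asarray(occupancy(regions, peaks, occupancy_frac), dtype=int)
    return counts


def hypergeom_tail(k: int, K: int, n: int, N: int) -> float:
    """P(X ≥ k) for X ~ Hypergeometric(N, n, K): exact upper tail.

    X counts how many of the K state regions fall among the n bound
    regions when the n are drawn from the N-region universe without
    replacement.  k=0 gives 1 by construction.
    """
    if not (0 <= k <= min(K, n) and K <= N and n <= N):
        raise ValueError(f"invalid hypergeometric bounds: k={k}, K={K}, n={n}, N={N}")
    return float(stats.hypergeom.sf(k - 1, N, n, K))


def enrich_factors(
    state_calls: Sequence,  # list of StateCall over the universe regions
    factor_bound: Mapping[str, Sequence[bool]],
    states: Sequence[State] = NAMED_STATES,
) -> list[EnrichmentRecord]:
    """One hypergeometric record per (factor, state) with Bonferroni.

    ``factor_bound`` maps factor id → per-region bound flags aligned
    with ``state_calls`` (from :func:`occupancy`).  The universe is the
    full set of reference regions behind the calls; states with no
    regions are skipped.  Bonferroni multiplicity is the number of
    tests actually performed; records come back sorted by adjusted p.
    """
    N = len(state_calls)
    labels = [c.state for c in state_calls]
    present_states = [s for s in states if any(lab is s for lab in labels)]
    tests: list[tuple[str, State, int, int, int]] = []
    for fid, flags in factor_bound.items():
        if len(flags) != N:
            raise ValueError(f"factor {fid!r}: flag vector length {len(flags)} != {N}")
        n = int(sum(flags))
        for s in present_states:
            idx = [i for i, lab in enumerate(labels) if lab is s]
            K = len(idx)
            k = int(sum(flags[i] for i in idx))
            tests.append((fid, s, k, K, n))
    m = len(tests)
    records = [
        EnrichmentRecord(
            factor_id=fid, state=s, k=k, K=K, n=n, N=N,
            p_value=(p := hypergeom_tail(k, K, n, N)),
            p_adjusted=min(1.0, m * p),
        )
        for fid, s, k, K, n in tests
    ]
    records.sort(key=lambda r: (r.p_adjusted, r.p_value, r.factor_id, r.state.value))
    return records


def enrichment_table(records: Iterable[EnrichmentRecord]) -> pd.DataFrame:
    rows = [
        {
            "factor_id": r.factor_id,
            "state": r.state.value,
            "k_bound_in_state": r.k,
            "K_state_regions": r.K,
            "n_bound_total": r.n,
            "N_universe": r.N,
            "fraction_bound": r.fraction_bound,
            "p_value": r.p_value,
            "p_adjusted": r.p_adjusted,
        }
        for r in records
    ]
    return pd.DataFrame(rows)


def overlap_fraction_with_set(
    state_regions: Sequence[GenomicInterval],
    external_set: IntervalSet,
    min_frac: float = 0.25,
) -> tuple[float, float]:
    """Two-way fractional-overlap summary against an external region set.

    Forward: fraction of state regions with at least ``min_frac`` of
    their width covered by the external set.  Reciprocal: fraction of
    external intervals with at least ``min_frac`` of their width
    covered by the state regions.  An empty state group yields NaN
    (undefined), never 0.
    """
    if not 0 < min_frac <= 1:
        raise ValueError("min_frac must be in (0, 1]")
    if not state_regions:
        forward = float("nan")
    else:
        hits = sum(
            1
            for r in state_regions
            if coverage_fraction(r, external_set) >= min_frac
        )
        forward = hits / len(state_regions)
    if len(external_set) == 0:
        reciprocal = float("nan")
    else:
        state_set = IntervalSet(state_regions)
        rhits = sum(
            1 for iv in external_set if coverage_fraction(iv, state_set) >= min_frac
        )
        reciprocal = rhits / len(external_set)
    return forward, reciprocal
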