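"""State dynamics of the ES-cell reference regions across other tissues,
cell types or reprogramming timepoints.

The reference ("putative enhancer") regions are fixed: each context's
peaks are scored against the *same* region set, so the per-context
states are directly comparable and transition fractions are fractions
of the ES groups.  Contexts usually have a single replicate per mark,
so the presence threshold is clamped per mark to the available sample
count; absence still means zero samples.  A region carrying no mark at
all in a context is LATENT.
"""

from __future__ import annotations

from collections import Counter
from typing import Mapping, Sequence

import pandas as pd

from .classify import RegionSampleMatrix, build_matrix, classify_counts
from .intervals import IntervalSet
from .io import Mark, PeakSet, Thresholds
from .states import State

__all__ = ["classify_in_context", "transition_fractions", "TARGET_LABELS"]

#: Target labels of a transition row: the five states, latent, and
#: unclassified (a marked region matching no class pattern).
TARGET_LABELS = (
    State.ACTIVE,
    State.BIVALENT,
    State.K4ME1_ONLY,
    State.K27AC_ONLY,
    State.K27ME3_ONLY,
    State.LATENT,
    State.UNCLASSIFIED,
)


def classify_in_context(
    es_regions: IntervalSet,
    context_peaksets: Sequence[PeakSet],
    thresholds: Thresholds | None = None,
) -> list[State]:
    """Chromatin state of each ES reference region in one context.

    ``presence_min`` is clamped per mark to ``min(presence_min,
    samples of that mark in the context)``; a mark with no sample in
    the context can never be present.  Regions with no mark → LATENT.
    """
    if not context_peaksets:
        raise ValueError("context supplied no peak files")
    thr = thresholds or Thresholds()
    matrix = build_matrix(es_regions, context_peaksets, thr.merge_frac)
    totals = matrix.mark_totals()
    pmins = tuple(
        min(thr.presence_min, t) if t > 0 else thr.presence_min for t in totals
    )
    counts = matrix.mark_counts()
    return [
        classify_counts(
            (int(n1), int(n2), int(n3)), pmins, thr.absence_max, latent_when_empty=True
        )
        for n1, n2, n3 in counts
    ]


def transition_fractions(
    es_calls: Sequence[State],
    context_calls: Sequence[State],
    context: str = "context",
) -> pd.DataFrame:
    """Per-ES-state distribution over context states, as a long table.

    Columns: source_state, context, target_state, fraction, n_regions.
    Each row block (one source state) sums to 1 over the target labels;
    ES states with no regions are omitted (undefined, not zeros).
    """
    if len(es_calls) != len(context_calls):
        raise ValueError("ES and context call vectors cover different region universes")
    rows = []
    for source in TARGET_LABELS:
        idx = [i for i, s in enumerate(es_calls) if s is source]
        if not idx:
            continue
        tally = Counter(context_calls[i] for i in idx)
        for target in TARGET_LABELS:
            rows.append(
                {
                    "source_state": source.value,
                    "context": context,
                    "target_state": target.value,
                    "fraction": tally.get(target, 0) / len(idx),
                    "n_regions": len(idx),
                }
            )
    return pd.DataFrame(rows)
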