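"""Characterisation of classified regions: nearest-gene assignment,
distance bins, genomic-location categories, conservation status and
gene-level overlap between enhancer groups and promoter groups.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .intervals import GenomicInterval, IntervalSet, coverage_fraction
from .io import TSSTable
from .states import State

__all__ = [
    "GeneAssignment",
    "assign_nearest_gene",
    "bin_distances",
    "annotate_location",
    "annotate_locations",
    "conservation_status",
    "gene_group_overlap",
    "DISTANCE_BIN_LABELS",
]

DISTANCE_BIN_LABELS = ("lt5kb", "5to50kb", "gt50kb")
LOCATION_LABELS = ("tss_5prime", "tts_3prime", "exon", "intron", "intergenic")


@dataclass(frozen=True)
class GeneAssignment:
    region: GenomicInterval
    gene_id: str | None  # None when the chromosome has no TSS
    distance: int | None


def assign_nearest_gene(
    regions: Iterable[GenomicInterval], tss: TSSTable
) -> tuple[list[GeneAssignment], float]:
    """Map each region to the gene with the nearest TSS (midpoint anchor).

    Ties break to the lower TSS position.  Regions on chromosomes with
    no TSS are flagged unassigned (gene_id None) and excluded from the
    mean-regions-per-gene summary, which is returned alongside.
    """
    if len(tss) == 0:
        raise ValueError("TSS table is empty")
    by_chrom: dict[str, list[tuple[int, str]]] = {}
    for r in tss:
        by_chrom.setdefault(r.chrom, []).append((r.tss, r.gene_id))
    for lst in by_chrom.values():
        lst.sort()

    out: list[GeneAssignment] = []
    per_gene: dict[str, int] = {}
    for region in regions:
        pts = by_chrom.get(region.chrom)
        if not pts:
            out.append(GeneAssignment(region, None, None))
            continue
        mid = region.midpoint
        positions = [p for p, _ in pts]
        i = bisect.bisect_left(positions, mid)
        best: tuple[int, int, str] | None = None  # (distance, position, gene)
        for j in (i - 1, i):
            if 0 <= j < len(pts):
                pos, gid = pts[j]
                cand = (abs(mid - pos), pos, gid)
                if best is None or cand < best:
                    best = cand
        assert best is not None
        out.append(GeneAssignment(region, best[2], best[0]))
        per_gene[best[2]] = per_gene.get(best[2], 0) + 1
    mean_per_gene = float(np.mean(list(per_gene.values()))) if per_gene else float("nan")
    return out, mean_per_gene


def bin_distances(
    distances: Sequence[int], edges: tuple[int, int] = (5000, 50000)
) -> dict[str, float]:
    """Fractions of distances in [0,e1), [e1,e2), [e2,∞); left-closed bins."""
    e1, e2 = edges
    if not e1 < e2:
        raise ValueError("bin edges must be strictly increasing")
    ds = [d for d in distances if d is not None]
    if not ds:
        return {lab: float("nan") for lab in DISTANCE_BIN_LABELS}
    n = len(ds)
    lt = sum(1 for d in ds if d < e1)
    mid = sum(1 for d in ds if e1 <= d < e2)
    return {
        "lt5kb": lt / n,
        "5to50kb": mid / n,
        "gt50kb": (n - lt - mid) / n,
    }


class _LocationIndex:
    """Per-chromosome sorted feature lists for midpoint membership tests."""

    def __init__(self, tss: TSSTable, tss_window: int, tts_window: int):
        self.tss_w: dict[str, list[tuple[int, int]]] = {}
        self.tts_w: dict[str, list[tuple[int, int]]] = {}
        self.exons: dict[str, list[tuple[int, int]]] = {}
        self.spans: dict[str, list[tuple[int, int]]] = {}
        for r in tss:
            self.tss_w.setdefault(r.chrom, []).append(
                (max(0, r.tss - tss_window), r.tss + tss_window)
            )
            self.tts_w.setdefault(r.chrom, []).append(
                (max(0, r.tts - tts_window), r.tts + tts_window)
            )
            for ex in r.exons:
                self.exons.setdefault(r.chrom, []).append((ex.start, ex.end))
            self.spans.setdefault(r.chrom, []).append((r.span.start, r.span.end))
        for d in (self.tss_w, self.tts_w, self.exons, self.spans):
            for chrom, lst in d.items():
                lst.sort()
                pmax: list[int] = []
                for _, e in lst:
                    pmax.append(max(e, pmax[-1]) if pmax else e)
                d[chrom] = (lst, pmax)  # type: ignore[assignment]

    @staticmethod
    def _contains(entry, pos: int) -> bool:
        if not entry:
            return False
        lst, pmax = entry
        i = bisect.bisect_right(lst, (pos, float("inf")))
        k = i - 1
        while k >= 0 and pmax[k] > pos:
            if lst[k][1] > pos:
                return True
            k -= 1
        return False

    def locate(self, region: GenomicInterval) -> str:
        mid = region.midpoint
        c = region.chrom
        if self._contains(self.tss_w.get(c), mid):
            return "tss_5prime"
        if self._contains(self.tts_w.get(c), mid):
            return "tts_3prime"
        if self._contains(self.exons.get(c), mid):
            return "exon"
        if self._contains(self.spans.get(c), mid):
            return "intron"
        return "intergenic"


def annotate_location(
    region: GenomicInterval,
    tss: TSSTable,
    tss_window: int = 500,
    tts_window: int = 500,
) -> str:
    """Genomic-location category of a single region (see :func:`annotate_locations`)."""
    return _LocationIndex(tss, tss_window, tts_window).locate(region)


def annotate_locations(
    regions: Iterable[GenomicInterval],
    tss: TSSTable,
    tss_window: int = 500,
    tts_window: int = 500,
) -> list[str]:
    """Categorise regions as tss_5prime / tts_3prime / exon / intron / intergenic.

    The category is decided by membership of the region *midpoint*, with
    the listed priority, so every region receives exactly one mutually
    exclusive category.  TSS/TTS windows default to ±500 b.  Gene models
    without exon detail simply never produce the exon category.
    """
    idx = _LocationIndex(tss, tss_window, tts_window)
    return [idx.locate(r) for r in regions]


def conservation_status(
    regions: Sequence[GenomicInterval],
    conserved_blocks: IntervalSet,
    conservation_frac: float = 0.75,
    inclusive: bool = False,
) -> tuple[list[bool], list[float]]:
    """Per-region conservation call from covered-base fraction.

    A region is conserved when more than ``conservation_frac`` of its
    bases fall inside the union of conserved blocks (strict > by
    default; ``inclusive=True`` switches to ≥).
    """
    if not 0 < conservation_frac <= 1:
        raise ValueError("conservation_frac must be in (0, 1]")
    fractions = [coverage_fraction(r, conserved_blocks) for r in regions]
    if inclusive:
        flags = [f >= conservation_frac for f in fractions]
    else:
        flags = [f > conservation_frac for f in fractions]
    return flags, fractions


def gene_group_overlap(
    enhancer_gene_sets: Mapping[State | str, set[str]],
    promoter_gene_sets: Mapping[str, set[str]],
    universe: set[str],
) -> pd.DataFrame:
    """Gene-level overlap between enhancer groups and promoter groups.

    For each (enhancer state, promoter class) pair, counts the shared
    genes and scores over-representation with a hypergeometric upper
    tail on the gene universe, Bonferroni-corrected across the grid.
    """
    from .enrichment import hypergeom_tail

    if not universe:
        raise ValueError("empty gene universe")
    for name, s in list(enhancer_gene_sets.items()) + list(promoter_gene_sets.items()):
        if not s <= universe:
            raise ValueError(f"gene set {name!r} is not contained in the universe")
    rows = []
    pairs = [(es, pc) for es in enhancer_gene_sets for pc in promoter_gene_sets]
    m = len(pairs)
    for es, pc in pairs:
        a, b = enhancer_gene_sets[es], promoter_gene_sets[pc]
        k = len(a & b)
        p = hypergeom_tail(k, len(a), len(b), len(universe))
        rows.append(
            {
                "enhancer_state": es.value if isinstance(es, State) else es,
                "promoter_class": pc,
                "n_enhancer_genes": len(a),
                "n_promoter_genes": len(b),
                "n_shared": k,
                "p_value": p,
                "p_adjusted": min(1.0, m * p),
            }
        )
    df = pd.DataFrame(rows)
    return df.sort_values(["p_adjusted", "enhancer_state", "promoter_class"]).reset_index(
        drop=True
    )
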