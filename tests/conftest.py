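"""Shared fixtures and independent oracles.

The oracles deliberately avoid the library's interval arithmetic: they
expand intervals into explicit per-base position sets, so any agreement
with the fast implementations is meaningful.
"""

from __future__ import annotations

import pytest
from hypothesis import HealthCheck, settings

from enhancerstates.intervals import GenomicInterval, IntervalSet
from enhancerstates.io import TSSRecord, TSSTable

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=100,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


# ---------------------------------------------------------------- oracles
def base_set(iv: GenomicInterval) -> set[tuple[str, int]]:
    return {(iv.chrom, p) for p in range(iv.start, iv.end)}


def oracle_overlap_bp(a: GenomicInterval, b: GenomicInterval) -> int:
    return len(base_set(a) & base_set(b))


def oracle_coverage_fraction(region: GenomicInterval, blocks) -> float:
    cover = set()
    for b in blocks:
        cover |= base_set(b)
    return len(base_set(region) & cover) / (region.end - region.start)


def oracle_classify(n1: int, n2: int, n3: int, pm: int = 3, am: int = 0) -> str:
    """Hand-written predicate table, independent of the implementation."""
    patterns = {
        "active": (n1 >= pm) and (n2 >= pm) and (n3 <= am),
        "bivalent": (n1 >= pm) and (n3 >= pm) and (n2 <= am),
        "h3k4me1_only": (n1 >= pm) and (n2 <= am) and (n3 <= am),
        "h3k27ac_only": (n2 >= pm) and (n1 <= am) and (n3 <= am),
        "h3k27me3_only": (n3 >= pm) and (n1 <= am) and (n2 <= am),
    }
    hits = [name for name, ok in patterns.items() if ok]
    assert len(hits) <= 1, f"oracle patterns not disjoint at {(n1, n2, n3)}"
    return hits[0] if hits else "unclassified"


# ---------------------------------------------------------------- fixtures
def iv(chrom: str, start: int, end: int) -> GenomicInterval:
    return GenomicInterval(chrom, start, end)


@pytest.fixture
def small_tss_table() -> TSSTable:
    """Two genes on chr1 (one per strand, with exons) and one on chr2."""
    return TSSTable(
        [
            TSSRecord(
                gene_id="geneA",
                chrom="chr1",
                tss=10_000,
                strand="+",
                span=GenomicInterval("chr1", 10_000, 20_000),
                exons=(
                    GenomicInterval("chr1", 10_000, 10_300),
                    GenomicInterval("chr1", 15_000, 15_400),
                ),
                promoter_class="active",
            ),
            TSSRecord(
                gene_id="geneB",
                chrom="chr1",
                tss=59_999,
                strand="-",
                span=GenomicInterval("chr1", 50_000, 60_000),
                exons=(GenomicInterval("chr1", 59_500, 60_000),),
                promoter_class="bivalent",
            ),
            TSSRecord(
                gene_id="geneC",
                chrom="chr2",
                tss=5_000,
                strand="+",
                span=GenomicInterval("chr2", 5_000, 9_000),
                promoter_class="latent",
            ),
        ]
    )
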