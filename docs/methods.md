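# Methods

## Coordinate conventions and interval algebra

All coordinates are 0-based, half-open (BED convention); every reader
and writer conforms, and zero-width intervals are rejected at parse
time. The interval layer provides the five primitives every rule in
the pipeline reduces to: base-pair overlap, fractional overlap with an
explicit denominator, fractional-overlap merging, covered-base
fraction, and midpoint-to-point distance.

**Merging.** Two peaks merge when their overlap is at least
`merge_frac` (default 0.25) of *either* peak — equivalently of the
smaller — and the merged interval is the union span. Because
qualifying pairs always overlap, merging never fabricates covered
bases. Merging is iterated to a fixpoint (no output pair qualifies).
Pairwise-merge fixpoints are not unique in adversarial configurations,
so the implementation fixes a canonical procedure: sort the pooled
input, sweep with a backward stack merge, repeat passes until stable.
The result is deterministic and independent of input order. One
consequence worth knowing: an interval nested inside two larger
intervals that do not merge with each other is contained in *two*
output intervals; inputs are never split, but containment is not
always unique.

**Distances.** Region-to-TSS distance is measured from the region
midpoint `⌊(start+end)/2⌋`, unsigned, with ties broken to the lower
TSS position. Strand-aware signed distance is deliberately not used;
reported quantities are unsigned bins. A chromosome with no TSS raises
an explicit no-neighbour error rather than returning zero.

## Thresholds

| parameter | default | meaning |
|---|---|---|
| `merge_frac` | 0.25 | fraction (of the smaller peak / of the reference region) that counts as overlapping; inclusive (≥) |
| `presence_min` | 3 | replicates of a mark required for presence (of 4) |
| `absence_max` | 0 | replicates tolerated for a mark required absent |
| `occupancy_frac` | 0.5 | fraction of a factor peak inside a region to call it bound; strict (>) |
| `conservation_frac` | 0.75 | covered fraction to call a region conserved; strict (>) |
| `promoter_halfwidth` | 500 b | half of the 1 kb promoter window around a TSS |

Comparison strictness follows the wording each rule is stated with:
"at least 25%" is inclusive, "more than 50%" and "more than 75%" are
strict. All three are configurable, as is the occupancy denominator
(factor peak vs region — the factor-peak default reflects that
histone-domain consensus regions are kb-scale while TF peaks are
point-source, so requiring half the *region* would void nearly all
calls) and the promoter window (±500 b vs ±1 kb).

"Presence in 3 or more sample pairs" for the two-mark classes is
interpreted as each mark independently present in ≥ 3 of its 4
replicates. Per-region, per-sample presence makes pair-counting
collapse to per-mark counts, and only this reading is consistent with
the separate "absence in all 4 samples" requirement on the third mark.

## Classification

The reference row space is the merged H3K4me1 peak set — ES replicates
pooled with any external-context compendium — so rows can lack ES
H3K4me1 entirely; that is what makes the `h3k27ac_only` and
`h3k27me3_only` classes observable. The state of a row is a pure
function of its three presence counts (an exhaustive truth-table test
covers all 125 count patterns); `unclassified` is an explicit label
and every downstream fraction states its denominator. With the default
thresholds, `active` and `bivalent` are mutually exclusive by
construction.

## Annotation

Genomic location is decided by the region midpoint with priority
TSS-window > TTS-window > exon > intron > intergenic, so the
categories partition each class. Distance bins are left-closed with
default edges at 5 kb and 50 kb. Gene-group overlap between enhancer
states (via nearest-TSS assignment) and promoter chromatin classes
(supplied in the gene-model table) is scored with an exact
hypergeometric upper tail on the gene universe, Bonferroni-corrected
over the grid.

## Enrichment

The hypergeometric universe is the full promoter-filtered reference
set, not the genome: the test contrasts states *within* the putative
enhancer universe. Tests are one-sided (over-representation);
Bonferroni multiplicity is the number of tests actually performed and
is recorded in the output. The tail probability itself is computed
with scipy's hypergeometric survival function; the test suite checks
it against exhaustive enumeration over the full parameter cube up to
N = 12.

## Dynamics

Context states are computed over the *same* ES reference regions
(never re-merged per tissue), so transition rows are fractions of the
ES groups. Contexts usually carry one replicate per mark, so
`presence_min` is clamped per mark to the available replicate count;
absence still means zero. A region with no mark in a context is
`latent`; a marked region matching no class pattern (possible with a
single replicate, e.g. all three marks) is kept as `unclassified`, so
every transition row sums to 1 over seven labels.

## Synthetic data

The generator emulates the analysed study design: a small genome
(2 × 10 Mb by default) with 400 genes, 800 planted enhancers in the
published class-size ordering (active > H3K4me1-only > bivalent >
H3K27ac-only > H3K27me3-only), 4 replicates per mark, per-replicate
detection probability 0.9, Gaussian boundary jitter (σ = 30 b, width
floor 50 b), uniform background peaks (2/Mb/replicate) avoiding
planted regions, factor peak sets drawn without replacement with
state-biased weights, conserved blocks covering > 75% of a target
share of regions, and one differentiated context in which bivalent
regions resolve (10% stay bivalent, 70% keep only H3K4me1, 20% switch
to H3K27ac). A pan-context H3K4me1 compendium file (a synthetic
stand-in for a multi-tissue peak catalogue) covers every planted
region so all five classes appear in the row space. Planted regions
are mutually disjoint with ≥ 500 b clearance and never touch promoter
windows; bivalent enhancers are anchored 2–20 kb from genes chosen
with 5:1 odds for bivalent-promoter genes, close enough that the
nearest-TSS assignment recovers the planted pairing.

One integer seed drives one named random stream per emission stage
(genes, enhancers, peaks, background, factors, conserved, contexts),
so adding a stage never perturbs earlier stages and a fixed seed
yields byte-identical bundles.

**What passing tests do and do not show.** The generator plants
rectangular, non-overlapping regions with independent per-replicate
dropout and mild boundary noise. Real peak sets have correlated
replicate failures, nested/overlapping domains, copy-number and
mappability artefacts, and promoter-proximal signal bleed; perfect
noise-free recovery and ~0.92 noisy recall on synthetic bundles
validate the *procedure's logic and thresholds*, not expected accuracy
on real chromatin data.

## Validation run sizes

The acceptance checks use: 800 planted regions for noise-free
recovery; 2,000 planted regions (3 × 20 Mb genome) for the
detection-dropout calibration, run without background peaks so the
measured ≥3-of-4 fraction isolates detection noise and is directly
comparable to its binomial closed form 4·0.9³·0.1 + 0.9⁴ ≈ 0.9477;
1,000 regions with 120 null factors (600 tests) for type-I
calibration, run at detection 1.0 so the uniform no-replacement factor
draw is exactly the hypergeometric null; and 1,000 bivalent regions
for transition-row recovery (multinomial sampling error < 0.03 with
high probability at that size).

## Known limitations

- Nearest-TSS gene assignment is the standard heuristic but not a
  contact map; enhancer targets can be skipped genes entirely.
- The midpoint rule for location/distance ignores very wide regions
  straddling several features.
- The merge fixpoint, while canonical and order-independent, is one of
  several defensible conventions (single-pass pairwise merging yields
  slightly different references on adversarial inputs).
- No per-base signal processing: inputs are called peaks only.
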