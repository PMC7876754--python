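# enhancerstates

Consensus calling and chromatin-state classification of putative
enhancers from histone-mark ChIP-seq peaks, with annotation, factor
enrichment and cross-tissue state-dynamics analyses — plus a
synthetic-data generator that plants ground truth so every stage can be
validated end to end.

## The problem

Distal regulatory elements (enhancers) in embryonic stem cells can be
mapped operationally from the chromatin marks they carry: H3K4me1
marks enhancer chromatin generally, H3K27ac marks active regulatory
chromatin, and H3K27me3 marks polycomb-repressed chromatin. A region
carrying H3K4me1 together with H3K27ac is an **active** enhancer; one
carrying H3K4me1 together with H3K27me3 is a **bivalent** (poised,
developmentally primed) enhancer. Calling these states robustly from
several independent ChIP-seq replicates per mark requires a consensus
procedure that tolerates replicate dropout and peak-boundary noise.

`enhancerstates` implements that procedure as a reusable library:

1. **Reference regions.** All H3K4me1 peak files (replicates plus any
   external-context compendium) are pooled and merged: two peaks merge
   when their overlap is ≥ 25% of either peak, iterated to a fixpoint;
   the merged span is the union of the pair. Merged regions within
   500 b of a transcription start site (the 1 kb promoter window) are
   removed.
2. **Presence matrix.** Each reference region × each sample gets a
   binary presence call: 1 when some peak of that sample covers ≥ 25%
   of the region.
3. **State calls.** With per-mark presence counts `(n_k4me1, n_k27ac,
   n_k27me3)` over 4 replicates per mark:
   `active` ⇔ n_k4me1 ≥ 3 ∧ n_k27ac ≥ 3 ∧ n_k27me3 = 0;
   `bivalent` ⇔ n_k4me1 ≥ 3 ∧ n_k27me3 ≥ 3 ∧ n_k27ac = 0;
   `h3k4me1_only` / `h3k27ac_only` / `h3k27me3_only` ⇔ the named mark
   ≥ 3 with the other two absent; everything else `unclassified`.
4. **Characterisation.** Nearest-TSS gene assignment and distance
   bins, genomic-location categories (TSS/TTS window, exon, intron,
   intergenic, decided by region midpoint), conservation status
   (> 75% covered by conserved blocks), gene-level overlap between
   enhancer groups and promoter chromatin classes, factor occupancy
   (> 50% of the factor peak inside the region) with exact
   hypergeometric enrichment per state and Bonferroni correction, and
   re-classification of the same regions in other tissue contexts to
   produce state-transition fractions.

## Worked example

```bash
python examples/01_simulate_and_classify.py
```

```
state           planted  called
active              300     274
bivalent            150     132
h3k4me1_only        240     228
h3k27ac_only         60      55
h3k27me3_only        50      45
unclassified          0     233

overall recall vs planted truth: 0.917
```

The generator plants 800 enhancers with known states and emits 4
replicate peak files per mark in which each truly-marked region is
detected with probability 0.9. Called counts sit slightly below the
planted counts because a class call needs the mark in ≥ 3 of 4
replicates; the shortfall lands in `unclassified` (never in a wrong
class — precision stays 1.0), matching the binomial expectation
4·0.9³·0.1 + 0.9⁴ ≈ 0.948 per required mark.

`examples/02_annotation.py`, `examples/03_factor_enrichment.py` and
`examples/04_state_dynamics.py` walk through the annotation grid (the
planted bivalent-enhancer/bivalent-promoter gene association surfaces
with adjusted p ≈ 5×10⁻⁹), factor enrichment (each planted factor
ranks its preferred state first; null factors stay at p ≈ 1), and
cross-context dynamics (≈ 10% of bivalent enhancers retain bivalency
in the differentiated context, the rest mostly fall back to
H3K4me1-only).

A thin CLI mirrors the library:

```bash
enhancerstates simulate --seed 42 --out ws/
enhancerstates all --workspace ws/ --out results/
```

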