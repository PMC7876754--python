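"""Synthetic data generator with planted ground truth.

Emits a complete input bundle — genome layout, gene models with TSSs
and promoter chromatin classes, planted enhancer regions with true
states, noisy per-sample peak BED files, factor peak sets with planted
state preferences, conserved blocks, and per-context peak sets — in
exactly the formats the pipeline consumes, together with truth tables.

What it emulates: detection dropout (each truly-marked region yields a
peak in each replicate independently with ``detection_prob``), peak
boundary jitter (rounded Gaussian noise on both endpoints), uniform
background peaks, factor binding biased towards a preferred state by an
odds ratio, and per-context state switching for the dynamics analysis.
A pan-context H3K4me1 "compendium" file (synthetic stand-in for a
multi-tissue H3K4me1 catalogue) seeds the reference row space so that
regions lacking ES H3K4me1 — the H3K27ac-only and H3K27me3-only
classes — still appear as matrix rows.

What it does not emulate: read-level ChIP-seq noise, peak-caller
statistics, mappability, or realistic genome annotation density.

Randomness is organised as one named stream per emission stage, all
derived from the single config seed, so adding a stage never perturbs
the output of earlier stages.
"""

from __future__ import annotations

import dataclasses
import json
from bisect import bisect_left, insort
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .intervals import GenomicInterval, IntervalSet, overlap_bp
from .io import Mark, write_bed, write_tss_table, TSSRecord, TSSTable
from .states import MARKS_BY_STATE, NAMED_STATES, State

__all__ = [
    "FactorSpec",
    "SimulationConfig",
    "PlantedRegion",
    "TruthBundle",
    "Workspace",
    "generate_dataset",
    "truth_recovery_report",
]

_STREAMS = {
    "genes": 1,
    "enhancers": 2,
    "peaks": 3,
    "background": 4,
    "factors": 5,
    "conserved": 6,
    "contexts": 7,
}

PROMOTER_CLASSES = ("bivalent", "active", "h3k27me3_only", "latent")


@dataclass(frozen=True)
class FactorSpec:
    """One simulated factor: number of peaks and optional state preference."""

    factor_id: str
    preferred_state: State | None = None
    odds_ratio: float = 1.0
    n_peaks: int = 300
    peak_width: int = 200


def _default_factors() -> list[FactorSpec]:
    return [
        FactorSpec("tf_active_a", State.ACTIVE, 5.0),
        FactorSpec("tf_active_b", State.ACTIVE, 5.0),
        FactorSpec("tf_bivalent", State.BIVALENT, 8.0),
        FactorSpec("tf_k4me1", State.K4ME1_ONLY, 3.0),
        FactorSpec("tf_null_a"),
        FactorSpec("tf_null_b"),
    ]


def _default_counts() -> dict[State, int]:
    # Scaled-down analogue of the published class-size ordering
    # (active > h3k4me1-only > bivalent > h3k27ac-only > h3k27me3-only).
    return {
        State.ACTIVE: 300,
        State.K4ME1_ONLY: 240,
        State.BIVALENT: 150,
        State.K27AC_ONLY: 60,
        State.K27ME3_ONLY: 50,
    }


def _default_transitions() -> dict[str, dict[State, dict[State, float]]]:
    # One differentiated context in which most bivalent regions resolve:
    # ~10% retain bivalency, most keep H3K4me1 only, a minority activate.
    return {
        "tissue": {
            State.BIVALENT: {
                State.BIVALENT: 0.10,
                State.K4ME1_ONLY: 0.70,
                State.K27AC_ONLY: 0.20,
            },
            State.ACTIVE: {
                State.ACTIVE: 0.40,
                State.K4ME1_ONLY: 0.35,
                State.LATENT: 0.25,
            },
        }
    }


@dataclass
class SimulationConfig:
    """Study-design parameters of a synthetic bundle.

    Defaults mirror the analysed design: 4 replicates per histone mark,
    ~90% per-replicate detection of a truly-marked region, tens of
    planted enhancers per Mb with kb-scale widths, and a handful of
    factors with known state preferences.
    """

    seed: int = 0
    n_chromosomes: int = 2
    chrom_length: int = 10_000_000
    n_genes: int = 400
    n_enhancers_per_state: dict[State, int] = field(default_factory=_default_counts)
    enhancer_width: tuple[int, int] = (600, 2000)
    samples_per_mark: int = 4
    detection_prob: float = 0.9
    boundary_jitter_sd: float = 30.0
    background_peak_rate: float = 2.0  # peaks per Mb per sample
    factor_specs: list[FactorSpec] = field(default_factory=_default_factors)
    conserved_fraction_target: float = 0.55
    promoter_class_probs: dict[str, float] = field(
        default_factory=lambda: {
            "bivalent": 0.15, "active": 0.45, "h3k27me3_only": 0.10, "latent": 0.30
        }
    )
    bivalent_near_bivalent_gene_odds: float = 5.0
    context_transition_spec: dict[str, dict[State, dict[State, float]]] = field(
        default_factory=_default_transitions
    )
    context_samples_per_mark: int = 1
    context_detection_prob: float = 1.0
    context_jitter_sd: float = 0.0
    promoter_halfwidth: int = 500
    min_region_gap: int = 500  # clearance between planted regions
    min_peak_width: int = 50  # width floor enforced after jitter

    def validate(self) -> None:
        for p in (self.detection_prob, self.context_detection_prob):
            if not 0 <= p <= 1:
                raise ValueError("detection probabilities must lie in [0, 1]")
        if self.enhancer_width[0] <= 0 or self.enhancer_width[0] > self.enhancer_width[1]:
            raise ValueError("enhancer_width must be a positive (min, max) pair")
        if min(self.n_enhancers_per_state.values(), default=1) < 0:
            raise ValueError("enhancer counts must be non-negative")
        for ctx in self.context_transition_spec.values():
            for src, row in ctx.items():
                tot = sum(row.values())
                if tot > 1 + 1e-9:
                    raise ValueError(f"transition row for {src} sums to {tot} > 1")

    def rng(self, stage: str) -> np.random.Generator:
        return np.random.default_rng([self.seed, _STREAMS[stage]])

    def chrom_names(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(self.n_chromosomes)]


@dataclass(frozen=True)
class PlantedRegion:
    region_id: str
    interval: GenomicInterval
    state: State


@dataclass
class TruthBundle:
    """Ground truth for a generated bundle, serialisable to TSV."""

    regions: list[PlantedRegion]
    gene_classes: dict[str, str]  # gene_id -> promoter class
    factor_prefs: list[FactorSpec]
    transitions: pd.DataFrame  # region_id, context, source_state, target_state

    def regions_by_state(self) -> dict[State, list[PlantedRegion]]:
        out: dict[State, list[PlantedRegion]] = {s: [] for s in NAMED_STATES}
        for pr in self.regions:
            out[pr.state].append(pr)
        return out

    def save(self, truth_dir: Path) -> None:
        truth_dir.mkdir(parents=True, exist_ok=True)
        pd.DataFrame(
            [
                {
                    "region_id": pr.region_id,
                    "chrom": pr.interval.chrom,
                    "start": pr.interval.start,
                    "end": pr.interval.end,
                    "state": pr.state.value,
                }
                for pr in self.regions
            ]
        ).to_csv(truth_dir / "regions.tsv", sep="\t", index=False)
        pd.DataFrame(
            sorted(self.gene_classes.items()), columns=["gene_id", "promoter_class"]
        ).to_csv(truth_dir / "gene_classes.tsv", sep="\t", index=False)
        pd.DataFrame(
            [
                {
                    "factor_id": f.factor_id,
                    "preferred_state": f.preferred_state.value if f.preferred_state else "",
                    "odds_ratio": f.odds_ratio,
                    "n_peaks": f.n_peaks,
                }
                for f in self.factor_prefs
            ]
        ).to_csv(truth_dir / "factors.tsv", sep="\t", index=False)
        self.transitions.to_csv(truth_dir / "transitions.tsv", sep="\t", index=False)

    @classmethod
    def load(cls, truth_dir: Path) -> "TruthBundle":
        rdf = pd.read_csv(truth_dir / "regions.tsv", sep="\t")
        regions = [
            PlantedRegion(
                row.region_id,
                GenomicInterval(row.chrom, int(row.start), int(row.end)),
                State(row.state),
            )
            for row in rdf.itertuples()
        ]
        gdf = pd.read_csv(truth_dir / "gene_classes.tsv", sep="\t")
        fdf = pd.read_csv(truth_dir / "factors.tsv", sep="\t", keep_default_na=False)
        prefs = [
            FactorSpec(
                row.factor_id,
                State(row.preferred_state) if row.preferred_state else None,
                float(row.odds_ratio),
                int(row.n_peaks),
            )
            for row in fdf.itertuples()
        ]
        tdf = pd.read_csv(truth_dir / "transitions.tsv", sep="\t")
        return cls(regions, dict(zip(gdf.gene_id, gdf.promoter_class)), prefs, tdf)


@dataclass
class Workspace:
    """Paths of a generated input bundle."""

    root: Path
    manifest: Path
    tss_table: Path
    compendium: Path
    factor_beds: dict[str, Path]
    conserved: Path
    context_manifest: Path
    truth_dir: Path


class _Packer:
    """Tracks occupied intervals per chromosome for collision-free placement."""

    def __init__(self) -> None:
        self._by_chrom: dict[str, list[tuple[int, int]]] = {}

    def collides(self, chrom: str, start: int, end: int, margin: int) -> bool:
        lst = self._by_chrom.get(chrom, [])
        i = bisect_left(lst, (start - margin,))
        for j in (i - 1, i):
            if 0 <= j < len(lst):
                s, e = lst[j]
                if s < end + margin and start - margin < e:
                    return True
        return False

    def add(self, chrom: str, start: int, end: int) -> None:
        insort(self._by_chrom.setdefault(chrom, []), (start, end))


def _make_genes(config: SimulationConfig) -> TSSTable:
    rng = config.rng("genes")
    per_chrom = config.n_genes // config.n_chromosomes
    records: list[TSSRecord] = []
    classes = list(config.promoter_class_probs)
    probs = np.array([config.promoter_class_probs[c] for c in classes], dtype=float)
    probs = probs / probs.sum()
    gid = 0
    for chrom in config.chrom_names():
        spacing = config.chrom_length / (per_chrom + 1)
        for i in range(per_chrom):
            anchor = int((i + 1) * spacing + rng.integers(-spacing // 4, spacing // 4 + 1))
            strand = "+" if rng.random() < 0.5 else "-"
            length = int(rng.integers(2000, 20001))
            if strand == "+":
                span = GenomicInterval(chrom, anchor, min(anchor + length, config.chrom_length))
                tss = span.start
            else:
                span = GenomicInterval(chrom, max(0, anchor - length + 1), anchor + 1)
                tss = span.end - 1
            exons: list[GenomicInterval] = []
            n_ex = int(rng.integers(2, 7))
            offsets = np.sort(rng.integers(0, max(1, span.width - 400), size=n_ex))
            last_end = span.start
            for off in offsets:
                s = span.start + int(off)
                if s < last_end:
                    continue
                e = min(s + int(rng.integers(100, 401)), span.end)
                if e > s:
                    exons.append(GenomicInterval(chrom, s, e))
                    last_end = e
            records.append(
                TSSRecord(
                    gene_id=f"gene{gid:04d}",
                    chrom=chrom,
                    tss=tss,
                    strand=strand,
                    span=span,
                    exons=tuple(exons),
                    promoter_class=str(rng.choice(classes, p=probs)),
                )
            )
            gid += 1
    return TSSTable(records)


def _plant_enhancers(
    config: SimulationConfig, tss: TSSTable
) -> list[PlantedRegion]:
    rng = config.rng("enhancers")
    promoters = tss.promoter_windows(config.promoter_halfwidth)
    packer = _Packer()
    genes = list(tss)
    biv_weights = np.array(
        [
            config.bivalent_near_bivalent_gene_odds if g.promoter_class == "bivalent" else 1.0
            for g in genes
        ]
    )
    biv_weights = biv_weights / biv_weights.sum()
    wmin, wmax = config.enhancer_width
    planted: list[PlantedRegion] = []
    rid = 0
    for state in NAMED_STATES:
        for _ in range(config.n_enhancers_per_state.get(state, 0)):
            placed = False
            for attempt in range(400):
                width = int(rng.integers(wmin, wmax + 1))
                if attempt < 200:
                    if state is State.BIVALENT:
                        g = genes[int(rng.choice(len(genes), p=biv_weights))]
                    else:
                        g = genes[int(rng.integers(0, len(genes)))]
                    # stay inside the anchor gene's neighbourhood so the
                    # nearest-TSS assignment recovers the planted pairing
                    d = int(rng.integers(2000, 20001))
                    side = 1 if rng.random() < 0.5 else -1
                    start = g.tss + side * d
                    chrom = g.chrom
                else:  # fall back to uniform placement
                    chrom = config.chrom_names()[int(rng.integers(0, config.n_chromosomes))]
                    start = int(rng.integers(0, config.chrom_length - width))
                end = start + width
                if start < 0 or end > config.chrom_length:
                    continue
                cand = GenomicInterval(chrom, start, end)
                if packer.collides(chrom, start, end, config.min_region_gap):
                    continue
                if promoters.overlappers(cand):
                    continue
                packer.add(chrom, start, end)
                planted.append(PlantedRegion(f"enh{rid:05d}", cand, state))
                rid += 1
                placed = True
                break
            if not placed:
                raise RuntimeError(
                    "infeasible packing: could not place all planted enhancers; "
                    "reduce counts or enlarge the genome"
                )
    return planted


def _jitter_interval(
    iv: GenomicInterval,
    rng: np.random.Generator,
    sd: float,
    chrom_length: int,
    min_width: int,
) -> GenomicInterval:
    if sd > 0:
        ds = int(round(rng.normal(0, sd)))
        de = int(round(rng.normal(0, sd)))
    else:
        ds = de = 0
    s, e = iv.start + ds, iv.end + de
    if e - s < min_width:
        mid = (s + e) // 2
        s, e = mid - min_width // 2, mid - min_width // 2 + min_width
    s = max(0, s)
    e = min(chrom_length, max(e, s + min_width))
    return GenomicInterval(iv.chrom, s, e)


def _emit_mark_samples(
    planted: Sequence[PlantedRegion],
    mark: Mark,
    n_samples: int,
    detection_prob: float,
    jitter_sd: float,
    config: SimulationConfig,
    rng: np.random.Generator,
    bg_rng: np.random.Generator | None,
    out_dir: Path,
    prefix: str,
) -> list[Path]:
    carriers = [pr for pr in planted if mark.value in MARKS_BY_STATE[pr.state]]
    paths = []
    for s in range(n_samples):
        intervals: list[GenomicInterval] = []
        names: list[str] = []
        for pr in carriers:
            if rng.random() < detection_prob:
                intervals.append(
                    _jitter_interval(
                        pr.interval, rng, jitter_sd, config.chrom_length,
                        config.min_peak_width,
                    )
                )
                names.append(pr.region_id)
        if bg_rng is not None and config.background_peak_rate > 0:
            for chrom in config.chrom_names():
                n_bg = bg_rng.poisson(
                    config.background_peak_rate * config.chrom_length / 1e6
                )
                for _ in range(n_bg):
                    for _try in range(50):
                        width = int(bg_rng.integers(*config.enhancer_width))
                        start = int(bg_rng.integers(0, config.chrom_length - width))
                        cand = GenomicInterval(chrom, start, start + width)
                        if not any(
                            overlap_bp(cand, pr.interval) for pr in planted
                            if pr.interval.chrom == chrom
                        ):
                            intervals.append(cand)
                            names.append("background")
                            break
        order = sorted(range(len(intervals)), key=lambda i: (
            intervals[i].chrom, intervals[i].start, intervals[i].end))
        path = out_dir / f"{prefix}_{mark.value}_r{s + 1}.bed"
        write_bed([intervals[i] for i in order], path, [names[i] for i in order])
        paths.append(path)
    return paths


def generate_dataset(
    config: SimulationConfig, out_dir: str | Path
) -> tuple[Workspace, TruthBundle]:
    """Materialise a full synthetic workspace; deterministic for a fixed seed."""
    config.validate()
    root = Path(out_dir)
    (root / "peaks").mkdir(parents=True, exist_ok=True)
    (root / "factors").mkdir(exist_ok=True)
    (root / "contexts").mkdir(exist_ok=True)

    tss = _make_genes(config)
    write_tss_table(tss, root / "tss_table.tsv")
    planted = _plant_enhancers(config, tss)

    # ES replicate peak files, one stream for detections, one for background
    peak_rng = config.rng("peaks")
    bg_rng = config.rng("background")
    manifest_samples = []
    for mark in (Mark.H3K4ME1, Mark.H3K27AC, Mark.H3K27ME3):
        paths = _emit_mark_samples(
            planted, mark, config.samples_per_mark, config.detection_prob,
            config.boundary_jitter_sd, config, peak_rng, bg_rng,
            root / "peaks", "ES",
        )
        for i, p in enumerate(paths):
            manifest_samples.append(
                {
                    "path": str(p.relative_to(root)),
                    "sample_id": f"ES_{mark.value}_r{i + 1}",
                    "mark": mark.value,
                    "context": "ES",
                }
            )

    # pan-context H3K4me1 compendium seeding the reference row space
    compendium = root / "peaks" / "compendium_H3K4me1.bed"
    write_bed([pr.interval for pr in planted], compendium,
              [pr.region_id for pr in planted])

    manifest = root / "manifest.yaml"
    with manifest.open("w") as fh:
        yaml.safe_dump(
            {"samples": manifest_samples, "thresholds": {}},
            fh, sort_keys=False,
        )

    # factor peaks: weighted draw of target regions without replacement
    f_rng = config.rng("factors")
    factor_beds: dict[str, Path] = {}
    for spec in config.factor_specs:
        weights = np.array(
            [
                spec.odds_ratio if pr.state is spec.preferred_state else 1.0
                for pr in planted
            ]
        )
        weights = weights / weights.sum()
        n_pick = min(spec.n_peaks, len(planted))
        chosen = f_rng.choice(len(planted), size=n_pick, replace=False, p=weights)
        intervals = []
        for idx in sorted(int(i) for i in chosen):
            reg = planted[idx].interval
            pw = min(spec.peak_width, reg.width - 2)
            off = int(f_rng.integers(0, reg.width - pw + 1))
            intervals.append(GenomicInterval(reg.chrom, reg.start + off, reg.start + off + pw))
        path = root / "factors" / f"{spec.factor_id}.bed"
        write_bed(sorted(intervals, key=lambda iv: (iv.chrom, iv.start)), path)
        factor_beds[spec.factor_id] = path

    # conserved blocks: covered fraction > 0.75 for the target share of regions
    c_rng = config.rng("conserved")
    blocks: list[GenomicInterval] = []
    for pr in planted:
        u = c_rng.random()
        w = pr.interval.width
        if u < config.conserved_fraction_target:
            frac = c_rng.uniform(0.80, 1.0)
        elif u < (1 + config.conserved_fraction_target) / 2:
            frac = c_rng.uniform(0.10, 0.60)
        else:
            continue
        c = max(1, int(round(frac * w)))
        off = int(c_rng.integers(0, w - c + 1))
        blocks.append(
            GenomicInterval(pr.interval.chrom, pr.interval.start + off,
                            pr.interval.start + off + c)
        )
    conserved = root / "conserved.bed"
    write_bed(sorted(blocks, key=lambda iv: (iv.chrom, iv.start)), conserved)

    # context peak sets with planted state transitions
    ctx_rng = config.rng("contexts")
    transitions_rows = []
    context_doc: dict[str, dict[str, list[str]]] = {}
    for ctx_name, spec in config.context_transition_spec.items():
        targets: list[PlantedRegion] = []
        for pr in planted:
            row = spec.get(pr.state)
            if row:
                labels = list(row)
                probs = np.array([row[t] for t in labels], dtype=float)
                rest = 1.0 - probs.sum()
                if rest > 1e-9:
                    labels.append(pr.state)
                    probs = np.append(probs, rest)
                probs = probs / probs.sum()
                target = labels[int(ctx_rng.choice(len(labels), p=probs))]
            else:
                target = pr.state
            targets.append(PlantedRegion(pr.region_id, pr.interval, target))
            transitions_rows.append(
                {
                    "region_id": pr.region_id,
                    "context": ctx_name,
                    "source_state": pr.state.value,
                    "target_state": target.value,
                }
            )
        context_doc[ctx_name] = {}
        for mark in (Mark.H3K4ME1, Mark.H3K27AC, Mark.H3K27ME3):
            paths = _emit_mark_samples(
                targets, mark, config.context_samples_per_mark,
                config.context_detection_prob, config.context_jitter_sd,
                config, ctx_rng, None, root / "contexts", ctx_name,
            )
            context_doc[ctx_name][mark.value] = [str(p.relative_to(root)) for p in paths]
    context_manifest = root / "contexts.yaml"
    with context_manifest.open("w") as fh:
        yaml.safe_dump(context_doc, fh, sort_keys=True)

    truth = TruthBundle(
        regions=planted,
        gene_classes={r.gene_id: r.promoter_class or "latent" for r in tss},
        factor_prefs=list(config.factor_specs),
        transitions=pd.DataFrame(
            transitions_rows,
            columns=["region_id", "context", "source_state", "target_state"],
        ),
    )
    truth.save(root / "truth")
    with (root / "truth" / "config.json").open("w") as fh:
        json.dump(_config_to_json(config), fh, indent=2, sort_keys=True)

    ws = Workspace(
        root=root,
        manifest=manifest,
        tss_table=root / "tss_table.tsv",
        compendium=compendium,
        factor_beds=factor_beds,
        conserved=conserved,
        context_manifest=context_manifest,
        truth_dir=root / "truth",
    )
    return ws, truth


def _config_to_json(config: SimulationConfig) -> dict:
    def conv(obj):
        if isinstance(obj, State):
            return obj.value
        if isinstance(obj, dict):
            return {conv(k): conv(v) for k, v in obj.items()}
        if isinstance(obj, (list, tuple)):
            return [conv(x) for x in obj]
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return conv(dataclasses.asdict(obj))
        return obj

    return conv(dataclasses.asdict(config))


def match_calls_to_truth(
    truth: TruthBundle, calls: Sequence
) -> tuple[dict[str, int], dict[int, str]]:
    """Match planted regions to called reference regions by maximal overlap.

    A planted region matches the call region with the largest overlap,
    provided that overlap covers at least half the planted width.
    Returns (planted id → call index, call index → planted id); a call
    region absorbing several planted regions is left unmatched in the
    reverse map (ambiguous).
    """
    call_set = IntervalSet([c.region for c in calls])
    index_of = {c.region: i for i, c in enumerate(calls)}
    fwd: dict[str, int] = {}
    rev_count: dict[int, list[str]] = {}
    for pr in truth.regions:
        best_i, best_ov = None, 0
        for reg in call_set.overlappers(pr.interval):
            ov = overlap_bp(pr.interval, reg)
            if ov > best_ov:
                best_ov, best_i = ov, index_of[reg]
        if best_i is not None and best_ov >= 0.5 * pr.interval.width:
            fwd[pr.region_id] = best_i
            rev_count.setdefault(best_i, []).append(pr.region_id)
    rev = {i: ids[0] for i, ids in rev_count.items() if len(ids) == 1}
    return fwd, rev


def truth_recovery_report(
    truth: TruthBundle,
    calls: Sequence,
    enrichment_records: Sequence | None = None,
    transition_df: pd.DataFrame | None = None,
) -> dict:
    """Compare pipeline outputs against the planted truth.

    Returns per-state precision/recall for the classification, the rank
    of each preference-planted factor's preferred state by adjusted p,
    and per-(context, source) maximum absolute transition-row error.
    """
    if not truth.regions:
        raise ValueError("truth bundle contains no planted regions")
    fwd, rev = match_calls_to_truth(truth, calls)
    state_of_planted = {pr.region_id: pr.state for pr in truth.regions}

    per_state: dict[str, dict[str, float]] = {}
    for state in NAMED_STATES:
        planted_ids = [pr.region_id for pr in truth.regions if pr.state is state]
        n_recovered = sum(
            1
            for rid in planted_ids
            if rid in fwd and calls[fwd[rid]].state is state
        )
        called_idx = [i for i, c in enumerate(calls) if c.state is state]
        n_correct_calls = sum(
            1 for i in called_idx if i in rev and state_of_planted[rev[i]] is state
        )
        per_state[state.value] = {
            "n_planted": len(planted_ids),
            "n_called": len(called_idx),
            "recall": n_recovered / len(planted_ids) if planted_ids else float("nan"),
            "precision": (
                n_correct_calls / len(called_idx) if called_idx else float("nan")
            ),
        }
    matched = [(rid, i) for rid, i in fwd.items()]
    overall_recall = (
        sum(1 for rid, i in matched if calls[i].state is state_of_planted[rid])
        / len(truth.regions)
    )
    report: dict = {"per_state": per_state, "overall_recall": overall_recall}

    if enrichment_records is not None:
        ranks = {}
        by_factor: dict[str, list] = {}
        for r in enrichment_records:
            by_factor.setdefault(r.factor_id, []).append(r)
        for spec in truth.factor_prefs:
            if spec.preferred_state is None or spec.factor_id not in by_factor:
                continue
            recs = sorted(by_factor[spec.factor_id], key=lambda r: (r.p_adjusted, r.p_value))
            rank = next(
                (i + 1 for i, r in enumerate(recs) if r.state is spec.preferred_state),
                None,
            )
            ranks[spec.factor_id] = rank
        report["preferred_state_rank"] = ranks

    if transition_df is not None and len(truth.transitions):
        errors = {}
        for (ctx, src), grp in truth.transitions.groupby(["context", "source_state"]):
            true_row = grp["target_state"].value_counts(normalize=True)
            obs = transition_df[
                (transition_df["context"] == ctx)
                & (transition_df["source_state"] == src)
            ].set_index("target_state")["fraction"]
            labels = set(true_row.index) | set(obs.index)
            err = max(
                abs(float(true_row.get(lab, 0.0)) - float(obs.get(lab, 0.0)))
                for lab in labels
            )
            errors[f"{ctx}:{src}"] = err
        report["transition_max_abs_error"] = errors
    return report
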