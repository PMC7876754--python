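"""End-to-end orchestration over a workspace directory.

A workspace is a directory holding ``manifest.yaml`` (ES replicate peak
files), ``tss_table.tsv``, and optionally
``peaks/compendium_H3K4me1.bed`` (external-context H3K4me1 seeding the
reference row space), ``factors/*.bed``, ``conserved.bed`` and
``contexts.yaml``.  Stages communicate only via files on disk; each
stage is independently callable from the library, and every output
table carries a provenance header (package version, thresholds, input
hashes).
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml

from . import __version__
from .annotate import (
    annotate_locations,
    assign_nearest_gene,
    bin_distances,
    conservation_status,
    gene_group_overlap,
    DISTANCE_BIN_LABELS,
)
from .classify import (
    RegionSampleMatrix,
    StateCall,
    build_matrix,
    build_reference_regions,
    classify_all,
    filter_promoter_regions,
)
from .dynamics import classify_in_context, transition_fractions
from .enrichment import (
    EnrichmentRecord,
    enrich_factors,
    enrichment_table,
    factor_count_per_region,
    occupancy,
)
from .intervals import IntervalSet
from .io import (
    Mark,
    PeakSet,
    SampleManifest,
    TSSTable,
    Thresholds,
    read_bed,
    read_manifest,
    read_tss_table,
    write_bed,
    write_table,
)
from .states import NAMED_STATES, State

log = logging.getLogger("enhancerstates")

__all__ = ["PipelineResult", "run_classify", "run_annotate", "run_enrich",
           "run_dynamics", "run_pipeline"]


@dataclass
class PipelineResult:
    thresholds: Thresholds
    matrix: RegionSampleMatrix
    calls: list[StateCall]
    state_counts: dict[State, int]
    n_promoter_filtered: int
    annotations: pd.DataFrame | None = None
    mean_regions_per_gene: float | None = None
    gene_overlap: pd.DataFrame | None = None
    enrichment_records: list[EnrichmentRecord] = field(default_factory=list)
    factor_counts: pd.DataFrame | None = None
    transitions: pd.DataFrame | None = None


def _hash_file(path: Path) -> str:
    h = hashlib.sha256()
    with path.open("rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()[:12]


def _provenance(thr: Thresholds, inputs: Sequence[Path]) -> list[str]:
    lines = [f"enhancerstates {__version__}", f"thresholds: {thr}"]
    lines += [f"input {p.name} sha256:{_hash_file(p)}" for p in inputs]
    return lines


def run_classify(
    manifest: SampleManifest,
    tss: TSSTable,
    extra_h3k4me1: Sequence[IntervalSet] = (),
) -> tuple[RegionSampleMatrix, list[StateCall], dict[State, int], int]:
    """Reference building, promoter filtering, matrix and state calls."""
    thr = manifest.thresholds
    peaksets = manifest.load_peaksets()
    k4me1 = [ps for ps in peaksets if ps.mark is Mark.H3K4ME1]
    reference = build_reference_regions(
        list(k4me1) + list(extra_h3k4me1), thr.merge_frac
    )
    filtered, n_removed = filter_promoter_regions(reference, tss, thr.promoter_halfwidth)
    log.info(
        "reference: %d merged regions, %d removed at promoters, %d kept",
        len(reference), n_removed, len(filtered),
    )
    matrix = build_matrix(filtered, peaksets, thr.merge_frac)
    calls, tally = classify_all(matrix, thr)
    return matrix, calls, tally, n_removed


def run_annotate(
    calls: Sequence[StateCall],
    tss: TSSTable,
    conserved: IntervalSet | None = None,
    thresholds: Thresholds | None = None,
) -> tuple[pd.DataFrame, float, pd.DataFrame | None]:
    """Per-region annotation table, mean regions/gene, gene-group overlap."""
    thr = thresholds or Thresholds()
    regions = [c.region for c in calls]
    assignments, mean_per_gene = assign_nearest_gene(regions, tss)
    locations = annotate_locations(regions, tss)
    rows = []
    cons_flags: list[bool] | None = None
    cons_fracs: list[float] | None = None
    if conserved is not None:
        cons_flags, cons_fracs = conservation_status(
            regions, conserved, thr.conservation_frac
        )
    for i, (c, ga, loc) in enumerate(zip(calls, assignments, locations)):
        rows.append(
            {
                "chrom": c.region.chrom,
                "start": c.region.start,
                "end": c.region.end,
                "state": c.state.value,
                "nearest_gene": ga.gene_id,
                "distance_bp": ga.distance,
                "location": loc,
                "conserved": cons_flags[i] if cons_flags is not None else None,
                "conserved_fraction": cons_fracs[i] if cons_fracs is not None else None,
            }
        )
    annotations = pd.DataFrame(rows).sort_values(["chrom", "start", "end"]).reset_index(
        drop=True
    )

    overlap = None
    promoter_classes: dict[str, set[str]] = {}
    for r in tss:
        if r.promoter_class:
            promoter_classes.setdefault(r.promoter_class, set()).add(r.gene_id)
    if promoter_classes:
        enh_sets: dict[State, set[str]] = {}
        for c, ga in zip(calls, assignments):
            if c.state in NAMED_STATES and ga.gene_id is not None:
                enh_sets.setdefault(c.state, set()).add(ga.gene_id)
        if enh_sets:
            overlap = gene_group_overlap(enh_sets, promoter_classes, tss.gene_ids())
    return annotations, mean_per_gene, overlap


def run_enrich(
    calls: Sequence[StateCall],
    factor_beds: dict[str, Path],
    thresholds: Thresholds | None = None,
) -> tuple[list[EnrichmentRecord], pd.DataFrame]:
    """Occupancy calls, per-region factor counts, and enrichment records."""
    thr = thresholds or Thresholds()
    regions = [c.region for c in calls]
    factor_sets = {fid: read_bed(p) for fid, p in sorted(factor_beds.items())}
    bound = {
        fid: occupancy(regions, peaks, thr.occupancy_frac)
        for fid, peaks in factor_sets.items()
    }
    records = enrich_factors(list(calls), bound)
    counts = factor_count_per_region(regions, factor_sets, thr.occupancy_frac)
    fc = pd.DataFrame(
        {
            "chrom": [r.chrom for r in regions],
            "start": [r.start for r in regions],
            "end": [r.end for r in regions],
            "state": [c.state.value for c in calls],
            "n_factors": counts,
        }
    )
    return records, fc


def run_dynamics(
    calls: Sequence[StateCall],
    context_files: dict[str, dict[str, list[Path]]],
    thresholds: Thresholds | None = None,
) -> pd.DataFrame:
    """Per-context re-classification of the reference regions and
    transition-fraction rows (long format)."""
    thr = thresholds or Thresholds()
    regions = IntervalSet([c.region for c in calls])
    es_states = [c.state for c in calls]
    frames = []
    for ctx_name in sorted(context_files):
        peaksets = []
        for mark_name, paths in sorted(context_files[ctx_name].items()):
            mark = Mark.parse(mark_name)
            for i, p in enumerate(paths):
                peaksets.append(
                    PeakSet(f"{ctx_name}_{mark.value}_r{i + 1}", mark, ctx_name,
                            read_bed(Path(p)))
                )
        ctx_states = classify_in_context(regions, peaksets, thr)
        frames.append(transition_fractions(es_states, ctx_states, ctx_name))
    return pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()


def _state_summary(
    calls: Sequence[StateCall], annotations: pd.DataFrame
) -> pd.DataFrame:
    rows = []
    for state in list(NAMED_STATES) + [State.UNCLASSIFIED]:
        sub = annotations[annotations["state"] == state.value]
        if len(sub) == 0:
            continue
        row = {"state": state.value, "n_regions": len(sub)}
        bins = bin_distances([d for d in sub["distance_bp"] if pd.notna(d)])
        row.update({f"dist_{k}": v for k, v in bins.items()})
        for loc in ("intergenic", "intron", "exon", "tss_5prime", "tts_3prime"):
            row[f"loc_{loc}"] = float((sub["location"] == loc).mean())
        if sub["conserved"].notna().any():
            row["conserved_fraction"] = float(sub["conserved"].astype(bool).mean())
        rows.append(row)
    return pd.DataFrame(rows)


def run_pipeline(
    workspace: str | Path,
    out_dir: str | Path,
    thresholds: Thresholds | None = None,
) -> PipelineResult:
    """Run every stage available in the workspace and write result tables."""
    root = Path(workspace)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    manifest = read_manifest(root / "manifest.yaml")
    if thresholds is not None:
        manifest.thresholds = thresholds
        manifest.validate()
    thr = manifest.thresholds
    tss = read_tss_table(root / "tss_table.tsv")
    inputs = [root / "manifest.yaml", root / "tss_table.tsv"]

    compendium_path = root / "peaks" / "compendium_H3K4me1.bed"
    extra = []
    if compendium_path.exists():
        extra.append(read_bed(compendium_path))
        inputs.append(compendium_path)

    matrix, calls, tally, n_removed = run_classify(manifest, tss, extra)
    prov = _provenance(thr, inputs)

    # per-state BED files and summary tables
    for state in list(NAMED_STATES) + [State.UNCLASSIFIED]:
        regs = [c.region for c in calls if c.state is state]
        write_bed(regs, out / f"regions_{state.value}.bed", [state.value] * len(regs))
    counts_df = pd.DataFrame(
        [{"state": s.value, "n_regions": n} for s, n in tally.items()]
    )
    write_table(counts_df, out / "state_counts.tsv", prov)
    mat_df = pd.DataFrame(
        matrix.presence,
        columns=[sid for sid, _ in matrix.samples],
    )
    mat_df.insert(0, "chrom", [r.chrom for r in matrix.regions])
    mat_df.insert(1, "start", [r.start for r in matrix.regions])
    mat_df.insert(2, "end", [r.end for r in matrix.regions])
    write_table(mat_df, out / "region_sample_matrix.tsv", prov)

    conserved = None
    if (root / "conserved.bed").exists():
        conserved = read_bed(root / "conserved.bed")
    annotations, mean_per_gene, gene_overlap = run_annotate(calls, tss, conserved, thr)
    write_table(annotations, out / "annotations.tsv", prov)
    write_table(_state_summary(calls, annotations), out / "state_summary.tsv", prov)
    if gene_overlap is not None:
        write_table(gene_overlap, out / "gene_group_overlap.tsv", prov)

    records: list[EnrichmentRecord] = []
    factor_counts = None
    factor_dir = root / "factors"
    factor_beds = (
        {p.stem: p for p in sorted(factor_dir.glob("*.bed"))}
        if factor_dir.is_dir()
        else {}
    )
    if factor_beds:
        records, factor_counts = run_enrich(calls, factor_beds, thr)
        write_table(enrichment_table(records), out / "enrichment.tsv", prov)
        write_table(factor_counts, out / "factor_counts.tsv", prov)
    else:
        log.warning("no factor BED files found; enrichment stage skipped")

    transitions = None
    ctx_path = root / "contexts.yaml"
    if ctx_path.exists():
        with ctx_path.open() as fh:
            doc = yaml.safe_load(fh) or {}
        context_files = {
            ctx: {mark: [root / p for p in paths] for mark, paths in marks.items()}
            for ctx, marks in doc.items()
        }
        if context_files:
            transitions = run_dynamics(calls, context_files, thr)
            write_table(transitions, out / "transitions.tsv", prov)

    return PipelineResult(
        thresholds=thr,
        matrix=matrix,
        calls=calls,
        state_counts=tally,
        n_promoter_filtered=n_removed,
        annotations=annotations,
        mean_regions_per_gene=mean_per_gene,
        gene_overlap=gene_overlap,
        enrichment_records=records,
        factor_counts=factor_counts,
        transitions=transitions,
    )
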