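"""Readers and writers for peak BED files, TSS/gene-model tables, sample
manifests and result tables.

All region files are BED3+ (0-based, half-open).  Gene models use a
simplified tab-separated contract rather than full GTF: one row per
gene with TSS, strand, transcript span, optional exon extents and an
optional promoter chromatin class.  Parsers never silently drop
records: accepted / rejected / skipped line counts are logged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import yaml

from .intervals import GenomicInterval, IntervalSet

log = logging.getLogger("enhancerstates")

__all__ = [
    "Mark",
    "PeakSet",
    "TSSRecord",
    "TSSTable",
    "ManifestEntry",
    "Thresholds",
    "SampleManifest",
    "BedParseError",
    "read_bed",
    "write_bed",
    "read_tss_table",
    "write_tss_table",
    "read_manifest",
    "write_table",
]


class Mark(str, Enum):
    """Histone modification carried by a ChIP-seq peak set."""

    H3K4ME1 = "H3K4me1"
    H3K27AC = "H3K27ac"
    H3K27ME3 = "H3K27me3"
    OTHER = "OTHER"

    @classmethod
    def parse(cls, text: str) -> "Mark":
        for m in cls:
            if m.value.lower() == text.strip().lower():
                return m
        raise ValueError(f"unknown mark: {text!r}")


@dataclass
class PeakSet:
    """One sample's called peaks for one histone mark."""

    sample_id: str
    mark: Mark
    context: str
    intervals: IntervalSet

    def __post_init__(self) -> None:
        if not self.sample_id:
            raise ValueError("empty sample_id")


@dataclass(frozen=True)
class TSSRecord:
    gene_id: str
    chrom: str
    tss: int  # point coordinate of the transcription start site
    strand: str  # '+' or '-'
    span: GenomicInterval  # transcript span
    exons: tuple[GenomicInterval, ...] = ()
    promoter_class: str | None = None

    @property
    def tts(self) -> int:
        """Transcription termination site (the far end of the span)."""
        return self.span.start if self.strand == "-" else self.span.end - 1


class TSSTable:
    """Validated collection of gene models, unique per gene_id."""

    def __init__(self, records: Iterable[TSSRecord]):
        self.records: list[TSSRecord] = list(records)
        seen: set[str] = set()
        for r in self.records:
            if r.gene_id in seen:
                raise ValueError(f"duplicate gene_id: {r.gene_id}")
            seen.add(r.gene_id)
            if not (r.span.start <= r.tss < r.span.end):
                raise ValueError(
                    f"TSS outside transcript span for gene {r.gene_id}: "
                    f"tss={r.tss}, span={r.span}"
                )
            for ex in r.exons:
                if ex.chrom != r.chrom or ex.start < r.span.start or ex.end > r.span.end:
                    raise ValueError(f"exon outside transcript span for gene {r.gene_id}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def tss_points(self) -> list[tuple[str, int]]:
        return [(r.chrom, r.tss) for r in self.records]

    def gene_ids(self) -> set[str]:
        return {r.gene_id for r in self.records}

    def promoter_windows(self, halfwidth: int) -> IntervalSet:
        """Promoter regions: ``halfwidth`` bases either side of each TSS."""
        ivs = []
        for r in self.records:
            s = max(0, r.tss - halfwidth)
            ivs.append(GenomicInterval(r.chrom, s, r.tss + halfwidth))
        return IntervalSet(ivs)


class BedParseError(ValueError):
    pass


def read_bed(path: str | Path, with_names: bool = False):
    """Read a BED3+ file into an :class:`IntervalSet`.

    Track/browser/comment lines are tolerated; extra columns are
    ignored.  With ``with_names=True`` returns ``(IntervalSet, names)``
    where ``names`` maps each interval to its column-4 value (or None).
    """
    path = Path(path)
    intervals: list[GenomicInterval] = []
    names: dict[GenomicInterval, str | None] = {}
    n_skip = n_ok = 0
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track", "browser")):
                n_skip += 1
                continue
            fields = line.split()
            if len(fields) < 3:
                raise BedParseError(f"{path}:{lineno}: expected ≥3 columns, got {len(fields)}")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise BedParseError(f"{path}:{lineno}: malformed coordinate: {exc}") from None
            if end <= start:
                raise BedParseError(
                    f"{path}:{lineno}: start must be < end (got {start} ≥ {end})"
                )
            iv = GenomicInterval(chrom, start, end)
            intervals.append(iv)
            names[iv] = fields[3] if len(fields) > 3 else None
            n_ok += 1
    log.info("read_bed %s: accepted=%d skipped=%d", path.name, n_ok, n_skip)
    iset = IntervalSet(intervals)
    return (iset, names) if with_names else iset


def write_bed(
    intervals: Iterable[GenomicInterval],
    path: str | Path,
    names: dict[GenomicInterval, str] | Sequence[str] | None = None,
) -> None:
    """Write intervals as BED3 (or BED4 when names/labels are supplied).

    Round-trips losslessly through :func:`read_bed`; an empty input
    yields an empty file.
    """
    path = Path(path)
    intervals = list(intervals)
    if isinstance(names, dict):
        labels = [names.get(iv) for iv in intervals]
    elif names is not None:
        labels = list(names)
        if len(labels) != len(intervals):
            raise ValueError("names length must match interval count")
    else:
        labels = [None] * len(intervals)
    with path.open("w") as fh:
        for iv, lab in zip(intervals, labels):
            if lab is None:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")
            else:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{lab}\n")


_TSS_COLUMNS = [
    "gene_id", "chrom", "tss", "strand", "tx_start", "tx_end",
    "exon_starts", "exon_ends", "promoter_class",
]


def read_tss_table(path: str | Path) -> TSSTable:
    """Read the tab-separated gene-model table.

    Columns: gene_id, chrom, tss, strand, tx_start, tx_end, then
    optional comma-separated exon_starts/exon_ends and an optional
    promoter_class.  A minus-strand TSS given as the exclusive span end
    is normalised to the last covered base (half-open convention).
    """
    path = Path(path)
    records: list[TSSRecord] = []
    with path.open() as fh:
        header: list[str] | None = None
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if header is None:
                if fields[0] == "gene_id":
                    header = fields
                    continue
                header = _TSS_COLUMNS[: len(fields)]
            row = dict(zip(header, fields))
            try:
                chrom = row["chrom"]
                tss = int(row["tss"])
                tx_start, tx_end = int(row["tx_start"]), int(row["tx_end"])
                strand = row["strand"]
            except (KeyError, ValueError) as exc:
                raise ValueError(f"{path}:{lineno}: malformed gene record: {exc}") from None
            if strand not in "+-":
                raise ValueError(f"{path}:{lineno}: bad strand {strand!r}")
            if strand == "-" and tss == tx_end:
                tss -= 1  # exclusive end given as the start site
            exons: list[GenomicInterval] = []
            es, ee = row.get("exon_starts", ""), row.get("exon_ends", "")
            if es and ee:
                for a, b in zip(es.split(","), ee.split(",")):
                    if a and b:
                        exons.append(GenomicInterval(chrom, int(a), int(b)))
            records.append(
                TSSRecord(
                    gene_id=row["gene_id"],
                    chrom=chrom,
                    tss=tss,
                    strand=strand,
                    span=GenomicInterval(chrom, tx_start, tx_end),
                    exons=tuple(exons),
                    promoter_class=row.get("promoter_class") or None,
                )
            )
    table = TSSTable(records)
    log.info("read_tss_table %s: %d genes", path.name, len(table))
    return table


def write_tss_table(table: TSSTable, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write("\t".join(_TSS_COLUMNS) + "\n")
        for r in table:
            fh.write(
                "\t".join(
                    [
                        r.gene_id, r.chrom, str(r.tss), r.strand,
                        str(r.span.start), str(r.span.end),
                        ",".join(str(e.start) for e in r.exons),
                        ",".join(str(e.end) for e in r.exons),
                        r.promoter_class or "",
                    ]
                )
                + "\n"
            )


@dataclass
class ManifestEntry:
    path: Path
    sample_id: str
    mark: Mark
    context: str = "ES"


@dataclass
class Thresholds:
    """Pipeline thresholds; defaults follow the published procedure.

    presence_min: samples of a mark that must show the mark for it to
        count as present (3 of 4 replicates).
    absence_max: samples allowed to show a mark that must be absent (0).
    merge_frac: fractional overlap (of the smaller peak) to merge peaks
        into one consensus region (0.25).
    occupancy_frac: fraction of a factor peak that must fall inside a
        region to call the factor bound, strict (0.5).
    conservation_frac: fraction of a region that must be covered by
        conserved blocks to call it conserved, strict (0.75).
    promoter_halfwidth: half of the 1 kb promoter window around a TSS.
    """

    presence_min: int = 3
    absence_max: int = 0
    merge_frac: float = 0.25
    occupancy_frac: float = 0.5
    conservation_frac: float = 0.75
    promoter_halfwidth: int = 500

    def validate(self) -> None:
        for name in ("merge_frac", "occupancy_frac", "conservation_frac"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must be in (0, 1], got {v}")
        if self.absence_max >= self.presence_min:
            raise ValueError("absence_max must be < presence_min")
        if self.presence_min < 1:
            raise ValueError("presence_min must be ≥ 1")
        if self.promoter_halfwidth <= 0:
            raise ValueError("promoter_halfwidth must be > 0")


@dataclass
class SampleManifest:
    entries: list[ManifestEntry]
    thresholds: Thresholds = field(default_factory=Thresholds)

    def samples_per_mark(self) -> dict[Mark, int]:
        counts: dict[Mark, int] = {}
        for e in self.entries:
            counts[e.mark] = counts.get(e.mark, 0) + 1
        return counts

    def validate(self) -> None:
        self.thresholds.validate()
        if not self.entries:
            raise ValueError("manifest has no sample entries")
        for mark, n in self.samples_per_mark().items():
            if self.thresholds.presence_min > n:
                raise ValueError(
                    f"presence_min={self.thresholds.presence_min} exceeds the "
                    f"{n} samples available for {mark.value}"
                )

    def load_peaksets(self) -> list[PeakSet]:
        return [
            PeakSet(e.sample_id, e.mark, e.context, read_bed(e.path))
            for e in self.entries
        ]


def read_manifest(path: str | Path) -> SampleManifest:
    """Read a YAML sample manifest and apply default thresholds."""
    path = Path(path)
    with path.open() as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict) or "samples" not in doc:
        raise ValueError(f"{path}: manifest must contain a 'samples' list")
    entries = []
    for i, item in enumerate(doc["samples"]):
        if "path" not in item:
            raise ValueError(f"{path}: sample entry {i} missing 'path'")
        p = Path(item["path"])
        if not p.is_absolute():
            p = path.parent / p
        entries.append(
            ManifestEntry(
                path=p,
                sample_id=str(item.get("sample_id", f"sample{i}")),
                mark=Mark.parse(str(item["mark"])),
                context=str(item.get("context", "ES")),
            )
        )
    thr = Thresholds(**(doc.get("thresholds") or {}))
    manifest = SampleManifest(entries=entries, thresholds=thr)
    manifest.validate()
    return manifest


def write_table(df, path: str | Path, header_lines: Sequence[str] = ()) -> None:
    """Write a result table as TSV with commented provenance header lines.

    Column order is taken from the frame; rows should be pre-sorted by
    the caller so diffs are stable.
    """
    path = Path(path)
    with path.open("w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=False)
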