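"""Genomic intervals, peaks, BED-family I/O and annotation-based classification.

Coordinates are 0-based half-open throughout (BED convention).  A peak is an
interval with a summit (its maximum-enrichment base) and a score; an
annotation set pairs transcription start sites with gene spans.  The
classification rules implemented here are the standard peak-centric ones:
a peak is a *promoter* peak iff it overlaps a symmetric window around any
TSS by at least 1 bp, and non-promoter peaks are assigned to every gene
whose span lies within a fixed distance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from intervaltree import IntervalTree

__all__ = [
    "GenomicInterval",
    "Peak",
    "AnnotationSet",
    "PeakClassification",
    "ParseError",
    "parse_peaks",
    "write_peaks",
    "parse_intervals",
    "write_intervals",
    "read_annotation_table",
    "write_annotation_table",
    "read_annotation_bed12",
    "filter_blacklist",
    "partition_common_specific",
    "classify_promoter",
    "overlaps",
]


class ParseError(ValueError):
    """Raised when a BED-family or annotation file has a malformed line."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A located genomic region, 0-based half-open.

    ``strand`` is '+', '-' or '.' (unstranded) and does not participate in
    overlap logic.
    """

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        """True iff the two intervals share >= 1 bp."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def distance(self, other: "GenomicInterval") -> int | None:
        """Gap in bp between the intervals; 0 if overlapping, None if on
        different chromosomes."""
        if self.chrom != other.chrom:
            return None
        if self.overlaps(other):
            return 0
        if self.end <= other.start:
            return other.start - self.end
        return self.start - other.end


def overlaps(a: GenomicInterval, b: GenomicInterval) -> bool:
    return a.overlaps(b)


@dataclass(frozen=True)
class Peak:
    """An enrichment peak: an interval plus its summit and score."""

    interval: GenomicInterval
    summit: int
    score: float = 0.0
    label: str = ""

    def __post_init__(self) -> None:
        if not (self.interval.start <= self.summit < self.interval.end):
            raise ValueError(
                f"summit {self.summit} outside peak "
                f"{self.interval.chrom}:{self.interval.start}-{self.interval.end}"
            )
        if self.score < 0:
            raise ValueError("peak score must be nonnegative")

    @property
    def chrom(self) -> str:
        return self.interval.chrom


@dataclass
class AnnotationSet:
    """TSS records and gene spans used for promoter classification.

    ``tss_records`` maps gene id -> (chrom, tss position, strand);
    ``gene_spans`` maps gene id -> GenomicInterval.  The two must cover the
    same genes, and every TSS must lie within (or at an endpoint of) its
    gene span.
    """

    tss_records: dict[str, tuple[str, int, str]]
    gene_spans: dict[str, GenomicInterval]

    def __post_init__(self) -> None:
        if set(self.tss_records) != set(self.gene_spans):
            missing = set(self.tss_records) ^ set(self.gene_spans)
            raise ValueError(f"TSS/span gene sets differ; symmetric diff {sorted(missing)[:5]}")
        for gene, (chrom, tss, _strand) in self.tss_records.items():
            span = self.gene_spans[gene]
            if chrom != span.chrom or not (span.start <= tss <= span.end):
                raise ValueError(f"TSS of {gene} at {chrom}:{tss} outside span {span}")

    def __len__(self) -> int:
        return len(self.tss_records)


@dataclass
class PeakClassification:
    """Promoter / non-promoter partition with gene assignments."""

    promoter_peaks: list[Peak]
    nonpromoter_peaks: list[Peak]
    gene_assignments: dict[str, list[str]] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# BED-family I/O
# ---------------------------------------------------------------------------

def _unique_labels(labels: Iterable[str]) -> list[str]:
    """Disambiguate duplicate labels by appending an ordinal suffix."""
    seen: dict[str, int] = {}
    out = []
    for lab in labels:
        if lab in seen:
            seen[lab] += 1
            out.append(f"{lab}_{seen[lab]}")
        else:
            seen[lab] = 0
            out.append(lab)
    return out


def _parse_int(text: str, what: str, lineno: int) -> int:
    try:
        return int(text)
    except ValueError:
        raise ParseError(f"line {lineno}: non-integer {what}: {text!r}") from None


def parse_peaks(path: str | Path, dialect: str = "narrowPeak") -> list[Peak]:
    """Read peaks from a BED6 or ENCODE narrowPeak file.

    narrowPeak summit = start + column-10 offset; an offset of -1 falls back
    to the interval midpoint (rounded down), as does BED6 which has no summit
    column.  Duplicate names get an ordinal suffix.
    """
    if dialect not in ("bed6", "narrowPeak"):
        raise ValueError(f"unknown dialect {dialect!r}")
    min_cols = 10 if dialect == "narrowPeak" else 4
    rows: list[tuple[GenomicInterval, int, float, str]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            if len(cols) < min_cols:
                raise ParseError(
                    f"line {lineno}: expected >= {min_cols} columns for "
                    f"{dialect}, got {len(cols)}"
                )
            start = _parse_int(cols[1], "start", lineno)
            end = _parse_int(cols[2], "end", lineno)
            if start >= end:
                raise ParseError(f"line {lineno}: start {start} >= end {end}")
            strand = cols[5] if len(cols) > 5 and cols[5] in ("+", "-") else "."
            try:
                iv = GenomicInterval(cols[0], start, end, strand)
            except ValueError as exc:
                raise ParseError(f"line {lineno}: {exc}") from None
            score = float(cols[4]) if len(cols) > 4 and cols[4] not in (".", "") else 0.0
            if dialect == "narrowPeak":
                score = float(cols[6])  # signalValue is the enrichment score
                offset = _parse_int(cols[9], "summit offset", lineno)
                summit = start + offset if offset >= 0 else start + (end - start) // 2
            else:
                summit = start + (end - start) // 2
            if not (start <= summit < end):
                raise ParseError(f"line {lineno}: summit {summit} outside [{start},{end})")
            name = cols[3] if len(cols) > 3 and cols[3] != "." else f"peak_{lineno}"
            rows.append((iv, summit, max(score, 0.0), name))
    labels = _unique_labels(name for *_rest, name in rows)
    return [
        Peak(interval=iv, summit=summit, score=score, label=lab)
        for (iv, summit, score, _), lab in zip(rows, labels)
    ]


def write_peaks(peaks: Sequence[Peak], path: str | Path, dialect: str = "narrowPeak") -> None:
    """Write peaks sorted by coordinate, as BED6 or narrowPeak."""
    if dialect not in ("bed6", "narrowPeak"):
        raise ValueError(f"unknown dialect {dialect!r}")
    ordered = sorted(peaks, key=lambda p: (p.interval.chrom, p.interval.start, p.interval.end))
    with open(path, "w") as fh:
        for p in ordered:
            iv = p.interval
            if dialect == "bed6":
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{p.label}\t{p.score!r}\t{iv.strand}\n")
            else:
                offset = p.summit - iv.start
                fh.write(
                    f"{iv.chrom}\t{iv.start}\t{iv.end}\t{p.label}\t0\t{iv.strand}"
                    f"\t{p.score!r}\t-1\t-1\t{offset}\n"
                )


def parse_intervals(path: str | Path) -> list[GenomicInterval]:
    """Read plain intervals from a BED3+ file (e.g. a blacklist)."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            if len(cols) < 3:
                raise ParseError(f"line {lineno}: expected >= 3 columns, got {len(cols)}")
            start = _parse_int(cols[1], "start", lineno)
            end = _parse_int(cols[2], "end", lineno)
            if start >= end:
                raise ParseError(f"line {lineno}: start {start} >= end {end}")
            strand = cols[5] if len(cols) > 5 and cols[5] in ("+", "-") else "."
            out.append(GenomicInterval(cols[0], start, end, strand))
    return out


def write_intervals(intervals: Sequence[GenomicInterval], path: str | Path) -> None:
    ordered = sorted(intervals)
    with open(path, "w") as fh:
        for iv in ordered:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t.\t0\t{iv.strand}\n")


# ---------------------------------------------------------------------------
# Annotation I/O
# ---------------------------------------------------------------------------

def read_annotation_table(path: str | Path) -> AnnotationSet:
    """Read a refFlat-like TSV: gene, chrom, strand, txStart, txEnd.

    A header line is permitted (detected by a non-integer txStart field).
    The TSS is txStart for '+' genes and txEnd - 1 for '-' genes.
    """
    tss: dict[str, tuple[str, int, str]] = {}
    spans: dict[str, GenomicInterval] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < 5:
                raise ParseError(f"line {lineno}: expected 5 columns, got {len(cols)}")
            gene, chrom, strand, s_start, s_end = cols[:5]
            if lineno == 1 and not s_start.lstrip("-").isdigit():
                continue  # header
            start = _parse_int(s_start, "txStart", lineno)
            end = _parse_int(s_end, "txEnd", lineno)
            if strand not in ("+", "-"):
                raise ParseError(f"line {lineno}: bad strand {strand!r}")
            if gene in tss:
                raise ParseError(f"line {lineno}: duplicate gene id {gene!r}")
            spans[gene] = GenomicInterval(chrom, start, end, strand)
            tss[gene] = (chrom, start if strand == "+" else end - 1, strand)
    return AnnotationSet(tss_records=tss, gene_spans=spans)


def write_annotation_table(ann: AnnotationSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("gene\tchrom\tstrand\ttxStart\ttxEnd\n")
        for gene in sorted(ann.gene_spans, key=lambda g: (ann.gene_spans[g].chrom,
                                                          ann.gene_spans[g].start, g)):
            span = ann.gene_spans[gene]
            fh.write(f"{gene}\t{span.chrom}\t{span.strand}\t{span.start}\t{span.end}\n")


def read_annotation_bed12(path: str | Path) -> AnnotationSet:
    """Read gene models from BED12 (only chrom/start/end/name/strand are used)."""
    tss: dict[str, tuple[str, int, str]] = {}
    spans: dict[str, GenomicInterval] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            if len(cols) < 12:
                raise ParseError(f"line {lineno}: BED12 requires 12 columns, got {len(cols)}")
            chrom, s_start, s_end, gene = cols[0], cols[1], cols[2], cols[3]
            strand = cols[5]
            start = _parse_int(s_start, "start", lineno)
            end = _parse_int(s_end, "end", lineno)
            if strand not in ("+", "-"):
                raise ParseError(f"line {lineno}: bad strand {strand!r}")
            if gene in tss:
                raise ParseError(f"line {lineno}: duplicate gene id {gene!r}")
            spans[gene] = GenomicInterval(chrom, start, end, strand)
            tss[gene] = (chrom, start if strand == "+" else end - 1, strand)
    return AnnotationSet(tss_records=tss, gene_spans=spans)


# ---------------------------------------------------------------------------
# Overlap algebra
# ---------------------------------------------------------------------------

def _build_trees(intervals: Iterable[GenomicInterval]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for iv in intervals:
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end)
    return trees


def filter_blacklist(peaks: Sequence[Peak], blacklist: Sequence[GenomicInterval]) -> list[Peak]:
    """Drop every peak overlapping a blacklist interval by >= 1 bp.

    Survivor order is preserved.  An empty blacklist is the identity.
    """
    trees = _build_trees(blacklist)
    out = []
    for p in peaks:
        tree = trees.get(p.interval.chrom)
        if tree is None or not tree.overlaps(p.interval.start, p.interval.end):
            out.append(p)
    return out


def partition_common_specific(
    peaks_a: Sequence[Peak], peaks_b: Sequence[Peak]
) -> tuple[list[Peak], list[Peak], list[Peak], list[Peak]]:
    """Split each peak set into common / specific by >= 1 bp cross-overlap.

    Returns ``(common_a, specific_a, common_b, specific_b)``; each side is
    partitioned exactly, in input order.
    """
    trees_b = _build_trees(p.interval for p in peaks_b)
    trees_a = _build_trees(p.interval for p in peaks_a)

    def split(peaks, trees):
        common, specific = [], []
        for p in peaks:
            tree = trees.get(p.interval.chrom)
            if tree is not None and tree.overlaps(p.interval.start, p.interval.end):
                common.append(p)
            else:
                specific.append(p)
        return common, specific

    common_a, specific_a = split(peaks_a, trees_b)
    common_b, specific_b = split(peaks_b, trees_a)
    return common_a, specific_a, common_b, specific_b


def classify_promoter(
    peaks: Sequence[Peak],
    ann: AnnotationSet,
    flank: int = 2000,
    max_gene_dist: int = 50_000,
) -> PeakClassification:
    """Partition peaks into promoter vs non-promoter and assign genes.

    A peak is a promoter peak iff it overlaps ``[TSS - flank, TSS + flank)``
    of any gene by >= 1 bp; the window is symmetric so gene strand is
    irrelevant.  Remaining peaks are assigned to every gene whose span lies
    within ``max_gene_dist`` bp (gap distance; 0 if overlapping).  Peaks near
    no gene receive an empty assignment.  The promoter rule takes precedence:
    promoter peaks are not gene-assigned by distance.
    """
    if flank <= 0:
        raise ValueError("flank must be positive")
    labels = _unique_labels(p.label for p in peaks)

    tss_trees: dict[str, IntervalTree] = {}
    for gene, (chrom, tss, _strand) in ann.tss_records.items():
        lo = max(0, tss - flank)
        tss_trees.setdefault(chrom, IntervalTree()).addi(lo, tss + flank, gene)

    gene_trees: dict[str, IntervalTree] = {}
    for gene, span in ann.gene_spans.items():
        lo = max(0, span.start - max_gene_dist)
        gene_trees.setdefault(span.chrom, IntervalTree()).addi(lo, span.end + max_gene_dist, gene)

    promoter, nonpromoter = [], []
    assignments: dict[str, list[str]] = {}
    for p, lab in zip(peaks, labels):
        iv = p.interval
        tree = tss_trees.get(iv.chrom)
        if tree is not None and tree.overlaps(iv.start, iv.end):
            promoter.append(p)
            continue
        nonpromoter.append(p)
        gtree = gene_trees.get(iv.chrom)
        hits = sorted({h.data for h in gtree.overlap(iv.start, iv.end)}) if gtree else []
        assignments[lab] = hits
    return PeakClassification(
        promoter_peaks=promoter, nonpromoter_peaks=nonpromoter, gene_assignments=assignments
    )
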