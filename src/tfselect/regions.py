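"""Labeled genomic region catalog: binding domains (BD), non-BD coding remainder,
the full coding space (ALLGENES), cis-regulatory modules (CRM), and motif-derived
binding sites (TFBS).

All coordinates are 0-based half-open; conversion to 1-based happens only at the
GFF3/VCF boundary. CRM filtering keeps modules with an annotation score strictly
above a threshold whose overlap with the union of gene +/- window flanks reaches a
minimum number of base pairs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

from intervaltree import IntervalTree

BD = "BD"
NONBD = "NONBD"
ALLGENES = "ALLGENES"
CRM = "CRM"
TFBS = "TFBS"

REGION_CLASSES = (BD, NONBD, ALLGENES, CRM, TFBS)


@dataclass(frozen=True)
class GenomicInterval:
    contig: str
    start: int
    end: int
    strand: str = "."
    label: str | None = None
    score: int | None = None

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid interval [{self.start}, {self.end})")

    def __len__(self) -> int:
        return self.end - self.start

    def overlap_len(self, other: "GenomicInterval") -> int:
        if self.contig != other.contig:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


@dataclass
class TranscriptModel:
    """Representative transcript of a gene: a single-CDS span with phase 0."""

    gene_id: str
    contig: str
    start: int
    end: int
    strand: str = "+"
    is_tf: bool = False


def merge_intervals(intervals) -> list[tuple[int, int]]:
    """Merge overlapping or touching (start, end) pairs on one contig."""
    pairs = sorted((iv.start, iv.end) if hasattr(iv, "start") else tuple(iv) for iv in intervals)
    merged: list[list[int]] = []
    for s, e in pairs:
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [tuple(p) for p in merged]


def complement_domains(cds_span, bd_intervals) -> list[tuple[int, int]]:
    """Set-complement of BD intervals within a coding span.

    ``cds_span`` is a (start, end) pair or GenomicInterval; BD intervals must lie
    within it. Overlapping BD intervals are merged first (with a warning). Returns
    (start, end) pairs; empty when BD covers the span.
    """
    span = (cds_span.start, cds_span.end) if hasattr(cds_span, "start") else tuple(cds_span)
    bd = [((iv.start, iv.end) if hasattr(iv, "start") else tuple(iv)) for iv in bd_intervals]
    for s, e in bd:
        if s < span[0] or e > span[1]:
            raise ValueError(f"BD interval [{s}, {e}) outside coding span {span}")
    n_before = len(bd)
    bd = merge_intervals(bd)
    if len(bd) < n_before:
        warnings.warn("overlapping BD intervals merged before complement", stacklevel=2)
    out = []
    cursor = span[0]
    for s, e in bd:
        if s > cursor:
            out.append((cursor, s))
        cursor = max(cursor, e)
    if cursor < span[1]:
        out.append((cursor, span[1]))
    return out


def filter_crms(
    crms,
    genes,
    score_min: int = 30,
    window_bp: int = 2000,
    min_overlap_bp: int = 500,
) -> list:
    """Retain CRMs with score > score_min (strict) overlapping gene vicinity windows.

    The vicinity of a gene is its span extended by ``window_bp`` on both sides,
    including the gene body. A CRM is kept when its overlap with the union of all
    vicinity windows on its contig is at least ``min_overlap_bp``. 500 bp is the
    default minimum overlap; 250 bp is the documented setting for compact genomes.
    """
    windows: dict[str, list[tuple[int, int]]] = {}
    for g in genes:
        contig = g.contig if hasattr(g, "contig") else g[0]
        start = g.start if hasattr(g, "start") else g[1]
        end = g.end if hasattr(g, "end") else g[2]
        windows.setdefault(contig, []).append((max(0, start - window_bp), end + window_bp))
    merged = {c: merge_intervals(ivs) for c, ivs in windows.items()}

    retained = []
    for crm in crms:
        if crm.score is None:
            raise ValueError(f"CRM {crm} has no score")
        if crm.score <= score_min:
            continue
        overlap = 0
        for s, e in merged.get(crm.contig, []):
            overlap += max(0, min(crm.end, e) - max(crm.start, s))
        if overlap >= min_overlap_bp:
            retained.append(crm)
    return retained


@dataclass
class RegionCatalog:
    """Interval sets per region class plus the gene -> transcript map."""

    transcripts: dict = field(default_factory=dict)  # gene_id -> TranscriptModel
    intervals: dict = field(default_factory=lambda: {c: [] for c in REGION_CLASSES})
    _trees: dict = field(default_factory=dict, repr=False)

    def add(self, label: str, interval: GenomicInterval) -> None:
        if label not in REGION_CLASSES:
            raise ValueError(f"unknown region class {label!r}")
        self.intervals[label].append(interval)
        self._trees.pop((label, interval.contig), None)

    def contigs(self) -> set:
        return {iv.contig for ivs in self.intervals.values() for iv in ivs}

    def _tree(self, label: str, contig: str) -> IntervalTree:
        key = (label, contig)
        if key not in self._trees:
            tree = IntervalTree()
            for iv in self.intervals[label]:
                if iv.contig == contig:
                    tree.addi(iv.start, iv.end, iv)
            self._trees[key] = tree
        return self._trees[key]

    def labels_at(self, contig: str, position: int) -> set:
        """Region-class labels whose intervals contain a position (deduplicated)."""
        found = set()
        for label in REGION_CLASSES:
            if self._tree(label, contig).overlaps_point(position):
                found.add(label)
        return found

    def class_length(self, label: str) -> int:
        by_contig: dict[str, list] = {}
        for iv in self.intervals[label]:
            by_contig.setdefault(iv.contig, []).append(iv)
        return sum(e - s for ivs in by_contig.values() for s, e in merge_intervals(ivs))


def assign_variants(variants, catalog: RegionCatalog, known_contigs=None):
    """Attach every containing region-class label to each variant (in place).

    Variants inside several overlapping TFBS intervals receive the TFBS label once
    (variant pooling). A variant on an unknown contig raises ``ValueError``.
    """
    contigs = set(known_contigs) if known_contigs is not None else catalog.contigs()
    for v in variants:
        contig = getattr(v, "contig", None) or "chr1"
        if contigs and contig not in contigs:
            raise ValueError(f"variant at {contig}:{v.position} is off-contig")
        v.labels |= catalog.labels_at(contig, v.position)
    return variants
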