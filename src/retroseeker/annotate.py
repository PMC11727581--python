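"""Genomic categorization and L1-endonuclease motif scanning.

Candidates are intersected with user-supplied interval annotations (one
BED file per category: repeats, CDS, introns, ...) and assigned the
highest-priority overlapping category, defaulting to ``intergenic``.  The
second half scans the sequence around each candidate's 5' insertion edge
for the LINE-1 endonuclease cleavage hexamer (TTAAAA by default), exactly
and within a small Hamming neighbourhood, and records the signed offset
between the motif's 3' end and the insertion edge (negative = upstream in
element orientation).
"""

from __future__ import annotations

import collections
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd
from intervaltree import IntervalTree

from ._seq import chrom_length, fetch, revcomp
from .detect import RetroCandidate

DEFAULT_PRIORITY = ["repeat", "CDS", "UTR", "exon", "intron", "promoter"]
INTERGENIC = "intergenic"


@dataclass
class AnnotationSet:
    """Named interval collections with a total priority order.

    When a candidate overlaps several categories the earliest name in
    ``priority`` wins; no overlap at all yields ``intergenic``.
    """

    trees: dict[str, dict[str, IntervalTree]] = field(default_factory=dict)
    priority: list[str] = field(default_factory=lambda: list(DEFAULT_PRIORITY))

    def add_intervals(
        self, category: str, intervals: Iterable[tuple[str, int, int]]
    ) -> None:
        per_chrom = self.trees.setdefault(category, {})
        for chrom, start, end in intervals:
            if end <= start:
                continue
            per_chrom.setdefault(chrom, IntervalTree()).addi(start, end)
        if category not in self.priority:
            self.priority.append(category)

    @classmethod
    def from_bed_files(
        cls, beds: Mapping[str, str], priority: Sequence[str] | None = None
    ) -> "AnnotationSet":
        """Build from ``{category: bed_path}``; BED is 0-based half-open."""
        ann = cls(priority=list(priority) if priority is not None else list(DEFAULT_PRIORITY))
        for category, path in beds.items():
            intervals = []
            with open(path) as fh:
                for line in fh:
                    if not line.strip() or line.startswith(("#", "track", "browser")):
                        continue
                    parts = line.split("\t")
                    intervals.append((parts[0], int(parts[1]), int(parts[2])))
            ann.add_intervals(category, intervals)
        return ann

    def overlapping(self, chrom: str, start: int, end: int) -> set[str]:
        hits = set()
        for category, per_chrom in self.trees.items():
            tree = per_chrom.get(chrom)
            if tree is not None and tree.overlap(start, end):
                hits.add(category)
        return hits


def assign_category(
    candidate: RetroCandidate | tuple[str, int, int], annotation: AnnotationSet
) -> str:
    """Highest-priority category overlapping the insertion interval by >= 1 base."""
    if isinstance(candidate, RetroCandidate):
        chrom, start, end = candidate.ref_chrom, candidate.start, candidate.end
    else:
        chrom, start, end = candidate
    hits = annotation.overlapping(chrom, start, end)
    if not hits:
        return INTERGENIC
    rank = {name: i for i, name in enumerate(annotation.priority)}
    return min(hits, key=lambda name: rank.get(name, len(rank)))


def summarize_distribution(
    candidates: Sequence[RetroCandidate], annotation: AnnotationSet
) -> dict[str, tuple[int, float]]:
    """Per-category (count, fraction); fractions sum to 1 over non-empty categories."""
    if not candidates:
        return {}
    counts = collections.Counter(assign_category(c, annotation) for c in candidates)
    total = sum(counts.values())
    return {cat: (n, n / total) for cat, n in counts.most_common()}


# ---------------------------------------------------------------------------
# endonuclease motif scanning
# ---------------------------------------------------------------------------


@dataclass
class MotifHit:
    """Motif scan result for one candidate."""

    candidate_id: str
    has_exact: bool
    has_similar: bool  # within max_mismatch of the motif; exact implies similar
    best_offset: int | None  # motif 3' end minus insertion edge; negative = upstream
    best_mismatches: int | None


@dataclass
class MotifReport:
    """Cohort-level motif statistics."""

    hits: list[MotifHit]
    motif: str
    window: int
    max_mismatch: int
    exact_fraction: float
    similar_fraction: float
    offset_histogram: dict[int, int]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "id": h.candidate_id,
                    "hasExactMotif": h.has_exact,
                    "hasSimilarMotif": h.has_similar,
                    "bestOffset": h.best_offset,
                    "bestMismatches": h.best_mismatches,
                }
                for h in self.hits
            ]
        )


def scan_motif(
    candidate: RetroCandidate,
    genome: Mapping[str, object],
    motif: str = "TTAAAA",
    window: int = 20,
    max_mismatch: int = 1,
) -> MotifHit:
    """Scan +/- ``window`` nt around the candidate's 5' insertion edge.

    The scan is strand-aware: for minus-strand candidates the reverse
    complement around the right insertion edge is searched, so offsets are
    always in element orientation.  ``best_offset`` is the qualifying
    occurrence closest to the edge (ties resolved upstream), measured from
    the motif's 3' end to the edge.
    """
    k = len(motif)
    chrom = candidate.ref_chrom
    n = chrom_length(genome, chrom)
    if candidate.strand == "+":
        edge = candidate.start
        lo = max(0, edge - window - k)
        hi = min(n, edge + window)
        seq = fetch(genome, chrom, lo, hi)
        edge_local = edge - lo
    else:
        edge = candidate.end
        lo = max(0, edge - window)
        hi = min(n, edge + window + k)
        seq = revcomp(fetch(genome, chrom, lo, hi))
        edge_local = hi - edge

    best: tuple[int, int, int] | None = None  # (|offset|, offset_sign_rank, mismatches)
    best_offset = None
    best_mm = None
    has_exact = False
    has_similar = False
    for offset in range(-window, window + 1):
        # motif occupies [edge_local + offset - k, edge_local + offset)
        s = edge_local + offset - k
        if s < 0 or s + k > len(seq):
            continue
        mm = sum(1 for a, b in zip(seq[s : s + k], motif) if a != b)
        if mm == 0:
            has_exact = True
        if mm <= max_mismatch:
            has_similar = True
            key = (abs(offset), 0 if offset < 0 else 1, mm)
            if best is None or key < best:
                best = key
                best_offset = offset
                best_mm = mm
    return MotifHit(
        candidate_id=candidate.id,
        has_exact=has_exact,
        has_similar=has_similar,
        best_offset=best_offset,
        best_mismatches=best_mm,
    )


def motif_report(
    candidates: Sequence[RetroCandidate],
    genome: Mapping[str, object],
    motif: str = "TTAAAA",
    window: int = 20,
    max_mismatch: int = 1,
) -> MotifReport:
    hits = [scan_motif(c, genome, motif, window, max_mismatch) for c in candidates]
    n = len(hits)
    histogram = collections.Counter(
        h.best_offset for h in hits if h.best_offset is not None
    )
    return MotifReport(
        hits=hits,
        motif=motif,
        window=window,
        max_mismatch=max_mismatch,
        exact_fraction=(sum(h.has_exact for h in hits) / n) if n else 0.0,
        similar_fraction=(sum(h.has_similar for h in hits) / n) if n else 0.0,
        offset_histogram=dict(sorted(histogram.items())),
    )
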