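"""The retrotransposon caller.

A target-primed reverse transcription (TPRT) insertion leaves two
diagnostic scars on the reference genome: a short direct repeat of the
target site on both sides of the element (the target-site duplication,
TSD) and a 3' run of adenosines inherited from the transcript (the
poly(A) tail; it appears as poly(T) upstream of the element for
minus-strand insertions).  In a pairwise alignment net, the inserted copy
shows up as a fill nested inside a gap: the flanking locus aligns to the
query genome, the insertion itself does not, but its body re-aligns to
the parental locus elsewhere.

For every such gap-enclosed fill this module extends the fill edges
outwards and inwards, searches the two flanks for the best TSD pair with
a small dynamic-programming alignment, looks for a poly(A) run abutting
the 3' TSD, repeats both searches on the reverse complement, scores the
features additively (one unit per matching base, minus one per
mismatch/indel/interruption), and keeps candidates passing the length
and score filters (TSD >= 7, poly(A) >= 5 by default).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import pandas as pd

from ._seq import chrom_length, fetch, revcomp
from .netio import NetFile, iter_gap_fill_pairs


@dataclass(frozen=True)
class DetectParams:
    """Tunable knobs of the caller.

    The defaults implement the stringent calling profile: TSD length >= 7,
    poly(A) length >= 5, and a minimum additive score of 12 (the sum of the
    two length floors, so the score stays an independent knob).  ``mode``
    is informational: self-genome and cross-species nets run the identical
    workflow and differ only in which net file is supplied.
    """

    min_tsd_len: int = 7
    min_polya_len: int = 5
    extend_out: int = 30  # bases of outward flank extension beyond each fill edge
    extend_in: int = 30  # bases of inward extension into the fill
    max_tsd_mismatches: int = 1  # mismatches + indels allowed in the TSD alignment
    max_polya_interruptions: int = 1  # internal non-A positions allowed in the tail
    polya_max_gap_from_tsd: int = 5  # bases between tail 3' end and the 3' TSD
    min_score: float = 12.0
    mode: str = "self"  # "self" | "cross"

    def __post_init__(self) -> None:
        if self.min_tsd_len < 1 or self.min_polya_len < 1:
            raise ValueError("length floors must be >= 1")
        if self.extend_out < self.min_tsd_len:
            raise ValueError("extend_out must be >= min_tsd_len")
        if self.mode not in ("self", "cross"):
            raise ValueError("mode must be 'self' or 'cross'")


@dataclass
class TSDHit:
    """The two aligned copies of a target-site duplication.

    Coordinates are half-open intervals; from :func:`find_tsd` they are
    local to the supplied flanks, from :func:`detect_candidates` they are
    reference coordinates.  score = matches - mismatches - indels.
    """

    left_start: int
    left_end: int
    right_start: int
    right_end: int
    length: int  # aligned columns
    matches: int
    mismatches: int
    indels: int
    score: int
    seq_left: str = ""
    seq_right: str = ""


@dataclass
class PolyAHit:
    """A poly(A) run abutting the element's 3' TSD.

    ``a_count`` counts A on the searched strand (these are T on the
    reference for minus-strand candidates).  score = a_count - interruptions.
    """

    start: int
    end: int
    length: int
    a_count: int
    interruptions: int
    score: int


@dataclass
class RetroCandidate:
    """A called retrotransposon insertion on the reference genome.

    ``start``/``end`` bound the insertion between the inner edges of the
    two TSD copies; ``source_*`` is the query locus of the nested fill
    (the putative parental locus).
    """

    id: str
    ref_chrom: str
    start: int
    end: int
    strand: str
    tsd: TSDHit
    polya: Optional[PolyAHit]
    source_chrom: str
    source_strand: str
    source_start: int
    source_size: int
    tsd_score: float
    polya_score: float
    total_score: float
    passed_filters: bool


@dataclass
class Flanks:
    """Flank sequences around a fill plus offsets back to reference coords."""

    left: str
    right: str
    left_offset: int  # reference coordinate of left[0]
    right_offset: int  # reference coordinate of right[0]
    left_edge: int  # index of the fill 5' edge within `left`
    right_edge: int  # index of the fill 3' edge within `right`

    def left_to_ref(self, pos: int) -> int:
        return self.left_offset + pos

    def right_to_ref(self, pos: int) -> int:
        return self.right_offset + pos


def extend_flanks(
    genome: Mapping[str, object],
    chrom: str,
    fill_start: int,
    fill_end: int,
    params: DetectParams,
) -> Flanks:
    """Extract the two TSD search windows around a fill interval.

    The left flank spans [fill_start - extend_out, fill_start + extend_in),
    the right flank [fill_end - extend_in, fill_end + extend_out), both
    clamped at chromosome edges.
    """
    n = chrom_length(genome, chrom)
    ls = max(0, fill_start - params.extend_out)
    le = min(n, fill_start + params.extend_in)
    rs = max(0, fill_end - params.extend_in)
    re_ = min(n, fill_end + params.extend_out)
    return Flanks(
        left=fetch(genome, chrom, ls, le),
        right=fetch(genome, chrom, rs, re_),
        left_offset=ls,
        right_offset=rs,
        left_edge=min(fill_start, n) - ls,
        right_edge=min(fill_end, n) - rs,
    )


# ---------------------------------------------------------------------------
# TSD search
# ---------------------------------------------------------------------------
#
# With at most one edit allowed (the default), every admissible alignment is
# a maximal exact match run, or two runs joined by a single mismatch or
# indel.  The search therefore enumerates all maximal match runs per
# diagonal of the (left, right) comparison — the dynamic-programming
# recurrence run-length(i, j) = run-length(i-1, j-1) + 1 on matches — and
# stitches runs across single edits.  Alignments are required to begin and
# end on matching columns (dangling edits at the termini would only pad the
# reported length without adding evidence, mirroring the poly(A) rule that
# terminal positions must be A).  For edit budgets >= 2 the stitching is
# chained; alignments whose edits are immediately adjacent (no match
# between two edits) are not considered.


def _match_runs(left: str, right: str):
    """All maximal exact-match runs between the two flanks.

    Returns (runs, by_point) where runs are (a, b, length) triples —
    left[a + t] == right[b + t] for t in [0, length) — and by_point maps
    every (i, j) on a run to (run_index, offset).
    """
    n_l, n_r = len(left), len(right)
    runs: list[tuple[int, int, int]] = []
    by_point: dict[tuple[int, int], tuple[int, int]] = {}
    for d in range(-n_l + 1, n_r):
        i = max(0, -d)
        j = i + d
        start = -1
        while i <= n_l and j <= n_r:
            inside = i < n_l and j < n_r and left[i] == right[j]
            if inside and start < 0:
                start = i
            elif not inside and start >= 0:
                length = i - start
                idx = len(runs)
                runs.append((start, start + d, length))
                for off in range(length):
                    by_point[(start + off, start + d + off)] = (idx, off)
                start = -1
            i += 1
            j += 1
    return runs, by_point



def find_tsd(
    left: str,
    right: str,
    params: DetectParams,
    left_edge: int | None = None,
    right_edge: int | None = None,
) -> Optional[TSDHit]:
    """Best-scoring TSD alignment between the two flanks, or None.

    Positional anchoring: the left copy must end within ``extend_in`` bases
    of the fill 5' edge (``left_edge``, an index into ``left``; defaults to
    the unclamped layout produced by :func:`extend_flanks`) and the right
    copy must begin within ``extend_in`` bases of the fill 3' edge.

    Ties are broken by longer aligned length, then fewer mismatches, then
    smaller distance of the left copy's end to the fill edge, then smaller
    coordinates, so the result is deterministic.
    """
    if not left or not right:
        return None
    if left_edge is None:
        left_edge = max(0, len(left) - params.extend_in)
    if right_edge is None:
        right_edge = min(params.extend_in, len(right))

    e_lo = max(1, left_edge - params.extend_in)
    e_hi = min(len(left), left_edge + params.extend_in)
    s_lo = max(0, right_edge - params.extend_in)
    s_hi = min(len(right) - 1, right_edge + params.extend_in)
    if e_lo > e_hi or s_lo > s_hi:
        return None

    runs, by_point = _match_runs(left, right)
    min_len = params.min_tsd_len
    budget = params.max_tsd_mismatches

    best: tuple | None = None
    best_hit: TSDHit | None = None

    def consider(a_start, e_l, s_r, b_end, matches, mism, ind):
        nonlocal best, best_hit
        length = matches + mism + ind
        if length < min_len:
            return
        score = matches - mism - ind
        key = (score, length, -mism, -ind, -abs(e_l - left_edge), -e_l, -s_r)
        if best is None or key > best:
            best = key
            best_hit = TSDHit(
                left_start=a_start,
                left_end=e_l,
                right_start=s_r,
                right_end=b_end,
                length=length,
                matches=matches,
                mismatches=mism,
                indels=ind,
                score=score,
                seq_left=left[a_start:e_l],
                seq_right=right[s_r:b_end],
            )

    # single-run (edit-free) alignments: the longest feasible sub-run
    for a, b, length in runs:
        t = max(0, s_lo - b)
        u = min(length, e_hi - a)
        if u - t < min_len:
            continue
        if b + t > s_hi or a + u < e_lo:
            continue
        consider(a + t, a + u, b + t, b + u, u - t, 0, 0)

    if budget >= 1 and runs:
        # Chains: match segment -(edit)- segment -(edit)- ... with at most
        # `budget` edits.  A mismatch edit can only sit at a maximal run's
        # end (a matching column is never counted as a mismatch), while an
        # indel may leave a run at any interior position to resume on the
        # neighbouring diagonal.  Only the first segment's start and the
        # last segment's end are trimmable; interior segments are kept
        # whole, so alignments whose edits sit immediately adjacent are
        # outside the search space (irrelevant at the default budget of 1).

        def close(first, interior, a, b, avail, mism, ind):
            a0, b0, c0 = first  # first segment start + matches available in it
            s1_hi = min(c0, c0 - (s_lo - b0))
            s1_lo = max(1, c0 - (s_hi - b0))
            s2_hi = min(avail, e_hi - a)
            s2_lo = max(1, e_lo - a)
            if s1_lo <= s1_hi and s2_lo <= s2_hi:
                s1, s2 = s1_hi, s2_hi
                consider(a0 + (c0 - s1), a + s2, b0 + (c0 - s1), b + s2,
                         s1 + interior + s2, mism, ind)

        def exits(a, b, avail):
            """Single-edit departures from a segment: (consumed_matches,
            resume_point, d_mismatch, d_indel)."""
            out = [(avail, (a + avail + 1, b + avail + 1), 1, 0)]  # mismatch at run end
            for c in range(1, avail + 1):
                x, y = a + c - 1, b + c - 1  # last matched pair before the edit
                out.append((c, (x + 2, y + 1), 0, 1))  # skip a left-flank base
                out.append((c, (x + 1, y + 2), 0, 1))  # skip a right-flank base
            return out

        def explore(idx, off, first, interior, mism, ind):
            a, b, length = runs[idx]
            a += off
            b += off
            avail = length - off
            close(first, interior, a, b, avail, mism, ind)
            if mism + ind >= budget:
                return
            for consumed, point, dm, dx in exits(a, b, avail):
                nxt = by_point.get(point)
                if nxt is not None:
                    explore(nxt[0], nxt[1], first, interior + consumed, mism + dm, ind + dx)

        for a, b, length in runs:
            for consumed, point, dm, dx in exits(a, b, length):
                nxt = by_point.get(point)
                if nxt is not None:
                    explore(nxt[0], nxt[1], (a, b, consumed), 0, dm, dx)

    return best_hit


def find_polya(inner_sequence: str, params: DetectParams) -> Optional[PolyAHit]:
    """Best poly(A) run in a window whose 3' end abuts the 3' TSD.

    ``inner_sequence`` reads 5'->3' on the element strand and its right
    end sits at the inner edge of the 3' TSD.  The run must end within
    ``polya_max_gap_from_tsd`` bases of that edge, start and end on A,
    contain at most ``max_polya_interruptions`` internal non-A bases and
    reach ``min_polya_len``.  Runs are ranked by length, then score
    (a_count - interruptions), then proximity to the TSD.
    """
    n = len(inner_sequence)
    if n == 0:
        return None
    is_a = [c == "A" for c in inner_sequence]
    pref = [0]
    for flag in is_a:
        pref.append(pref[-1] + int(flag))

    best_key = None
    best = None
    min_end = max(params.min_polya_len, n - params.polya_max_gap_from_tsd)
    for end in range(n, min_end - 1, -1):
        if not is_a[end - 1]:
            continue
        for start in range(0, end - params.min_polya_len + 1):
            if not is_a[start]:
                continue
            length = end - start
            a_count = pref[end] - pref[start]
            interruptions = length - a_count
            if interruptions > params.max_polya_interruptions:
                continue
            score = a_count - interruptions
            key = (length, score, end, -start)
            if best_key is None or key > best_key:
                best_key = key
                best = PolyAHit(
                    start=start,
                    end=end,
                    length=length,
                    a_count=a_count,
                    interruptions=interruptions,
                    score=score,
                )
    return best


def score_candidate(tsd: TSDHit, polya: PolyAHit) -> tuple[float, float, float]:
    """Additive unit-per-base scoring of the two TPRT features.

    tsd_score = matches - mismatches - indels; polya_score = a_count -
    interruptions; total = their sum.  No length normalization is applied.
    """
    tsd_score = float(tsd.matches - tsd.mismatches - tsd.indels)
    polya_score = float(polya.a_count - polya.interruptions)
    return tsd_score, polya_score, tsd_score + polya_score


# ---------------------------------------------------------------------------
# full caller
# ---------------------------------------------------------------------------


def _search_region(
    seq: str, fill_lo: int, fill_hi: int, params: DetectParams
) -> tuple[Optional[TSDHit], Optional[PolyAHit]]:
    """Run the TSD + poly(A) search on one orientation of an extracted region.

    ``seq`` spans the fill plus up to ``extend_out`` bases on each side;
    ``fill_lo``/``fill_hi`` are the fill edges in region coordinates.
    Returned hits are in region coordinates.
    """
    n = len(seq)
    l_lo, l_hi = max(0, fill_lo - params.extend_out), min(n, fill_lo + params.extend_in)
    r_lo, r_hi = max(0, fill_hi - params.extend_in), min(n, fill_hi + params.extend_out)
    left, right = seq[l_lo:l_hi], seq[r_lo:r_hi]
    tsd = find_tsd(left, right, params, left_edge=fill_lo - l_lo, right_edge=fill_hi - r_lo)
    if tsd is None:
        return None, None
    # back to region coordinates
    tsd = replace(
        tsd,
        left_start=tsd.left_start + l_lo,
        left_end=tsd.left_end + l_lo,
        right_start=tsd.right_start + r_lo,
        right_end=tsd.right_end + r_lo,
    )
    window = params.extend_in + params.extend_out
    inner_lo = max(tsd.left_end, tsd.right_start - window)
    polya = find_polya(seq[inner_lo:tsd.right_start], params)
    if polya is not None:
        polya = replace(polya, start=polya.start + inner_lo, end=polya.end + inner_lo)
    return tsd, polya


def _passes(tsd: TSDHit, polya: Optional[PolyAHit], total: float, params: DetectParams) -> bool:
    return (
        tsd.length >= params.min_tsd_len
        and polya is not None
        and polya.length >= params.min_polya_len
        and total >= params.min_score
    )


def detect_candidates(
    net: NetFile,
    genome: Mapping[str, object],
    params: DetectParams | None = None,
    species: str = "sim",
) -> list[RetroCandidate]:
    """Call retrotransposon candidates from a net file and its reference genome.

    Every gap-enclosed fill (at any synteny depth) is examined on both
    orientations; the orientation with the higher total score wins (ties go
    to plus).  Candidates are sorted by (chromosome, start) and named
    ``<species>-retrotransposon-N`` in that order.  Candidates failing the
    TSD/poly(A)/score filters are still returned with
    ``passed_filters=False``; use :func:`filter_candidates` to drop them.
    """
    if params is None:
        params = DetectParams()
    raw: list[RetroCandidate] = []
    for gap, fill in iter_gap_fill_pairs(net):
        chrom = fill.ref_chrom
        n = chrom_length(genome, chrom)
        fs, fe = fill.ref_start, fill.ref_end
        lo = max(0, fs - params.extend_out)
        hi = min(n, fe + params.extend_out)
        seq = fetch(genome, chrom, lo, hi)

        results = {}
        tsd_f, polya_f = _search_region(seq, fs - lo, fe - lo, params)
        if tsd_f is not None:
            results["+"] = (tsd_f, polya_f)
        rc = revcomp(seq)
        tsd_r, polya_r = _search_region(rc, len(seq) - (fe - lo), len(seq) - (fs - lo), params)
        if tsd_r is not None:
            results["-"] = (tsd_r, polya_r)
        if not results:
            continue

        def total_of(item):
            tsd, polya = item
            return tsd.score + (polya.score if polya is not None else 0)

        strand = "+"
        if "-" in results and ("+" not in results or total_of(results["-"]) > total_of(results["+"])):
            strand = "-"
        tsd, polya = results[strand]

        if strand == "-":
            # map region-RC coordinates back to forward region coordinates;
            # the RC left copy is the forward right copy and vice versa
            m = len(seq)
            ls, le_ = m - tsd.right_end, m - tsd.right_start
            rs, re_ = m - tsd.left_end, m - tsd.left_start
            tsd = replace(
                tsd,
                left_start=ls + lo,
                left_end=le_ + lo,
                right_start=rs + lo,
                right_end=re_ + lo,
                seq_left=seq[ls:le_],
                seq_right=seq[rs:re_],
            )
            if polya is not None:
                ps, pe = m - polya.end, m - polya.start
                polya = replace(polya, start=ps + lo, end=pe + lo)
        else:
            tsd = replace(
                tsd,
                left_start=tsd.left_start + lo,
                left_end=tsd.left_end + lo,
                right_start=tsd.right_start + lo,
                right_end=tsd.right_end + lo,
            )
            if polya is not None:
                polya = replace(polya, start=polya.start + lo, end=polya.end + lo)

        tsd_score = float(tsd.score)
        polya_score = float(polya.score) if polya is not None else 0.0
        total = tsd_score + polya_score
        raw.append(
            RetroCandidate(
                id="",
                ref_chrom=chrom,
                start=tsd.left_end,
                end=tsd.right_start,
                strand=strand,
                tsd=tsd,
                polya=polya,
                source_chrom=fill.query_chrom,
                source_strand=fill.query_strand,
                source_start=fill.query_start,
                source_size=fill.query_size,
                tsd_score=tsd_score,
                polya_score=polya_score,
                total_score=total,
                passed_filters=_passes(tsd, polya, total, params),
            )
        )

    raw.sort(key=lambda c: (c.ref_chrom, c.start, c.end))
    for i, cand in enumerate(raw, start=1):
        cand.id = f"{species}-retrotransposon-{i}"
    return raw


def filter_candidates(
    candidates: Sequence[RetroCandidate], params: DetectParams | None = None
) -> list[RetroCandidate]:
    """Retain candidates meeting the TSD/poly(A) length floors and score cut."""
    if params is None:
        params = DetectParams()
    return [
        c
        for c in candidates
        if _passes(c.tsd, c.polya, c.total_score, params)
    ]


# ---------------------------------------------------------------------------
# tabular output
# ---------------------------------------------------------------------------

CANDIDATE_COLUMNS = [
    "id", "chrom", "start", "end", "strand",
    "tsdLen", "tsdSeqLeft", "tsdSeqRight", "tsdMismatches",
    "polyALen", "polyAInterruptions",
    "sourceChrom", "sourceStrand", "sourceStart", "sourceSize",
    "tsdScore", "polyAScore", "totalScore", "passedFilters",
]


def candidates_to_frame(candidates: Sequence[RetroCandidate]) -> pd.DataFrame:
    rows = []
    for c in candidates:
        rows.append(
            {
                "id": c.id,
                "chrom": c.ref_chrom,
                "start": c.start,
                "end": c.end,
                "strand": c.strand,
                "tsdLen": c.tsd.length,
                "tsdSeqLeft": c.tsd.seq_left,
                "tsdSeqRight": c.tsd.seq_right,
                "tsdMismatches": c.tsd.mismatches,
                "polyALen": c.polya.length if c.polya else 0,
                "polyAInterruptions": c.polya.interruptions if c.polya else 0,
                "sourceChrom": c.source_chrom,
                "sourceStrand": c.source_strand,
                "sourceStart": c.source_start,
                "sourceSize": c.source_size,
                "tsdScore": c.tsd_score,
                "polyAScore": c.polya_score,
                "totalScore": c.total_score,
                "passedFilters": c.passed_filters,
            }
        )
    return pd.DataFrame(rows, columns=CANDIDATE_COLUMNS)


def frame_to_candidates(frame: pd.DataFrame) -> list[RetroCandidate]:
    """Rebuild candidates from the extended TSV table.

    Per-base alignment detail not stored in the table (exact match/indel
    split) is reconstructed conservatively from the summary columns.
    """
    out: list[RetroCandidate] = []
    for row in frame.itertuples(index=False):
        tsd_len = int(row.tsdLen)
        tsd = TSDHit(
            left_start=int(row.start) - tsd_len,
            left_end=int(row.start),
            right_start=int(row.end),
            right_end=int(row.end) + tsd_len,
            length=tsd_len,
            matches=tsd_len - int(row.tsdMismatches),
            mismatches=int(row.tsdMismatches),
            indels=0,
            score=int(row.tsdScore),
            seq_left=str(row.tsdSeqLeft),
            seq_right=str(row.tsdSeqRight),
        )
        polya = None
        if int(row.polyALen) > 0:
            polya = PolyAHit(
                start=0,
                end=0,
                length=int(row.polyALen),
                a_count=int(row.polyALen) - int(row.polyAInterruptions),
                interruptions=int(row.polyAInterruptions),
                score=int(row.polyAScore),
            )
        out.append(
            RetroCandidate(
                id=str(row.id),
                ref_chrom=str(row.chrom),
                start=int(row.start),
                end=int(row.end),
                strand=str(row.strand),
                tsd=tsd,
                polya=polya,
                source_chrom=str(row.sourceChrom),
                source_strand=str(row.sourceStrand),
                source_start=int(row.sourceStart),
                source_size=int(row.sourceSize),
                tsd_score=float(row.tsdScore),
                polya_score=float(row.polyAScore),
                total_score=float(row.totalScore),
                passed_filters=bool(row.passedFilters),
            )
        )
    return out


def write_outputs(candidates: Sequence[RetroCandidate], prefix: str) -> tuple[str, str]:
    """Write the BED6 insertion intervals and the extended TSV table."""
    frame = candidates_to_frame(candidates)
    tsv_path = f"{prefix}.candidates.tsv"
    bed_path = f"{prefix}.candidates.bed"
    frame.to_csv(tsv_path, sep="\t", index=False)
    with open(bed_path, "w") as fh:
        for c in candidates:
            fh.write(
                f"{c.ref_chrom}\t{c.start}\t{c.end}\t{c.id}\t{round(c.total_score)}\t{c.strand}\n"
            )
    return bed_path, tsv_path
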