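"""Insertion simulation and caller benchmarking.

The validation protocol: build a random genome, place one parental copy
of a LINE1-like element, splice in TPRT-style insertions (random-sequence
TSDs of 7-20 nt duplicated on both sides of the strand-oriented element
plus a 5-20 nt poly(A) tail) together with bare-element negative
controls, then emulate the net file a pairwise pre-vs-post whole-genome
alignment would produce: one level-1 fill spanning the backbone, a gap at
every inserted block, and a level-2 fill inside each gap whose reference
span covers the element body and whose query coordinates point at the
parental locus.  Fill edges are independently jittered by a few bases to
stand in for alignment-boundary fuzz.  Matching called candidates back to
the ground truth yields sensitivity, specificity and a ROC/AUC over the
candidate scores.

The emulation keeps the benchmark free of an external aligner; a net
produced by a real lastz/axtChain/chainNet run can be supplied to
:func:`retroseeker.detect.detect_candidates` directly instead.
"""

from __future__ import annotations

import importlib.resources
import json
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from ._seq import revcomp
from .detect import DetectParams, RetroCandidate, detect_candidates
from .netio import NetChrom, NetFile, NetNode

CHROM = "chrSim"


def load_default_element() -> str:
    """The bundled synthetic ~1 kb element used as the inserted sequence.

    It is a synthetic stand-in with realistic base composition, not a
    biological LINE1 consensus; any sequence may be supplied instead via
    ``SimConfig.element_sequence``.
    """
    path = importlib.resources.files("retroseeker").joinpath("data/element_synthetic.fa")
    lines = path.read_text().splitlines()
    return "".join(line.strip() for line in lines if not line.startswith(">")).upper()


@dataclass
class SimConfig:
    """Study conditions of the insertion benchmark.

    The full-scale protocol is a 60 Mb genome with 1000 true + 1000
    control insertions; the desk default keeps the identical per-insertion
    statistics (TSD 7-20 nt, poly(A) 5-20 nt, random strand) on a 5 Mb
    genome with 200 + 200 insertions.
    """

    genome_length: int = 5_000_000
    base_probs: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)  # A, C, G, T
    n_true: int = 200
    n_control: int = 200
    tsd_len_range: tuple[int, int] = (7, 20)
    polya_len_range: tuple[int, int] = (5, 20)
    element_sequence: Optional[str] = None  # default: bundled synthetic element
    strand_random: bool = True
    boundary_jitter: int = 3  # max +/- nt perturbation of emulated fill edges
    motif_mode: str = "off"  # "off" | "tprt"
    motif: str = "TTAAAA"
    motif_offset: int = 10  # nt between motif 3' end and the element 5' start
    min_spacing: int = 1000  # minimum distance between insertion sites
    seed: int = 0

    def __post_init__(self) -> None:
        if self.genome_length <= 0:
            raise ValueError("genome_length must be positive")
        if self.n_true < 0 or self.n_control < 0:
            raise ValueError("insertion counts must be >= 0")
        if self.tsd_len_range[0] < 1 or self.tsd_len_range[0] > self.tsd_len_range[1]:
            raise ValueError("bad tsd_len_range")
        if self.polya_len_range[0] < 1 or self.polya_len_range[0] > self.polya_len_range[1]:
            raise ValueError("bad polya_len_range")
        if self.motif_mode not in ("off", "tprt"):
            raise ValueError("motif_mode must be 'off' or 'tprt'")
        if abs(sum(self.base_probs) - 1.0) > 1e-9:
            raise ValueError("base_probs must sum to 1")

    def element(self) -> str:
        if self.element_sequence is not None:
            return self.element_sequence.upper()
        return load_default_element()


@dataclass
class InsertionTruth:
    """Ground truth for one simulated insertion."""

    id: str
    chrom: str
    pre_position: int  # cut site in the pre-insertion genome
    post_start: int  # inserted block interval in the post-insertion genome
    post_end: int
    strand: str
    tsd_seq: str
    tsd_len: int
    polya_len: int
    is_control: bool


@dataclass
class EvalResult:
    """Sensitivity/specificity and the score ROC of one benchmark run."""

    true_positives: int
    false_negatives: int
    false_positives: int
    true_negatives: int
    sensitivity: float
    specificity: float
    roc_points: list[tuple[float, float]]
    auc: float
    match_tolerance: int
    scores: list[float] = field(default_factory=list, repr=False)
    labels: list[int] = field(default_factory=list, repr=False)

    def to_dict(self) -> dict:
        return {
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "auc": self.auc,
            "truePositives": self.true_positives,
            "falseNegatives": self.false_negatives,
            "falsePositives": self.false_positives,
            "trueNegatives": self.true_negatives,
            "matchTolerance": self.match_tolerance,
            "rocPoints": [list(p) for p in self.roc_points],
        }

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


_BASES = np.frombuffer(b"ACGT", dtype="S1")


def random_genome(config: SimConfig, rng: np.random.Generator | None = None) -> dict[str, str]:
    """An i.i.d. random chromosome under ``base_probs``, named ``chrSim``."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    draw = rng.choice(_BASES, size=config.genome_length, p=list(config.base_probs))
    return {CHROM: draw.tobytes().decode("ascii")}


def _spaced_positions(
    rng: np.random.Generator,
    length: int,
    n: int,
    spacing: int,
    exclude: tuple[int, int] | None = None,
) -> list[int]:
    """n sorted cut positions pairwise >= spacing apart, avoiding `exclude`."""
    margin = spacing
    if length < 2 * margin + (n + 1) * spacing:
        raise ValueError("genome too short for the requested number of spaced insertions")
    for _ in range(50):
        draws = np.sort(rng.integers(margin, length - margin, size=6 * n + 16))
        kept: list[int] = []
        last = -(10 * spacing)
        for pos in draws:
            p = int(pos)
            if p - last < spacing:
                continue
            if exclude is not None and exclude[0] - spacing <= p < exclude[1] + spacing:
                continue
            kept.append(p)
            last = p
            if len(kept) == n:
                return kept
    raise ValueError("could not place all insertions after bounded retries")


def _apply_motif(
    tsd: list[str],
    pre: bytearray,
    cut: int,
    strand: str,
    offset: int,
    motif: str,
) -> None:
    """Write the endonuclease motif so its 3' end sits ``offset`` nt upstream
    of the element's 5' start (in element orientation).

    Bases falling inside the target site are written into the TSD sequence
    (hence into both duplicated copies); bases beyond it go into the
    flanking genome around the cut site.
    """
    L = len(tsd)
    if strand == "+":
        for i, ch in enumerate(motif):
            j = L - offset - len(motif) + i
            if 0 <= j < L:
                tsd[j] = ch
            elif j < 0 and cut + j >= 0:
                pre[cut + j] = ord(ch)
    else:
        for i, ch in enumerate(revcomp(motif)):
            j = offset + i
            if j < L:
                tsd[j] = ch
            elif cut + (j - L) < len(pre):
                # past the duplicated site: first bases after the insertion point
                pre[cut + (j - L)] = ord(ch)


def plant_insertions(
    pre: Mapping[str, str],
    config: SimConfig,
    rng: np.random.Generator | None = None,
    exclude: tuple[int, int] | None = None,
) -> tuple[dict[str, str], list[InsertionTruth]]:
    """Splice TPRT-style insertions and bare-element controls into ``pre``.

    True blocks are ``TSD + oriented(element + A^polyA) + TSD`` (on the
    minus strand the tail shows up as poly(T) 5'-ward on the reference);
    controls are the strand-oriented bare element.  Insertion sites are
    pairwise >= ``min_spacing`` apart.  Returns the post-insertion genome
    and exact ground-truth coordinates in it.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    element = config.element()
    pre_seq = pre[CHROM]
    n = config.n_true + config.n_control
    if n == 0:
        return {CHROM: pre_seq}, []

    cuts = _spaced_positions(rng, len(pre_seq), n, max(config.min_spacing, 1), exclude)
    is_control = np.zeros(n, dtype=bool)
    is_control[: config.n_control] = True
    rng.shuffle(is_control)

    pre_arr = bytearray(pre_seq, "ascii")
    blocks: list[str] = []
    truths: list[InsertionTruth] = []
    t_lo, t_hi = config.tsd_len_range
    p_lo, p_hi = config.polya_len_range
    for i, cut in enumerate(cuts):
        strand = "+"
        if config.strand_random and rng.integers(0, 2) == 1:
            strand = "-"
        if is_control[i]:
            block = element if strand == "+" else revcomp(element)
            truths.append(
                InsertionTruth(
                    id=f"ins-{i:05d}",
                    chrom=CHROM,
                    pre_position=cut,
                    post_start=-1,
                    post_end=-1,
                    strand=strand,
                    tsd_seq="",
                    tsd_len=0,
                    polya_len=0,
                    is_control=True,
                )
            )
        else:
            tsd_len = int(rng.integers(t_lo, t_hi + 1))
            polya_len = int(rng.integers(p_lo, p_hi + 1))
            tsd = [
                "ACGT"[b] for b in rng.integers(0, 4, size=tsd_len)
            ]
            if config.motif_mode == "tprt":
                _apply_motif(tsd, pre_arr, cut, strand, config.motif_offset, config.motif)
            tsd_seq = "".join(tsd)
            body = element + "A" * polya_len
            if strand == "-":
                body = revcomp(body)
            block = tsd_seq + body + tsd_seq
            truths.append(
                InsertionTruth(
                    id=f"ins-{i:05d}",
                    chrom=CHROM,
                    pre_position=cut,
                    post_start=-1,
                    post_end=-1,
                    strand=strand,
                    tsd_seq=tsd_seq,
                    tsd_len=tsd_len,
                    polya_len=polya_len,
                    is_control=False,
                )
            )
        blocks.append(block)

    pre_final = pre_arr.decode("ascii")
    pieces: list[str] = []
    offset = 0
    prev = 0
    for truth, block in zip(truths, blocks):
        cut = truth.pre_position
        pieces.append(pre_final[prev:cut])
        pieces.append(block)
        truth.post_start = cut + offset
        truth.post_end = truth.post_start + len(block)
        offset += len(block)
        prev = cut
    pieces.append(pre_final[prev:])
    return {CHROM: "".join(pieces)}, truths


def emulate_net(
    truths: Sequence[InsertionTruth],
    pre_length: int,
    post_length: int,
    parent_locus: tuple[str, int, int],
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> NetFile:
    """Build the net file a pre-vs-post pairwise alignment would yield.

    One level-1 fill spans the whole aligned backbone; each inserted block
    becomes a gap containing a level-2 fill over the element body whose
    query coordinates point at ``parent_locus`` (TSDs and the poly(A) tail
    have no counterpart at the parental locus, so they fall outside the
    fill).  Both fill edges are independently jittered by up to
    ``boundary_jitter`` bases and clamped inside their gap.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    parent_chrom, parent_start, parent_len = parent_locus
    jitter = config.boundary_jitter

    top = NetNode(
        kind="fill",
        ref_chrom=CHROM,
        ref_start=0,
        ref_size=post_length,
        query_chrom=parent_chrom,
        query_strand="+",
        query_start=0,
        query_size=pre_length,
        level=1,
        attributes=[("id", "1")],
    )
    for k, truth in enumerate(sorted(truths, key=lambda t: t.post_start), start=2):
        gap = NetNode(
            kind="gap",
            ref_chrom=CHROM,
            ref_start=truth.post_start,
            ref_size=truth.post_end - truth.post_start,
            query_chrom=parent_chrom,
            query_strand="+",
            query_start=truth.pre_position,
            query_size=0,
        )
        if truth.is_control:
            body_lo, body_hi = truth.post_start, truth.post_end
        elif truth.strand == "+":
            body_lo = truth.post_start + truth.tsd_len
            body_hi = truth.post_end - truth.tsd_len - truth.polya_len
        else:
            body_lo = truth.post_start + truth.tsd_len + truth.polya_len
            body_hi = truth.post_end - truth.tsd_len
        if jitter > 0:
            body_lo += int(rng.integers(-jitter, jitter + 1))
            body_hi += int(rng.integers(-jitter, jitter + 1))
        body_lo = max(truth.post_start, min(body_lo, truth.post_end - 1))
        body_hi = max(body_lo + 1, min(body_hi, truth.post_end))
        size = body_hi - body_lo
        if truth.strand == "+":
            q_start = parent_start
        else:
            q_start = pre_length - (parent_start + parent_len)
        fill = NetNode(
            kind="fill",
            ref_chrom=CHROM,
            ref_start=body_lo,
            ref_size=size,
            query_chrom=parent_chrom,
            query_strand=truth.strand,
            query_start=q_start,
            query_size=min(size, parent_len),
            level=2,
            attributes=[("id", str(k))],
        )
        gap.children.append(fill)
        top.children.append(gap)
    return NetFile(chroms=[NetChrom(name=CHROM, size=post_length, fills=[top])])


# ---------------------------------------------------------------------------
# scoring the caller against the truth
# ---------------------------------------------------------------------------


def _roc(scores: Sequence[float], labels: Sequence[int]) -> tuple[list[tuple[float, float]], float]:
    """ROC points (FPR, TPR) from a descending threshold sweep + trapezoidal AUC."""
    n_pos = sum(labels)
    n_neg = len(labels) - n_pos
    order = sorted(range(len(scores)), key=lambda i: -scores[i])
    points = [(0.0, 0.0)]
    tp = fp = 0
    i = 0
    while i < len(order):
        thr = scores[order[i]]
        if thr == float("-inf"):
            break  # unmatched loci are never predicted positive at a finite cut
        while i < len(order) and scores[order[i]] == thr:
            if labels[order[i]]:
                tp += 1
            else:
                fp += 1
            i += 1
        points.append((fp / n_neg if n_neg else 0.0, tp / n_pos if n_pos else 0.0))
    points.append((1.0, 1.0))
    xs = [p[0] for p in points]
    ys = [p[1] for p in points]
    auc = float(np.trapezoid(ys, xs))
    return points, auc


def evaluate(
    candidates: Sequence[RetroCandidate],
    truths: Sequence[InsertionTruth],
    match_tolerance: int = 20,
    params: DetectParams | None = None,
) -> EvalResult:
    """Match candidates to the simulated ground truth.

    A true insertion is recovered when a filter-passing candidate's
    insertion interval overlaps the truth interval extended by
    ``match_tolerance`` bases on each side; specificity is the fraction of
    control insertions yielding no passing candidate.  The ROC sweeps a
    score threshold over every locus's best matched candidate score
    (pass-filter or not; loci with no matched candidate never become
    positive), labelling true insertions positive and controls negative.
    """
    n_true = sum(1 for t in truths if not t.is_control)
    n_control = len(truths) - n_true
    if n_true == 0:
        raise ValueError("no positive instances: truth set contains no true insertions")

    trees: dict[str, IntervalTree] = {}
    for idx, cand in enumerate(candidates):
        trees.setdefault(cand.ref_chrom, IntervalTree()).addi(cand.start, max(cand.end, cand.start + 1), idx)

    tp = fp = 0
    scores: list[float] = []
    labels: list[int] = []
    for truth in truths:
        lo = truth.post_start - match_tolerance
        hi = truth.post_end + match_tolerance
        tree = trees.get(truth.chrom)
        matched = [candidates[iv.data] for iv in tree.overlap(lo, hi)] if tree else []
        any_pass = any(c.passed_filters for c in matched)
        best = max((c.total_score for c in matched), default=float("-inf"))
        labels.append(0 if truth.is_control else 1)
        scores.append(best)
        if truth.is_control:
            fp += int(any_pass)
        else:
            tp += int(any_pass)

    roc_points, auc = _roc(scores, labels)
    return EvalResult(
        true_positives=tp,
        false_negatives=n_true - tp,
        false_positives=fp,
        true_negatives=n_control - fp,
        sensitivity=tp / n_true,
        specificity=(n_control - fp) / n_control if n_control else float("nan"),
        roc_points=roc_points,
        auc=auc,
        match_tolerance=match_tolerance,
        scores=scores,
        labels=labels,
    )


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------


@dataclass
class SimResult:
    """Everything produced by one simulation: genomes, truth, net, parent locus."""

    pre: dict[str, str]
    post: dict[str, str]
    truths: list[InsertionTruth]
    net: NetFile
    parent_locus: tuple[str, int, int]


def run_simulation(config: SimConfig) -> SimResult:
    """Generate genome + insertions + emulated net under one seed."""
    rng = np.random.default_rng(config.seed)
    base = random_genome(config, rng)
    element = config.element()
    # place the single parental copy the inserted sequences will align to
    parent_pos = int(rng.integers(config.min_spacing, config.genome_length - config.min_spacing))
    pre_seq = base[CHROM][:parent_pos] + element + base[CHROM][parent_pos:]
    pre = {CHROM: pre_seq}
    parent_locus = (CHROM, parent_pos, len(element))
    post, truths = plant_insertions(
        pre, config, rng, exclude=(parent_pos, parent_pos + len(element))
    )
    net = emulate_net(truths, len(pre_seq), len(post[CHROM]), parent_locus, config, rng)
    return SimResult(pre=pre, post=post, truths=truths, net=net, parent_locus=parent_locus)


def benchmark(
    config: SimConfig,
    params: DetectParams | None = None,
    match_tolerance: int = 20,
) -> EvalResult:
    """Simulate, detect and evaluate in one call."""
    sim = run_simulation(config)
    candidates = detect_candidates(sim.net, sim.post, params)
    return evaluate(candidates, sim.truths, match_tolerance=match_tolerance, params=params)


TRUTH_COLUMNS = [
    "id", "chrom", "prePosition", "postStart", "postEnd",
    "strand", "tsdSeq", "tsdLen", "polyALen", "isControl",
]


def truths_to_frame(truths: Sequence[InsertionTruth]) -> pd.DataFrame:
    rows = [
        {
            "id": t.id,
            "chrom": t.chrom,
            "prePosition": t.pre_position,
            "postStart": t.post_start,
            "postEnd": t.post_end,
            "strand": t.strand,
            "tsdSeq": t.tsd_seq,
            "tsdLen": t.tsd_len,
            "polyALen": t.polya_len,
            "isControl": t.is_control,
        }
        for t in truths
    ]
    return pd.DataFrame(rows, columns=TRUTH_COLUMNS)


def frame_to_truths(frame: pd.DataFrame) -> list[InsertionTruth]:
    truths = []
    for row in frame.itertuples(index=False):
        truths.append(
            InsertionTruth(
                id=str(row.id),
                chrom=str(row.chrom),
                pre_position=int(row.prePosition),
                post_start=int(row.postStart),
                post_end=int(row.postEnd),
                strand=str(row.strand),
                tsd_seq="" if pd.isna(row.tsdSeq) else str(row.tsdSeq),
                tsd_len=int(row.tsdLen),
                polya_len=int(row.polyALen),
                is_control=bool(row.isControl),
            )
        )
    return truths
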