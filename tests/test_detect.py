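"""TSD/poly(A) search and the end-to-end caller."""

import numpy as np
import pytest

from conftest import random_seq
from oracles import polya_oracle, tsd_key, tsd_oracle

from retroseeker._seq import revcomp
from retroseeker.detect import (
    DetectParams,
    PolyAHit,
    RetroCandidate,
    TSDHit,
    candidates_to_frame,
    detect_candidates,
    extend_flanks,
    filter_candidates,
    find_polya,
    find_tsd,
    score_candidate,
)
from retroseeker.netio import parse_net


# ---------------------------------------------------------------------------
# flank extraction
# ---------------------------------------------------------------------------


def test_extend_flanks_arithmetic(params, rng):
    genome = {"chr1": random_seq(rng, 1000)}
    fl = extend_flanks(genome, "chr1", 100, 200, params)
    assert (fl.left_offset, fl.left_offset + len(fl.left)) == (70, 130)
    assert (fl.right_offset, fl.right_offset + len(fl.right)) == (170, 230)
    assert fl.left == genome["chr1"][70:130]
    assert fl.right == genome["chr1"][170:230]
    assert (fl.left_edge, fl.right_edge) == (30, 30)


def test_extend_flanks_clamped_at_chromosome_start(params, rng):
    genome = {"chr1": random_seq(rng, 1000)}
    fl = extend_flanks(genome, "chr1", 5, 200, params)
    assert (fl.left_offset, fl.left_offset + len(fl.left)) == (0, 35)
    assert fl.left_edge == 5


def test_extend_flanks_offsets_recover_reference(params, rng):
    genome = {"chr1": random_seq(rng, 500)}
    fl = extend_flanks(genome, "chr1", 120, 300, params)
    for i in range(len(fl.left)):
        assert fl.left[i] == genome["chr1"][fl.left_to_ref(i)]
    for i in range(len(fl.right)):
        assert fl.right[i] == genome["chr1"][fl.right_to_ref(i)]


def test_unknown_chromosome_raises(params):
    with pytest.raises(KeyError, match="chrX"):
        extend_flanks({"chr1": "ACGT" * 100}, "chrX", 10, 50, params)


# ---------------------------------------------------------------------------
# TSD search
# ---------------------------------------------------------------------------


def test_find_tsd_exact_eight_mer(params):
    left = "T" * 16 + "GATTACAG"
    right = "GATTACAG" + "C" * 16
    hit = find_tsd(left, right, params, left_edge=len(left), right_edge=0)
    assert hit is not None
    assert (hit.length, hit.mismatches, hit.indels, hit.score) == (8, 0, 0, 8)
    assert hit.seq_left == hit.seq_right == "GATTACAG"


def test_find_tsd_rejects_six_mer_under_default_floor(params):
    # flanks engineered so no 7-column alignment with <= 1 edit exists
    left = "T" * 16 + "GATTAC"
    right = "GATTAC" + "G" * 16
    assert find_tsd(left, right, params, left_edge=len(left), right_edge=0) is None


def test_find_tsd_none_on_disjoint_flanks(params):
    assert find_tsd("T" * 30, "C" * 30, params, left_edge=30, right_edge=0) is None


def _hit_key(hit, left_edge):
    return tsd_key(hit.score, hit.length, hit.mismatches, hit.indels,
                   hit.left_end, hit.right_start, left_edge)


@pytest.mark.parametrize("budget", [0, 1])
def test_find_tsd_matches_exhaustive_oracle(budget, rng):
    """Optimal substring-pair search, checked by brute-force enumeration."""
    p = DetectParams(max_tsd_mismatches=budget)
    for trial in range(60):
        n = int(rng.integers(15, 41))
        left = random_seq(rng, n)
        right = random_seq(rng, n)
        if trial % 2 == 0:  # plant a duplication so hits exist
            t = int(rng.integers(7, 15))
            tsd = random_seq(rng, t)
            left = left[: n - t] + tsd
            right = tsd + right[t:]
        hit = find_tsd(left, right, p, left_edge=n, right_edge=0)
        expected = tsd_oracle(left, right, p, left_edge=n, right_edge=0)
        got = None if hit is None else _hit_key(hit, n)
        assert got == expected, (left, right)


# ---------------------------------------------------------------------------
# poly(A) search
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "seq, expected",
    [
        ("GG" + "A" * 8, (8, 8, 0, 8)),  # pure maximal run
        ("GG" + "A" * 4, None),  # below the 5 nt floor
        ("CC" + "AAAAGAAA", (8, 7, 1, 6)),  # one internal interruption
        ("AAAAAAGGGGGGG", None),  # run too far from the TSD edge
        ("GAAAAAGG", (5, 5, 0, 5)),  # within the 5 nt gap allowance
    ],
)
def test_find_polya_examples(seq, expected, params):
    hit = find_polya(seq, params)
    if expected is None:
        assert hit is None
    else:
        assert (hit.length, hit.a_count, hit.interruptions, hit.score) == expected


def test_find_polya_matches_exhaustive_scan(params, rng):
    for _ in range(300):
        seq = random_seq(rng, int(rng.integers(5, 40)), bases="AACGT")
        hit = find_polya(seq, params)
        expected = polya_oracle(seq, params)
        if expected is None:
            assert hit is None
        else:
            assert (hit.length, hit.a_count, hit.interruptions, hit.start, hit.end) == expected


def test_find_polya_terminal_positions_must_be_a(params):
    # a trailing non-A cannot be absorbed as an interruption
    assert find_polya("GAAAAG", params) is None
    hit = find_polya("GAAAAA", params)
    assert hit.length == 5 and hit.interruptions == 0


# ---------------------------------------------------------------------------
# scoring
# ---------------------------------------------------------------------------


def _tsd(length, mism=0, ind=0):
    return TSDHit(0, length, 100, 100 + length, length, length - mism - ind, mism, ind,
                  length - 2 * mism - 2 * ind)


def _polya(length, interruptions=0):
    return PolyAHit(0, length, length, length - interruptions, interruptions,
                    length - 2 * interruptions)


def test_score_minimal_passing_candidate():
    assert score_candidate(_tsd(7), _polya(5)) == (7.0, 5.0, 12.0)


def test_score_typical_candidate_in_reported_envelope():
    # a 15 nt exact TSD plus a pure 10 nt tail sits inside the 20-30 band
    assert score_candidate(_tsd(15), _polya(10)) == (15.0, 10.0, 25.0)


def test_score_monotone_in_evidence():
    base = score_candidate(_tsd(10), _polya(8))[2]
    assert score_candidate(_tsd(10), _polya(9))[2] > base
    assert score_candidate(_tsd(11), _polya(8))[2] > base
    assert score_candidate(_tsd(10, mism=1), _polya(8))[2] < base
    assert score_candidate(_tsd(10), _polya(8, interruptions=1))[2] < base


# ---------------------------------------------------------------------------
# end-to-end caller on constructed fixtures
# ---------------------------------------------------------------------------


def _fixture_genome(rng, strand, tsd="GCTAGCAT", polya_len=9, element_len=300):
    """Backbone + one planted TPRT insertion; returns (genome, net_text, layout)."""
    element = random_seq(rng, element_len)
    while element[-1] == "A":
        element = element[:-1] + "G"
    body = element + "A" * polya_len
    if strand == "-":
        body = revcomp(body)
    block = tsd + body + tsd
    backbone = random_seq(rng, 4000)
    cut = 2000
    genome = {"chrSim": backbone[:cut] + block + backbone[cut:]}
    block_lo, block_hi = cut, cut + len(block)
    if strand == "+":
        fill_lo, fill_hi = block_lo + len(tsd), block_hi - len(tsd) - polya_len
    else:
        fill_lo, fill_hi = block_lo + len(tsd) + polya_len, block_hi - len(tsd)
    size = len(genome["chrSim"])
    net_text = (
        f"net chrSim {size}\n"
        f" fill 0 {size} chrQ + 0 4000\n"
        f"  gap {block_lo} {len(block)} chrQ + {cut} 0\n"
        f"   fill {fill_lo} {fill_hi - fill_lo} chrQ {strand} 100 {fill_hi - fill_lo}\n"
    )
    return genome, net_text, (block_lo, block_hi, tsd, polya_len)


def test_detect_plus_strand_insertion(rng):
    genome, net_text, (lo, hi, tsd, polya_len) = _fixture_genome(rng, "+")
    cands = detect_candidates(parse_net(net_text), genome)
    assert len(cands) == 1
    c = cands[0]
    assert c.strand == "+"
    assert c.passed_filters
    assert c.tsd.length >= len(tsd)
    assert c.polya.length >= polya_len
    assert c.start >= lo and c.end <= hi
    assert c.id == "sim-retrotransposon-1"


def test_detect_minus_strand_insertion(rng):
    genome, net_text, (lo, hi, tsd, polya_len) = _fixture_genome(rng, "-")
    (c,) = detect_candidates(parse_net(net_text), genome)
    assert c.strand == "-"
    assert c.passed_filters
    assert c.tsd.length >= len(tsd)
    assert c.polya.length >= polya_len
    # the tail shows up as poly(T) on the reference, just inside the 5' TSD
    assert "T" * 5 in genome["chrSim"][c.start : c.start + polya_len + 5]


def mirror_net(net, length):
    """Reverse-complement transform of a net file (for symmetry checks)."""
    import copy

    flipped = copy.deepcopy(net)

    def flip(node):
        node.ref_start = length - (node.ref_start + node.ref_size)
        node.query_strand = "+" if node.query_strand == "-" else "-"
        node.children.reverse()
        for child in node.children:
            flip(child)

    for chrom in flipped.chroms:
        chrom.fills.reverse()
        for fill in chrom.fills:
            flip(fill)
    return flipped


def test_detect_strand_symmetry_under_reverse_complement(small_sim):
    """Mirroring the genome mirrors every passing call with identical scores."""
    _, sim = small_sim
    length = len(sim.post["chrSim"])
    fwd = filter_candidates(detect_candidates(sim.net, sim.post))
    mirrored_genome = {"chrSim": revcomp(sim.post["chrSim"])}
    rev = filter_candidates(detect_candidates(mirror_net(sim.net, length), mirrored_genome))
    flip_strand = {"+": "-", "-": "+"}
    fwd_set = sorted((c.start, c.end, c.strand, c.total_score) for c in fwd)
    rev_set = sorted(
        (length - c.end, length - c.start, flip_strand[c.strand], c.total_score) for c in rev
    )
    assert fwd_set == rev_set and len(fwd_set) > 0


def test_detect_gap_without_fill_gives_no_candidates(rng):
    genome = {"chrSim": random_seq(rng, 2000)}
    net = parse_net("net chrSim 2000\n fill 0 2000 chrQ + 0 2000\n  gap 500 100 chrQ + 500 0\n")
    assert detect_candidates(net, genome) == []


def test_detect_missing_chromosome_raises(rng):
    net = parse_net("net chrZ 2000\n fill 0 2000 chrQ + 0 2000\n  gap 500 100 chrQ + 500 0\n   fill 520 50 chrQ + 10 50\n")
    with pytest.raises(KeyError, match="chrZ"):
        detect_candidates(net, {"chrSim": "ACGT" * 500})


def test_detect_is_deterministic(small_sim):
    _, sim = small_sim
    a = candidates_to_frame(detect_candidates(sim.net, sim.post))
    b = candidates_to_frame(detect_candidates(sim.net, sim.post))
    assert a.equals(b)


# ---------------------------------------------------------------------------
# filtering
# ---------------------------------------------------------------------------


def _candidate(tsd_len, polya_len):
    tsd = _tsd(tsd_len)
    polya = _polya(polya_len)
    total = float(tsd.score + polya.score)
    return RetroCandidate(
        id=f"c{tsd_len}_{polya_len}", ref_chrom="chr1", start=100, end=500,
        strand="+", tsd=tsd, polya=polya, source_chrom="chr2", source_strand="+",
        source_start=0, source_size=400, tsd_score=float(tsd.score),
        polya_score=float(polya.score), total_score=total, passed_filters=True,
    )


def test_filter_enforces_both_length_floors():
    cands = [_candidate(t, p) for t in range(5, 11) for p in range(3, 9)]
    kept = filter_candidates(cands)
    assert kept, "grid contains passing candidates"
    assert min(c.tsd.length for c in kept) == 7
    assert min(c.polya.length for c in kept) == 5
    assert all(c.total_score >= 12 for c in kept)


def test_filter_empty_input():
    assert filter_candidates([]) == []


def test_filter_soundness_on_simulated_candidates(small_sim):
    _, sim = small_sim
    p = DetectParams()
    for c in filter_candidates(detect_candidates(sim.net, sim.post), p):
        assert c.tsd.length >= p.min_tsd_len
        assert c.polya.length >= p.min_polya_len
        assert c.total_score >= p.min_score
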