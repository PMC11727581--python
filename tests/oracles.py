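"""Independent brute-force oracles used by the test suite.

These deliberately share no code with the package: the TSD oracle
enumerates every admissible substring pair, the poly(A) oracle scans all
windows, and the AUC oracle uses the Mann-Whitney rank formulation.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import rankdata


def _align_once(u: str, v: str, budget: int):
    """Best unit-score global alignment of u vs v with <= budget edits and
    matching terminal columns; returns (matches, mismatches, indels) or None."""
    if not u or not v or u[0] != v[0] or u[-1] != v[-1]:
        return None
    m, n = len(u), len(v)
    if abs(m - n) > budget:
        return None
    if m == n:
        mism = sum(1 for a, b in zip(u, v) if a != b)
        if mism <= budget:
            return (m - mism, mism, 0)
        return None
    if budget >= 1 and abs(m - n) == 1:
        a, b = (u, v) if m < n else (v, u)
        i = 0
        while i < len(a) and a[i] == b[i]:
            i += 1
        j = 0
        while j < len(a) and a[len(a) - 1 - j] == b[len(b) - 1 - j]:
            j += 1
        if i + j >= len(a):
            return (len(a), 0, 1)
    return None


def tsd_key(score, length, mismatches, indels, left_end, right_start, left_edge):
    """Total order used to rank TSD alignments (higher is better)."""
    return (score, length, -mismatches, -indels, -abs(left_end - left_edge),
            -left_end, -right_start)


def tsd_oracle(left: str, right: str, params, left_edge: int, right_edge: int):
    """Exhaustive search over all (left substring, right substring) pairs.

    Only valid for edit budgets <= 1.  Returns the best ranking key or None.
    """
    assert params.max_tsd_mismatches <= 1
    e_lo = max(1, left_edge - params.extend_in)
    e_hi = min(len(left), left_edge + params.extend_in)
    s_lo = max(0, right_edge - params.extend_in)
    s_hi = min(len(right) - 1, right_edge + params.extend_in)
    best = None
    for e_l in range(e_lo, e_hi + 1):
        for s_r in range(s_lo, s_hi + 1):
            for m in range(1, e_l + 1):
                lo = max(1, m - params.max_tsd_mismatches)
                hi = min(len(right) - s_r, m + params.max_tsd_mismatches)
                for n in range(lo, hi + 1):
                    res = _align_once(left[e_l - m : e_l], right[s_r : s_r + n],
                                      params.max_tsd_mismatches)
                    if res is None:
                        continue
                    matches, mism, ind = res
                    if matches + mism + ind < params.min_tsd_len:
                        continue
                    key = tsd_key(matches - mism - ind, matches + mism + ind,
                                  mism, ind, e_l, s_r, left_edge)
                    if best is None or key > best:
                        best = key
    return best


def polya_oracle(seq: str, params):
    """Scan every window for the best qualifying poly(A) run.

    Returns (length, a_count, interruptions, start, end) or None.
    """
    n = len(seq)
    best_key = None
    best = None
    for end in range(1, n + 1):
        if n - end > params.polya_max_gap_from_tsd:
            continue
        for start in range(0, end):
            run = seq[start:end]
            if len(run) < params.min_polya_len:
                continue
            if run[0] != "A" or run[-1] != "A":
                continue
            interruptions = sum(1 for c in run if c != "A")
            if interruptions > params.max_polya_interruptions:
                continue
            a_count = len(run) - interruptions
            key = (len(run), a_count - interruptions, end, -start)
            if best_key is None or key > best_key:
                best_key = key
                best = (len(run), a_count, interruptions, start, end)
    return best


def rank_auc(scores, labels) -> float:
    """Mann-Whitney AUC with midrank tie handling."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    # rankdata cannot take -inf reliably across versions; map to a finite floor
    finite = scores[np.isfinite(scores)]
    floor = (finite.min() - 1.0) if finite.size else -1.0
    scores = np.where(np.isfinite(scores), scores, floor)
    ranks = rankdata(scores)
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    if n_pos == 0 or n_neg == 0:
        return float("nan")
    u = ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))
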