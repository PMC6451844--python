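"""Independent oracles used by the test suite.

Each oracle is implemented with a different algorithm (or a different
library) than the code under test, so agreement is evidence of correctness
rather than tautology.
"""

from __future__ import annotations

from Bio import Align

_PAIR_W = {
    ("G", "C"): 3, ("C", "G"): 3,
    ("A", "T"): 2, ("T", "A"): 2,
    ("G", "T"): 1, ("T", "G"): 1,
}


def best_fold_weight(seq: str) -> int:
    """Maximum weighted pairing by exhaustive top-down recursion (no memo).

    Enumerates every pseudoknot-free structure with minimum hairpin loop 3
    over the interval; feasible for sequences up to ~14 nt.
    """

    def best(i: int, j: int) -> int:
        if j - i < 4:
            return 0
        result = best(i + 1, j)  # i unpaired
        for k in range(i + 4, j + 1):
            w = _PAIR_W.get((seq[i], seq[k]), 0)
            if w:
                result = max(result, w + best(i + 1, k - 1) + best(k + 1, j))
        return result

    return best(0, len(seq) - 1)


def nw_global(a: str, b: str, match=1, mismatch=-2, gap=-3) -> int:
    """Plain global alignment score with a linear gap penalty."""
    m, n = len(a), len(b)
    prev = [j * gap for j in range(n + 1)]
    for i in range(1, m + 1):
        cur = [i * gap] + [0] * n
        for j in range(1, n + 1):
            s = match if a[i - 1] == b[j - 1] else mismatch
            cur[j] = max(prev[j - 1] + s, prev[j] + gap, cur[j - 1] + gap)
        prev = cur
    return prev[n]


def brute_local(a: str, b: str) -> int:
    """Best local score as the max global score over all substring pairs.

    O(n^4) substring pairs, each scored by full global alignment; only for
    very short sequences.
    """
    best = 0
    for i in range(len(a)):
        for j in range(i + 1, len(a) + 1):
            for k in range(len(b)):
                for l in range(k + 1, len(b) + 1):
                    best = max(best, nw_global(a[i:j], b[k:l]))
    return best


def biopython_local(a: str, b: str) -> float:
    """Smith-Waterman score via Biopython's independent aligner."""
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = 1
    aligner.mismatch_score = -2
    aligner.open_gap_score = -3
    aligner.extend_gap_score = -3
    return float(aligner.score(a, b))


def bisect_lambda(p_match=0.25, s_match=1, s_mismatch=-2, tol=1e-12) -> float:
    """Karlin-Altschul lambda by plain bisection on the moment condition."""

    def f(lam: float) -> float:
        from math import exp

        return p_match * exp(lam * s_match) + (1 - p_match) * exp(lam * s_mismatch) - 1.0

    lo, hi = 1e-9, 10.0
    assert f(lo) < 0 < f(hi)
    while hi - lo > tol:
        mid = (lo + hi) / 2
        if f(mid) < 0:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2
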