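"""Independent brute-force oracles used to check the library implementations.

Each oracle computes its quantity by exhaustive enumeration or exact
rational arithmetic, sharing no code path with the implementation it checks.
"""

from fractions import Fraction
from itertools import combinations
from math import comb

STOPS = ("TAA", "TAG", "TGA")
_COMP = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq):
    return seq.translate(_COMP)[::-1]


def brute_force_orfs(seq, min_len_aa):
    """Every (strand, start, end) triple that is a complete ATG->stop ORF.

    Checks all triples: start codon ATG, end codon a stop, no internal
    in-frame stop, protein length >= min_len_aa.  Returns a set of
    (strand, frame, start, end) tuples on strand-local coordinates.
    """
    found = set()
    for strand, s in (("+", seq), ("-", revcomp(seq))):
        n = len(s)
        for start in range(n - 2):
            if s[start:start + 3] != "ATG":
                continue
            for end in range(start + 6, n + 1, 3):
                if s[end - 3:end] not in STOPS:
                    continue
                internal = any(s[i:i + 3] in STOPS
                               for i in range(start, end - 3, 3))
                if internal:
                    break
                if (end - start) // 3 - 1 >= min_len_aa:
                    found.add((strand, start % 3, start, end))
                break  # first in-frame stop only
    return found


def _alignment_paths(n, m):
    """All global alignment op strings between sequences of length n and m."""
    if n == 0 and m == 0:
        yield ""
        return
    if n > 0:
        for rest in _alignment_paths(n - 1, m):
            yield "D" + rest          # consume a only (gap in b)
    if m > 0:
        for rest in _alignment_paths(n, m - 1):
            yield "I" + rest          # consume b only (gap in a)
    if n > 0 and m > 0:
        for rest in _alignment_paths(n - 1, m - 1):
            yield "M" + rest


def _score_path(path, a, b, matrix, gap_open, gap_extend):
    score, i, j = 0.0, 0, 0
    run = None
    for op in path:
        if op == "M":
            score += matrix[a[i], b[j]]
            i, j, run = i + 1, j + 1, None
        else:
            score -= gap_open if run != op else gap_extend
            run = op
            if op == "D":
                i += 1
            else:
                j += 1
    return score


def brute_force_local_align(a, b, matrix, gap_open=11.0, gap_extend=1.0):
    """Best local alignment score by enumerating every substring pair and
    every alignment path between them.  Gap of length k costs
    gap_open + (k-1) * gap_extend; the empty alignment scores 0."""
    best = 0.0
    for i1 in range(len(a) + 1):
        for j1 in range(i1, len(a) + 1):
            for i2 in range(len(b) + 1):
                for j2 in range(i2, len(b) + 1):
                    sub_a, sub_b = a[i1:j1], b[i2:j2]
                    for path in _alignment_paths(len(sub_a), len(sub_b)):
                        best = max(best, _score_path(
                            path, sub_a, sub_b, matrix, gap_open, gap_extend))
    return best


def fisher_two_sided(a, b, c, d):
    """Exact two-sided Fisher p by rational enumeration over the support."""
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    denom = comb(n, c1)
    def pmf(x):
        return Fraction(comb(r1, x) * comb(r2, c1 - x), denom)
    p_obs = pmf(a)
    total = Fraction(0)
    for x in range(max(0, c1 - r2), min(r1, c1) + 1):
        if pmf(x) <= p_obs:
            total += pmf(x)
    return float(total)


def hypergeom_upper_tail(M, K, n, k):
    """P(X >= k) by enumerating all C(M, n) study draws (M small)."""
    hits = sum(1 for draw in combinations(range(M), n)
               if sum(1 for x in draw if x < K) >= k)
    return float(Fraction(hits, comb(M, n)))


def bh_stepup(pvals):
    """Benjamini-Hochberg by the textbook step-up formula."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    adj = [0.0] * m
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, pvals[i] * m / rank)
        adj[i] = running
    return adj
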