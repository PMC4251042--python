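"""Test helpers: tiny protein factory and brute-force alignment oracles.

The oracles enumerate every possible alignment explicitly (exponential, fine
for lengths <= 5) and are kept entirely independent of the dynamic-programming
implementation they check.
"""

from functools import lru_cache

import foldrec as fr


def make_protein(pid, seq, fam, sf=None, fold=None, **kw):
    sf = sf if sf is not None else f"sf_{fam}"
    fold = fold if fold is not None else f"fold_{sf}"
    return fr.Protein(pid, seq, fam, sf, fold, **kw)


def brute_force_global(a, b, score, gap_open, gap_extend):
    """Best global alignment score by exhaustive recursion.

    ``score(i, j)`` gives the substitution score for a[i] vs b[j].  A gap of
    length g costs gap_open + (g - 1) * gap_extend; ``state`` tracks whether
    the previous move opened a gap in the same direction.
    """

    @lru_cache(maxsize=None)
    def best(i, j, state):
        # state: 0 = last move was a match/start, 1 = gap in b, 2 = gap in a
        if i == len(a) and j == len(b):
            return 0.0
        options = []
        if i < len(a) and j < len(b):
            options.append(score(i, j) + best(i + 1, j + 1, 0))
        if i < len(a):
            cost = gap_extend if state == 1 else gap_open
            options.append(cost + best(i + 1, j, 1))
        if j < len(b):
            cost = gap_extend if state == 2 else gap_open
            options.append(cost + best(i, j + 1, 2))
        return max(options)

    return best(0, 0, 0)


def brute_force_local(a, b, score, gap_open, gap_extend):
    """Best local alignment score: max over all substring pairs of the best
    alignment without leading or trailing gaps, floored at zero."""

    @lru_cache(maxsize=None)
    def best_ending_here(i, j, state):
        # best score of an alignment path that ends by consuming a[i]/b[j]
        # (state 0) or ends inside a gap (states 1/2), starting anywhere.
        if state == 0:
            base = score(i, j)
            prev = [0.0]
            if i > 0 and j > 0:
                prev.append(best_ending_here(i - 1, j - 1, 0))
                prev.append(best_ending_here(i - 1, j - 1, 1))
                prev.append(best_ending_here(i - 1, j - 1, 2))
            return base + max(prev)
        if state == 1:  # gap consuming a[i], j is the last b position used
            opts = []
            if i > 0:
                opts.append(best_ending_here(i - 1, j, 0) + gap_open)
                opts.append(best_ending_here(i - 1, j, 1) + gap_extend)
            return max(opts) if opts else float("-inf")
        opts = []
        if j > 0:
            opts.append(best_ending_here(i, j - 1, 0) + gap_open)
            opts.append(best_ending_here(i, j - 1, 2) + gap_extend)
        return max(opts) if opts else float("-inf")

    best = 0.0
    for i in range(len(a)):
        for j in range(len(b)):
            best = max(best, best_ending_here(i, j, 0))
    return best
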