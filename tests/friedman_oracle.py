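"""Brute-force reference implementation of the tie-corrected Friedman test.

Deliberately naive: ranks are computed by pairwise comparison counts, sums
by explicit loops, and tie groups by direct counting.  Shares no code with
``lvtdm.evaluation`` so it can serve as an independent oracle in tests.
"""

import math


def brute_force_friedman(table):
    """Return (rank_sums, chi_square, C) for a list-of-rows ordinal table."""
    n = len(table)
    k = len(table[0])
    rank_sums = [0.0] * k
    tie_term = 0
    for row in table:
        for j, x in enumerate(row):
            less = sum(1 for y in row if y < x)
            equal = sum(1 for y in row if y == x)  # includes self
            # mid-rank: average of ranks less+1 .. less+equal
            rank_sums[j] += less + (equal + 1) / 2.0
        for v in set(row):
            t = sum(1 for y in row if y == v)
            tie_term += t**3 - t
    chi_u = 12.0 * sum(r * r for r in rank_sums) / (n * k * (k + 1)) - 3.0 * n * (k + 1)
    C = 1.0 - tie_term / (n * k * (k * k - 1))
    if C <= 0:
        return rank_sums, 0.0, 0.0
    return rank_sums, max(chi_u / C, 0.0), C


def chi2_sf_df2(x):
    """Closed-form chi-square upper tail for two degrees of freedom."""
    return math.exp(-x / 2.0)
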