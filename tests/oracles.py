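"""Independent brute-force oracles used by the test suite.

These deliberately re-derive quantities by enumeration or simulation,
without touching the implementation paths they check.
"""

from fractions import Fraction
from math import comb

import numpy as np


def otsu_bruteforce(hist):
    """Exhaustive argmax of between-class variance over all 256 thresholds.

    Plain Python loops; returns (threshold, degenerate).
    """
    total = sum(hist)
    best_t, best_sigma = 0, -1.0
    for t in range(256):
        w0 = sum(hist[: t + 1])
        w1 = total - w0
        if w0 == 0 or w1 == 0:
            sigma = 0.0
        else:
            mu0 = sum(i * hist[i] for i in range(t + 1)) / w0
            mu1 = sum(i * hist[i] for i in range(t + 1, 256)) / w1
            sigma = w0 * w1 * (mu0 - mu1) ** 2
        if sigma > best_sigma:
            best_t, best_sigma = t, sigma
    return best_t, best_sigma == 0.0


def fisher_two_sided_exact(a, b, c, d):
    """Two-sided Fisher p as an exact rational, by hypergeometric enumeration.

    Sums P(table) over all tables with the observed margins whose
    probability does not exceed the observed table's.
    """
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    denom = comb(n, c1)
    p_obs = Fraction(comb(r1, a) * comb(r2, c1 - a), denom)
    total = Fraction(0)
    for k in range(max(0, c1 - r2), min(r1, c1) + 1):
        p_k = Fraction(comb(r1, k) * comb(r2, c1 - k), denom)
        if p_k <= p_obs:
            total += p_k
    return total


def chi2_stat(a, b, c, d):
    n = a + b + c + d
    return n * (a * d - b * c) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))


def chi2_permutation_p(a, b, c, d, n_perm=100_000, seed=0, mid_p=True):
    """Permutation null for the 2x2 chi-square: margins fixed, the count in
    cell (1,1) is hypergeometric.

    With ``mid_p`` (default) ties with the observed statistic count half —
    the standard mid-P convention for a discrete null, which is what the
    continuous asymptotic chi-square p approximates; ``mid_p=False`` gives
    the plain at-least-as-extreme share.
    """
    rng = np.random.default_rng(seed)
    r1, r2 = a + b, c + d
    c1 = a + c
    obs = chi2_stat(a, b, c, d)
    ks = rng.hypergeometric(r1, r2, c1, size=n_perm)
    uniq, counts = np.unique(ks, return_counts=True)
    stats = np.array([chi2_stat(k, r1 - k, c1 - k, r2 - (c1 - k)) for k in uniq])
    above = counts[stats > obs + 1e-12].sum()
    ties = counts[np.abs(stats - obs) <= 1e-12].sum()
    if mid_p:
        return float((above + 0.5 * ties) / n_perm)
    return float((above + ties) / n_perm)


def anova_f_by_hand(groups):
    """F from explicit sums of squares."""
    allv = [v for g in groups for v in g]
    grand = sum(allv) / len(allv)
    means = [sum(g) / len(g) for g in groups]
    ss_b = sum(len(g) * (m - grand) ** 2 for g, m in zip(groups, means))
    ss_w = sum((v - m) ** 2 for g, m in zip(groups, means) for v in g)
    df_b = len(groups) - 1
    df_w = len(allv) - len(groups)
    return (ss_b / df_b) / (ss_w / df_w)
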