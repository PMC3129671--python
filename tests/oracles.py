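"""Independent brute-force oracles used by the test suite.

Everything here is deliberately written as direct transcriptions of the
definitions (loops, rational arithmetic, sorting), sharing no code with the
implementation it checks.
"""

from fractions import Fraction
from math import comb

import numpy as np


def hwe_exact_bruteforce(n_hom_ref, n_het, n_hom_alt):
    """Exact two-sided HWE p-value by enumerating the conditional
    heterozygote-count distribution with rational arithmetic.

    P(N_het = h | allele counts) = C(n,h) C(n-h,(nA-h)/2) 2^h / C(2n, nA)
    summed over all h at least as improbable as the observed count.
    """
    n = n_hom_ref + n_het + n_hom_alt
    n_a = 2 * min(n_hom_ref, n_hom_alt) + n_het  # rare allele count
    denom = comb(2 * n, n_a)
    probs = {}
    for h in range(n_a % 2, min(n_a, 2 * n - n_a) + 1, 2):
        hom_rare = (n_a - h) // 2
        hom_common = n - h - hom_rare
        num = (Fraction(comb(n, h)) * comb(n - h, hom_rare) * (2 ** h))
        probs[h] = num / denom
    assert sum(probs.values()) == 1
    p_obs = probs[n_het]
    return float(sum(p for p in probs.values() if p <= p_obs))


def greedy_maximal_runs(calls, max_het=0.01):
    """Leftmost-greedy maximal homozygous runs honoring the overall het rule.

    Ignores gap structure (single-range / disabled gap arrays) and emits
    spans bounded by homozygous calls with >= 2 loci.
    """
    calls = list(calls)
    n = len(calls)
    hom = [c in (0, 2) for c in calls]
    out = []
    i = 0
    while i < n:
        if not hom[i]:
            i += 1
            continue
        best = None
        for j in range(i, n):
            if not hom[j]:
                continue
            span = calls[i:j + 1]
            if span.count(1) / len(span) <= max_het:
                best = j
        assert best is not None
        if best - i + 1 >= 2:
            out.append((i, best))
        i = best + 1
    return out


def quantile_type7(values, p):
    """Linear-interpolation quantile, written from the definition."""
    v = sorted(float(x) for x in values)
    n = len(v)
    h = (n - 1) * p
    lo = int(np.floor(h))
    hi = min(lo + 1, n - 1)
    return v[lo] + (h - lo) * (v[hi] - v[lo])


def cvm_bruteforce(a, b):
    """ω² by double loops over the unique combined values."""
    a = [float(x) for x in a]
    b = [float(x) for x in b]
    total = 0.0
    for x in sorted(set(a) | set(b)):
        fa = sum(1 for v in a if v <= x) / len(a)
        fb = sum(1 for v in b if v <= x) / len(b)
        total += (fa - fb) ** 2
    return total


def wc_theta_fraction(counts_a, counts_b):
    """Weir-Cockerham two-population genotype-based θ with exact rationals."""
    n1 = Fraction(sum(counts_a))
    n2 = Fraction(sum(counts_b))
    p1 = Fraction(2 * counts_a[0] + counts_a[1], 2 * sum(counts_a))
    p2 = Fraction(2 * counts_b[0] + counts_b[1], 2 * sum(counts_b))
    h1 = Fraction(counts_a[1], sum(counts_a))
    h2 = Fraction(counts_b[1], sum(counts_b))
    r = 2
    nbar = (n1 + n2) / r
    nc = (r * nbar - (n1 * n1 + n2 * n2) / (r * nbar)) / (r - 1)
    pbar = (n1 * p1 + n2 * p2) / (r * nbar)
    s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
    hbar = (n1 * h1 + n2 * h2) / (r * nbar)
    a = (nbar / nc) * (s2 - (pbar * (1 - pbar) - s2 * Fraction(r - 1, r)
                             - hbar / 4) / (nbar - 1))
    b = (nbar / (nbar - 1)) * (pbar * (1 - pbar) - s2 * Fraction(r - 1, r)
                               - hbar * (2 * nbar - 1) / (4 * nbar))
    c = hbar / 2
    if a + b + c == 0:
        return float("nan")
    return float(a / (a + b + c))


def ecdf_integral_quadrature(values, lower, upper):
    """Adaptive-quadrature integral of the ECDF (independent of the exact
    step summation)."""
    from scipy.integrate import quad

    x = np.sort(np.asarray(values, dtype=float))

    def F(t):
        return np.searchsorted(x, t, side="right") / x.size

    pts = [p for p in np.unique(x) if lower < p < upper]
    val, _ = quad(F, lower, upper, points=pts or None,
                  limit=max(200, 10 * len(pts) + 10))
    return val
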