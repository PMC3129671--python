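"""Agglomerative haplotype analysis (AHA).

Compares two groups' homozygous segment-length distributions at each SNP via
a discrete two-sample Cramér–von Mises statistic: ω² is the sum of squared
ECDF differences evaluated at the unique values of the combined sample. ω²
depends only on ranks, so significance comes from a label-permutation test
(achieved significance level, ASL).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

log = logging.getLogger("hzkit")


@dataclass
class CvmResult:
    locus_id: str
    omega2: float
    asl: float
    n_permutations: int
    seed: int


def cvm_omega2(values_a, values_b):
    """Discrete two-sample CVM statistic:
    ω² = Σ_{x ∈ unique(A ∪ B)} (F_A(x) − F_B(x))² with right-continuous
    ECDFs. NaN entries (masked cells) are dropped."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    a = a[~np.isnan(a)]
    b = b[~np.isnan(b)]
    if a.size == 0 or b.size == 0:
        raise ValueError("empty sample after masking")
    xs = np.unique(np.concatenate([a, b]))
    fa = np.searchsorted(np.sort(a), xs, side="right") / a.size
    fb = np.searchsorted(np.sort(b), xs, side="right") / b.size
    return float(np.sum((fa - fb) ** 2))


def permutation_test(values_a, values_b, n_perm=1000, seed=0,
                     plus_one=False):
    """Label-permutation significance of ω².

    ASL = #{ω²_perm >= ω²_obs} / n_perm (the ``plus_one`` convention adds one
    to numerator and denominator for a strictly positive ASL). Seeded and
    reproducible."""
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    a = a[~np.isnan(a)]
    b = b[~np.isnan(b)]
    if a.size == 0 or b.size == 0:
        raise ValueError("group size 0")
    obs = cvm_omega2(a, b)
    n_a, n = a.size, a.size + b.size
    pool = np.concatenate([a, b])
    order = np.argsort(pool, kind="stable")
    sorted_pool = pool[order]
    # last index of each tie-group marks a unique pooled value
    uniq_last = np.concatenate([sorted_pool[1:] != sorted_pool[:-1], [True]])
    rng = np.random.default_rng(seed)
    # each row: random subset of size n_a assigned to group A
    u = rng.random((n_perm, n))
    sel = np.argsort(u, axis=1, kind="stable")[:, :n_a]
    take_a = np.zeros((n_perm, n), dtype=bool)
    np.put_along_axis(take_a, sel, True, axis=1)  # random size-n_a relabeling
    in_a_sorted = take_a[:, order]
    ca = np.cumsum(in_a_sorted, axis=1)
    idx = np.arange(1, n + 1)
    fa = ca / n_a
    fb = (idx[None, :] - ca) / (n - n_a)
    stats = np.sum((fa[:, uniq_last] - fb[:, uniq_last]) ** 2, axis=1)
    hits = int(np.sum(stats >= obs - 1e-12))
    if plus_one:
        asl = (hits + 1) / (n_perm + 1)
    else:
        asl = hits / n_perm
    return CvmResult("", obs, float(asl), n_perm, seed)


def scan_chromosome(islm_a, islm_b, n_perm=1000, seed=0,
                    screen_omega2=None, locus_ids=None):
    """Per-locus ω² (and ASL) track between two groups' column-aligned ISLMs.

    ``islm_a``/``islm_b`` are 2-D arrays (samples x loci) in matching units;
    NaN cells are masked. With ``screen_omega2`` set, permutations run only
    at loci whose ω² exceeds the screen (two-stage scan); otherwise every
    locus is permuted when ``n_perm > 0``."""
    a = np.asarray(islm_a, dtype=float)
    b = np.asarray(islm_b, dtype=float)
    if a.shape[1] != b.shape[1]:
        raise ValueError("matrices are not column-aligned")
    n_loci = a.shape[1]
    if locus_ids is None:
        locus_ids = [str(j) for j in range(n_loci)]
    results = []
    ss = np.random.SeedSequence(seed)
    locus_seeds = ss.generate_state(n_loci) % (2 ** 31)
    for j in range(n_loci):
        va, vb = a[:, j], b[:, j]
        omega2 = cvm_omega2(va, vb)
        asl = float("nan")
        if n_perm and (screen_omega2 is None or omega2 > screen_omega2):
            asl = permutation_test(va, vb, n_perm=n_perm,
                                   seed=int(locus_seeds[j])).asl
        results.append(CvmResult(locus_ids[j], omega2, asl, n_perm, seed))
    return results


def results_to_frame(results, positions=None):
    df = pd.DataFrame([{
        "locus": r.locus_id, "omega2": r.omega2, "asl": r.asl,
        "n_perm": r.n_permutations,
    } for r in results])
    if positions is not None:
        df.insert(1, "position_bp", np.asarray(positions))
    return df
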