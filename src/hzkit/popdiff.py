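"""Population differentiation.

Per-locus Fst/θ between two populations using the genotype-frequency
(observed heterozygosity) moment estimator with the n_c correction for
unequal sample sizes — the Weir & Cockerham (1984) two-population form whose
ratio-of-averages version Weir & Hill (2002) re-derives. θ is reported as
computed (negative estimates are not truncated).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotypes import HET, HOM_ALT, HOM_REF

log = logging.getLogger("hzkit")

#: empirical selection thresholds for differentiated peaks
THETA_THRESHOLD_AUTOSOME = 0.0360
THETA_THRESHOLD_CHRX = 0.0538


def _abc(counts_a, counts_b):
    """Weir-Cockerham variance components (a, b, c) for one biallelic locus
    and two populations, from genotype counts (homRef, het, homAlt)."""
    n1 = sum(counts_a)
    n2 = sum(counts_b)
    if n1 == 0 or n2 == 0:
        raise ValueError("both populations need >= 1 called genotype")
    r = 2
    p1 = (2 * counts_a[0] + counts_a[1]) / (2 * n1)   # reference-allele freq
    p2 = (2 * counts_b[0] + counts_b[1]) / (2 * n2)
    h1 = counts_a[1] / n1                              # observed het freq
    h2 = counts_b[1] / n2
    nbar = (n1 + n2) / r
    nc = (r * nbar - (n1 ** 2 + n2 ** 2) / (r * nbar)) / (r - 1)
    pbar = (n1 * p1 + n2 * p2) / (r * nbar)
    s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
    hbar = (n1 * h1 + n2 * h2) / (r * nbar)
    if nbar <= 1:
        raise ValueError("need more than one diploid individual per locus")
    a = (nbar / nc) * (s2 - (pbar * (1 - pbar) - s2 * (r - 1) / r
                             - hbar / 4) / (nbar - 1))
    b = (nbar / (nbar - 1)) * (pbar * (1 - pbar) - s2 * (r - 1) / r
                               - hbar * (2 * nbar - 1) / (4 * nbar))
    c = hbar / 2
    return a, b, c


def fst_theta(counts_a, counts_b):
    """θ̂ = a/(a+b+c) for one locus; NaN when the locus is monomorphic for the
    same allele in both populations (undefined, excluded from aggregation)."""
    a, b, c = _abc(counts_a, counts_b)
    denom = a + b + c
    if denom == 0:
        return float("nan")
    return float(a / denom)


def genotype_counts(gm, population, locus_index=None):
    rows = gm.sample_index(population)
    calls = gm.calls[rows] if locus_index is None else gm.calls[rows][:, locus_index]
    return ((calls == HOM_REF).sum(axis=0),
            (calls == HET).sum(axis=0),
            (calls == HOM_ALT).sum(axis=0))


def locus_theta_track(gm, pop_a, pop_b):
    """Per-locus θ between two populations over the whole panel, plus the
    per-locus (a, a+b+c) components for ratio-of-averages aggregation."""
    ca = np.stack(genotype_counts(gm, pop_a), axis=1)
    cb = np.stack(genotype_counts(gm, pop_b), axis=1)
    theta = np.full(gm.n_loci, np.nan)
    comp_a = np.zeros(gm.n_loci)
    comp_d = np.zeros(gm.n_loci)
    for j in range(gm.n_loci):
        if ca[j].sum() == 0 or cb[j].sum() == 0:
            continue
        a, b, c = _abc(tuple(ca[j]), tuple(cb[j]))
        comp_a[j], comp_d[j] = a, a + b + c
        if a + b + c != 0:
            theta[j] = a / (a + b + c)
    return theta, comp_a, comp_d


def aggregate_theta(comp_a, comp_d):
    """Multi-locus ratio-of-averages estimate Σa / Σ(a+b+c)."""
    d = comp_d.sum()
    return float(comp_a.sum() / d) if d else float("nan")


def peak_fst(peak, theta, track):
    """Mean θ over defined loci within the peak span (one comparison)."""
    lo, hi = peak.low_valley_idx, peak.high_valley_idx
    v = theta[lo:hi + 1]
    v = v[~np.isnan(v)]
    return float(v.mean()) if v.size else float("nan")


def annotate_peak_fst(peaks, gm, base_pop, other_pops):
    """Fill fst_mean per comparison population for every peak."""
    tracks = {}
    for pop in other_pops:
        tracks[pop], _, _ = locus_theta_track(gm, base_pop, pop)
    for p in peaks:
        if p.population != base_pop:
            continue
        for pop, theta in tracks.items():
            p.fst_mean[pop] = peak_fst(p, theta, None)
    return peaks


@dataclass
class DifferentiatedPeak:
    peak: object
    n_extreme_loci: int
    prop_extreme: float
    freq_a: float        # minor(A)-allele-oriented mean frequency, pop A
    freq_b: float
    freq_diff: float


def differentiated_peaks(peaks_a, peaks_b, tracks, gm, pop_a, pop_b,
                         rank_min=0.90,
                         theta_autosome=THETA_THRESHOLD_AUTOSOME,
                         theta_chrx=THETA_THRESHOLD_CHRX):
    """Extract peaks high-ranking in BOTH populations with peak-level θ above
    the chromosome-type threshold, and estimate per-population haplotype
    frequencies as the average minor-allele frequency across the peak's
    extreme-θ loci."""
    theta, _, _ = locus_theta_track(gm, pop_a, pop_b)
    chroms = gm.chromosomes

    def chrom_thr(chrom):
        return (theta_chrx
                if str(chrom).removeprefix("chr").upper() in {"X", "23"}
                else theta_autosome)

    out = []
    for p in list(peaks_a) + list(peaks_b):
        other = pop_b if p.population == pop_a else pop_a
        rank_here = p.rank_self
        rank_there = p.rank_other.get(other, float("nan"))
        if not (rank_here >= rank_min and rank_there >= rank_min):
            continue
        lo, hi = p.low_valley_idx, p.high_valley_idx
        v = theta[lo:hi + 1]
        defined = ~np.isnan(v)
        if not defined.any():
            log.info("differentiated_peaks: peak at %s:%d has no defined θ; "
                     "dropped", p.chromosome, p.apex_bp)
            continue
        thr = chrom_thr(p.chromosome)
        if float(v[defined].mean()) <= thr:
            continue
        extreme = np.where(defined & (v > thr))[0] + lo
        if extreme.size == 0:
            log.info("differentiated_peaks: no extreme-θ loci under peak at "
                     "%s:%d; dropped", p.chromosome, p.apex_bp)
            continue
        fa = _oriented_mean_freq(gm, pop_a, pop_b, extreme)
        out.append(DifferentiatedPeak(
            peak=p, n_extreme_loci=int(extreme.size),
            prop_extreme=float(extreme.size / (hi - lo + 1)),
            freq_a=fa[0], freq_b=fa[1], freq_diff=abs(fa[0] - fa[1])))
    return out


def _oriented_mean_freq(gm, pop_a, pop_b, loci):
    """Average allele frequency across loci, alleles oriented so the pooled
    minor allele is the counted (A) allele."""
    freqs = {pop: [] for pop in (pop_a, pop_b)}
    for j in loci:
        per = {}
        tot_alt = tot_n = 0
        for pop in (pop_a, pop_b):
            c = gm.calls[gm.sample_index(pop), j]
            n = int((c != 3).sum())
            alt = int(2 * (c == HOM_ALT).sum() + (c == HET).sum())
            per[pop] = (alt, 2 * n)
            tot_alt += alt
            tot_n += 2 * n
        minor_is_alt = tot_n and tot_alt / tot_n <= 0.5
        for pop in (pop_a, pop_b):
            alt, two_n = per[pop]
            if two_n == 0:
                continue
            f = alt / two_n
            freqs[pop].append(f if minor_is_alt else 1 - f)
    return (float(np.mean(freqs[pop_a])) if freqs[pop_a] else float("nan"),
            float(np.mean(freqs[pop_b])) if freqs[pop_b] else float("nan"))


def theta_to_frame(gm, theta):
    df = gm.loci_frame()[["id", "chromosome", "position_bp"]].copy()
    df["theta"] = theta
    return df
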