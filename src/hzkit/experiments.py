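"""Planted-truth recovery experiments on synthetic panels.

Each experiment simulates a panel with one planted feature, runs the same
QC -> detection -> annotation -> extent chain as the pipeline, and measures
how well the planted truth is recovered. These are the package's standard
validation studies; the test suite and the acceptance script both run them.

Study conditions (chosen once, documented in docs/methods.md):

* two populations of 50 diploid samples, ~1 kb SNP spacing, MAF > 0.05 QC;
* autozygous tract: 2000 loci planted in one sample on a 3500-locus panel;
* extended haplotype: 1200-locus core at carrier frequency f on a
  6000-locus panel (f in {0.3, 0.6} for the standard runs);
* fixed region: 500-locus population-restricted core on a 2500-locus panel
  simulated without genotyping error — the 0th-percentile extent is a
  minimum over samples, so its boundary is sensitive to any single
  miscalled genotype by construction, and sub-SNP boundary recovery is only
  meaningful on a clean assay.
"""

from __future__ import annotations

import numpy as np

from . import annotate, detect, extent, popdiff
from .aha import cvm_omega2, permutation_test, scan_chromosome
from .genotypes import filter_maf
from .peaks import detect_fixed_areas, find_peaks, peak_haplotype_params
from .synth import (
    PlantedAutozygousTract,
    PlantedExtendedHaplotype,
    PlantedFixedRegion,
    SimConfig,
    panel_arm_rates,
    simulate_panel,
    simulate_two_group_shift,
)

MAF_CUTOFF = 0.05
HPS_CUTOFF = 0.01


def _qc(gm, panel):
    """MAF filter plus phased-panel column alignment."""
    gm = filter_maf(gm, MAF_CUTOFF)
    if panel is not None:
        keep = np.array([int(lc.id.removeprefix("rs")) - 1 for lc in gm.loci])
        import dataclasses

        panel = dataclasses.replace(panel, haplotypes=panel.haplotypes[:, keep])
    return gm, panel


def _analyze(cfg, with_founder=True):
    """QC, detect, annotate, build masked ISLMs and per-population extent
    tracks — the standard chain shared by all recovery experiments."""
    gm, panel, truth = simulate_panel(cfg)
    arm = panel_arm_rates(cfg, gm)
    gm, panel = _qc(gm, panel)
    segset = detect.detect_segments(gm)
    annotate.annotate_hps(segset, gm)
    islm_bp = extent.build_islm(segset, gm, "bp", max_hps_ex=HPS_CUTOFF)
    annotate.annotate_mad(segset, islm_bp)
    if with_founder:
        annotate.annotate_founder_freq(
            segset, gm, panel,
            predicate=lambda s: (s.length_bp >= 300_000
                                 or s.mad_score > annotate.MAD_AUTOZYGOUS_THRESHOLD))
    islm_cm = extent.build_islm(segset, gm, "cM", arm, max_hps_ex=HPS_CUTOFF)
    islm_cm_m = extent.mask_islm_autozygous(islm_cm, segset)
    return gm, panel, truth, segset, islm_cm_m


def tract_recovery(seed):
    """Plant an autozygous tract; report the best single-segment coverage of
    the tract, its MAD score and founder frequency, and the count of
    background segments that would also be called autozygous."""
    tract = (500, 2499)
    cfg = SimConfig(n_loci=3500, seed=seed,
                    planted=[PlantedAutozygousTract("POPA_000", *tract)])
    gm, panel, truth, segset, _ = _analyze(cfg)
    lo_bp, hi_bp = truth.tract_spans_bp["POPA_000"]
    span = hi_bp - lo_bp + 1
    best_cov, best = 0.0, None
    for s in segset.for_sample_chrom("POPA_000", cfg.chromosome):
        ov = (min(s.end_bp, hi_bp) - max(s.start_bp, lo_bp) + 1) / span
        if ov > best_cov:
            best_cov, best = ov, s
    n_background_calls = sum(
        1 for s in annotate.autozygous_calls(segset) if s is not best)
    return {
        "coverage": best_cov,
        "mad_score": best.mad_score if best else float("nan"),
        "founder_hap_freq": best.founder_hap_freq if best else float("nan"),
        "n_segments": len(segset.segments),
        "n_background_calls": n_background_calls,
    }


def extended_haplotype_recovery(seed, frequency):
    """Plant an extended haplotype at the given carrier frequency; report
    the outlier peaks covering the planted midpoint and the recovered
    haplotype frequency (Freq_hap-max of the midpoint peak)."""
    core = (2500, 3699)
    cfg = SimConfig(n_loci=6000, seed=seed,
                    planted=[PlantedExtendedHaplotype(
                        *core, {"POPA": frequency, "POPB": 0.05})])
    gm, panel, truth, segset, islm_cm_m = _analyze(cfg)
    track = extent.ext_auc_rank(extent.ext_auc(islm_cm_m, "POPA"))
    pemat = extent.pe_mat(islm_cm_m, "POPA")
    peaks = find_peaks(track)
    lo_bp, hi_bp = truth.ext_spans_bp[0]
    mid_bp = 0.5 * (lo_bp + hi_bp)
    hits = [p for p in peaks
            if p.outlier and p.low_valley_bp <= mid_bp <= p.high_valley_bp]
    freq = float("nan")
    if hits:
        peak_haplotype_params(hits[0], pemat, segset.segments)
        freq = hits[0].freq_hap_max
    return {
        "n_hit_peaks": len(hits),
        "freq_hap_max": freq,
        "target_frequency": frequency,
        "realized_frequency": truth.realized_hap_freq[0]["POPA"],
    }


def fixed_region_recovery(seed):
    """Plant a population-restricted fixed region on a clean panel; report
    the boundary error (in post-QC SNPs) of the best-matching RCL_0 run.

    The core is kept short (80 loci): the 1% heterozygote-absorption budget
    grows with segment length, so long cores legitimately accrete a few SNPs
    of absorbed shoulder coverage, while a short core cannot — boundary
    recovery at SNP resolution is a property of short fixed areas."""
    core = (1000, 1079)
    cfg = SimConfig(n_loci=2500, seed=seed, het_error_rate=0.0,
                    missing_rate=0.0,
                    planted=[PlantedFixedRegion(*core, population="POPA")])
    gm, panel, truth, segset, islm_cm_m = _analyze(cfg, with_founder=False)
    pemat = extent.pe_mat(islm_cm_m, "POPA")
    runs, candidates = detect_fixed_areas([pemat])
    lo_bp, hi_bp = truth.fixed_spans_bp[0]
    pos = gm.positions
    a = int(np.searchsorted(pos, lo_bp, side="left"))
    b = int(np.searchsorted(pos, hi_bp, side="right")) - 1
    berr = None
    for r in runs:
        if r.end_idx >= a and r.start_idx <= b:
            e = max(abs(r.start_idx - a), abs(r.end_idx - b))
            berr = e if berr is None else min(berr, e)
    return {
        "boundary_error_snps": float("inf") if berr is None else berr,
        "n_runs": len(runs),
        "n_candidates": len(candidates),
    }


# ---------------------------------------------------------------------------
# Population differentiation
# ---------------------------------------------------------------------------

def island_model_theta(seed, fst=0.1, n_loci=5000, n_per_deme=50):
    """Balding-Nichols two-deme island model at the given FST; returns the
    multi-locus ratio-of-averages θ estimate (expected ≈ fst)."""
    rng = np.random.default_rng(seed)
    comp_a = comp_d = 0.0
    for _ in range(n_loci):
        p = rng.uniform(0.1, 0.9)
        al = p * (1 - fst) / fst
        be = (1 - p) * (1 - fst) / fst
        counts = []
        for _ in range(2):
            pi = rng.beta(al, be)
            g = rng.binomial(2, pi, size=n_per_deme)
            counts.append((int(np.sum(g == 0)), int(np.sum(g == 1)),
                           int(np.sum(g == 2))))
        a, b, c = popdiff._abc(counts[0], counts[1])
        comp_a += a
        comp_d += a + b + c
    return comp_a / comp_d


def opposite_fixation_theta(n=50):
    return popdiff.fst_theta((n, 0, 0), (0, 0, n))


# ---------------------------------------------------------------------------
# AHA calibration
# ---------------------------------------------------------------------------

def aha_null_type1(seed, n_loci=1000, n_per_group=50, n_perm=999,
                   alpha=0.05):
    """Type-I error of the permutation CVM test at level alpha under the
    null (both groups drawn from the same segment-length distribution)."""
    rng = np.random.default_rng(seed)
    rejections = 0
    for j in range(n_loci):
        pool = rng.exponential(100.0, size=2 * n_per_group)
        pool[rng.random(2 * n_per_group) < 0.5] = 0.0  # uncovered samples
        res = permutation_test(pool[:n_per_group], pool[n_per_group:],
                               n_perm=n_perm,
                               seed=int(rng.integers(2 ** 31)))
        rejections += res.asl <= alpha
    return rejections / n_loci


def aha_shift_localization(seed, interval=(900, 1299), shift=4.0,
                           margin_loci=100):
    """Two-group panel with a planted segment-length shift; True when the
    genome-wide ω² argmax falls inside the planted window.

    The window carries a margin (default 100 loci): the carriers' homozygous
    segments extend past the planted core by their decay tails, so the
    shifted length distribution — and hence the ω² signal — covers slightly
    more than the core itself."""
    cfg = SimConfig(n_loci=2000, populations={"POPA": 25, "POPB": 25},
                    seed=seed)
    gm, panel, truth = simulate_two_group_shift(cfg, interval, shift=shift)
    lo_bp = gm.positions[max(0, interval[0] - margin_loci)]
    hi_bp = gm.positions[min(cfg.n_loci - 1, interval[1] + margin_loci)]
    gm = filter_maf(gm, MAF_CUTOFF)
    segset = detect.detect_segments(gm)
    annotate.annotate_hps(segset, gm)
    islm = extent.build_islm(segset, gm, "bp", max_hps_ex=HPS_CUTOFF)
    ra = islm.rows_for_population("POPA")
    rb = islm.rows_for_population("POPB")
    res = scan_chromosome(islm.values[ra], islm.values[rb], n_perm=0)
    omega = np.array([r.omega2 for r in res])
    arg = int(np.argmax(omega))
    pos = gm.positions[arg]
    return {"argmax_in_window": bool(lo_bp <= pos <= hi_bp),
            "argmax_bp": int(pos), "window_bp": (int(lo_bp), int(hi_bp)),
            "max_omega2": float(omega[arg])}
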