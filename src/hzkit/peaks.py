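"""Peak analysis of the ext_AUC track.

Spline smoothing, derivative-sign peak/valley delineation, iterative peak
merging, boxplot outlier extraction and region merging, per-peak haplotype
parameters from the percentile-extent matrix, fixed-area (RCL_0) detection,
and recombination-rate annotation against a genetic map.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import LSQUnivariateSpline

log = logging.getLogger("hzkit")

#: spline knot count as a fraction of the loci being smoothed
KNOT_FRACTION = 0.03
MIN_SMOOTH_LOCI = 34

#: reference bin grid (bp) for recombination-rate percentile matching
RATE_BIN_GRID = ([5_000] + list(range(10_000, 100_001, 10_000))
                 + list(range(200_000, 500_001, 100_000))
                 + [750_000, 1_000_000, 5_000_000, 10_000_000])


@dataclass
class Peak:
    population: str
    chromosome: str
    apex_idx: int              # global locus index into the track
    low_valley_idx: int
    high_valley_idx: int
    apex_bp: int
    low_valley_bp: int
    high_valley_bp: int
    height: float
    low_valley_val: float
    high_valley_val: float
    snp_count: int
    outlier: bool = False
    extent_min: float = float("nan")
    p_max: float = float("nan")
    freq_hap_exp: float = float("nan")
    freq_hap_max: float = float("nan")
    rank_self: float = float("nan")
    rank_other: dict = field(default_factory=dict)
    fst_mean: dict = field(default_factory=dict)
    recomb_rate: float = float("nan")
    recomb_rate_percentile: float = float("nan")
    width_cm: float = float("nan")
    gene_hits: list = field(default_factory=list)

    @property
    def width_bp(self):
        return self.high_valley_bp - self.low_valley_bp + 1


@dataclass
class PeakRegion:
    members: list
    chromosome: str
    population: str
    start_bp: int
    end_bp: int
    max_height: float
    min_extent_min: float
    max_freq_hap_max: float


@dataclass
class FixedArea:
    chromosome: str
    population: str
    start_idx: int
    end_idx: int
    start_bp: int
    end_bp: int
    snp_count: int
    extent: float        # max 0th-percentile value within the run (track units)
    extent_bp: int = 0


# ---------------------------------------------------------------------------
# Smoothing and peak delineation
# ---------------------------------------------------------------------------

def smooth_track(values, positions):
    """Cubic least-squares spline with knot count = ceil(0.03 * n_loci)
    (interior knots at position quantiles). Returns (fitted, derivative) on
    the locus grid."""
    values = np.asarray(values, dtype=float)
    x = np.asarray(positions, dtype=float)
    n = values.size
    if n < MIN_SMOOTH_LOCI:
        raise ValueError(
            f"need >= {MIN_SMOOTH_LOCI} loci to smooth (got {n}); merge this "
            "window with a neighbor")
    m = math.ceil(KNOT_FRACTION * n)
    q = np.linspace(0, 1, m + 2)[1:-1]
    knots = np.unique(np.quantile(x, q))
    knots = knots[(knots > x[0]) & (knots < x[-1])]
    spl = LSQUnivariateSpline(x, values, knots, k=3)
    return spl(x), spl.derivative()(x)


def detect_peaks(smoothed, derivative, positions, chromosome="chr",
                 population="POP", index_offset=0):
    """Delineate peaks at +/- sign changes of the first derivative.

    Apexes sit where the derivative crosses from positive to negative,
    valleys where it crosses back; chromosome ends count as valleys. Returns
    the complete (unmerged) peak list ordered by position."""
    s = np.asarray(smoothed, dtype=float)
    d = np.asarray(derivative, dtype=float)
    n = s.size
    sgn = np.sign(d)
    for i in range(1, n):      # carry sign through flat stretches
        if sgn[i] == 0:
            sgn[i] = sgn[i - 1]
    valleys = [0]
    for i in range(n - 1):
        if sgn[i] < 0 and sgn[i + 1] > 0:
            valleys.append(i + 1 if s[i + 1] <= s[i] else i)
    valleys.append(n - 1)
    valleys = sorted(set(valleys))
    peaks = []
    for v1, v2 in zip(valleys[:-1], valleys[1:]):
        if v2 - v1 < 2:
            continue
        inner = slice(v1, v2 + 1)
        apex = v1 + int(np.argmax(s[inner]))
        if apex in (v1, v2):
            continue  # monotone between valleys: no peak
        peaks.append(Peak(
            population=population, chromosome=str(chromosome),
            apex_idx=apex + index_offset,
            low_valley_idx=v1 + index_offset,
            high_valley_idx=v2 + index_offset,
            apex_bp=int(positions[apex]),
            low_valley_bp=int(positions[v1]),
            high_valley_bp=int(positions[v2]),
            height=float(s[apex]),
            low_valley_val=float(s[v1]),
            high_valley_val=float(s[v2]),
            snp_count=v2 - v1 + 1,
        ))
    return peaks


def merge_peaks(peaks, tolerance=0.10):
    """Iteratively merge adjacent peaks whose heights and intervening valley
    differ by less than ``tolerance`` (10%).

    Two adjacent peaks merge when |h1-h2|/max(h1,h2) < tolerance and
    (max(h1,h2) - v)/max(h1,h2) < tolerance, v being the intervening valley.
    The merged peak keeps the taller apex and the outer valleys. Repeats to a
    fixpoint."""
    peaks = sorted(peaks, key=lambda p: p.apex_idx)
    changed = True
    while changed:
        changed = False
        out = []
        i = 0
        while i < len(peaks):
            cur = peaks[i]
            while i + 1 < len(peaks):
                nxt = peaks[i + 1]
                h = max(cur.height, nxt.height)
                v = min(cur.high_valley_val, nxt.low_valley_val)
                if (h > 0 and abs(cur.height - nxt.height) / h < tolerance
                        and (h - v) / h < tolerance):
                    cur = _merged_pair(cur, nxt)
                    i += 1
                    changed = True
                else:
                    break
            out.append(cur)
            i += 1
        peaks = out
    return peaks


def _merged_pair(a, b):
    tall = a if a.height >= b.height else b
    return Peak(
        population=a.population, chromosome=a.chromosome,
        apex_idx=tall.apex_idx,
        low_valley_idx=a.low_valley_idx, high_valley_idx=b.high_valley_idx,
        apex_bp=tall.apex_bp,
        low_valley_bp=a.low_valley_bp, high_valley_bp=b.high_valley_bp,
        height=tall.height,
        low_valley_val=a.low_valley_val, high_valley_val=b.high_valley_val,
        snp_count=a.snp_count + b.snp_count - 1,
    )


def flag_outlier_peaks(peaks):
    """Flag peaks whose height exceeds Q3 + 1.5*IQR of their
    chromosome-population's merged-peak heights (needs >= 4 peaks)."""
    groups = {}
    for p in peaks:
        groups.setdefault((p.chromosome, p.population), []).append(p)
    for key, grp in groups.items():
        if len(grp) < 4:
            log.warning("flag_outlier_peaks: only %d peaks on %s/%s; no "
                        "outliers called", len(grp), *key)
            continue
        h = np.array([p.height for p in grp])
        q1, q3 = np.quantile(h, [0.25, 0.75])
        thr = q3 + 1.5 * (q3 - q1)
        for p in grp:
            p.outlier = p.height > thr
    return peaks


def merge_outlier_regions(outlier_peaks):
    """Merge directly adjoining outlier peaks lacking clear separation
    (intervening valley > 0.5 * min of the adjoining peaks' heights) into
    peak regions; iterates to a fixpoint."""
    peaks = sorted(outlier_peaks, key=lambda p: (p.chromosome, p.apex_idx))
    regions = []
    cur = None
    for p in peaks:
        if cur is not None and _adjoins(cur[-1], p):
            v = min(cur[-1].high_valley_val, p.low_valley_val)
            if v > 0.5 * min(cur[-1].height, p.height):
                cur.append(p)
                continue
        if cur:
            regions.append(_make_region(cur))
        cur = [p]
    if cur:
        regions.append(_make_region(cur))
    return regions


def _adjoins(a, b):
    return (a.chromosome == b.chromosome
            and a.population == b.population
            and b.low_valley_idx <= a.high_valley_idx)


def _make_region(members):
    def _nanmax(vals, default=float("nan")):
        vals = [v for v in vals if not np.isnan(v)]
        return max(vals) if vals else default

    return PeakRegion(
        members=list(members),
        chromosome=members[0].chromosome,
        population=members[0].population,
        start_bp=members[0].low_valley_bp,
        end_bp=members[-1].high_valley_bp,
        max_height=max(p.height for p in members),
        min_extent_min=min((p.extent_min for p in members), default=float("nan")),
        max_freq_hap_max=_nanmax([p.freq_hap_max for p in members]),
    )


# ---------------------------------------------------------------------------
# Per-peak haplotype parameters
# ---------------------------------------------------------------------------

def peak_haplotype_params(peak, pemat, segments=None):
    """Optimal (Extent_min, p_max) over the peak's PE_mat cells.

    Every (locus, percentile) pair inside the peak defines Extent (the PE_mat
    value) and Pr(X > Extent) = 1 - percentile/100; the pair maximizing
    Extent * Pr is chosen (ties toward larger Extent). Freq_hap-exp is
    sqrt(p_max); Freq_hap-max is the largest founder-haplotype frequency
    among supplied segments intersecting the peak with genetic length above
    Extent_min (0 when none qualifies)."""
    block = pemat.values[peak.low_valley_idx:peak.high_valley_idx + 1]
    pr = 1.0 - pemat.levels
    prod = block * pr[None, :]
    if np.all(np.isnan(prod)):
        return peak
    best = np.nanmax(prod)
    cand = np.argwhere(np.isclose(prod, best, rtol=0, atol=0) | (prod == best))
    extents = block[cand[:, 0], cand[:, 1]]
    k = int(np.argmax(extents))
    li, qi = cand[k]
    peak.extent_min = float(block[li, qi])
    peak.p_max = float(pr[qi])
    peak.freq_hap_exp = math.sqrt(peak.p_max)
    if segments is not None:
        best_f = 0.0
        # Extent_min comes from a 101-level interpolated quantile grid, so it
        # can land marginally above the observed lengths that define it; a
        # tolerance of the grid's interpolation resolution (1%) keeps those
        # segments qualified
        cutoff = peak.extent_min * (1 - 0.01)
        for s in segments:
            if (s.chromosome == peak.chromosome
                    and s.start_bp <= peak.high_valley_bp
                    and s.end_bp >= peak.low_valley_bp
                    and s.length_cm >= cutoff
                    and not np.isnan(s.founder_hap_freq)):
                best_f = max(best_f, s.founder_hap_freq)
        peak.freq_hap_max = best_f
    return peak


def cross_population_rank(peak, tracks):
    """Maximum per-locus ext_AUC rank within the peak span, per population.

    ``tracks`` maps population -> ExtAucTrack with ranks filled. The peak's
    own population fills ``rank_self``; the rest go to ``rank_other``."""
    lo, hi = peak.low_valley_idx, peak.high_valley_idx
    for pop, track in tracks.items():
        r = float(np.max(track.rank[lo:hi + 1]))
        if pop == peak.population:
            peak.rank_self = r
        else:
            peak.rank_other[pop] = r
    return peak


# ---------------------------------------------------------------------------
# Fixed areas (RCL_0)
# ---------------------------------------------------------------------------

def detect_fixed_areas(pemats, pooled_quartiles=True):
    """Runs of contiguous loci with non-zero 0th-percentile extent (RCL_0) —
    every individual of the population carries an intersecting segment.

    Returns (all_runs, candidates); candidates have SNP count and extent both
    above the first quartile, computed across all populations' runs when
    ``pooled_quartiles`` (per population otherwise)."""
    if not isinstance(pemats, (list, tuple)):
        pemats = [pemats]
    runs = []
    for pm in pemats:
        p0 = pm.values[:, 0]
        for chrom in dict.fromkeys(pm.chromosomes):
            idx = pm.chrom_index(chrom)
            nz = p0[idx] > 0
            start = None
            for k in range(len(idx) + 1):
                on = k < len(idx) and nz[k]
                if on and start is None:
                    start = k
                elif not on and start is not None:
                    gi, gj = int(idx[start]), int(idx[k - 1])
                    runs.append(FixedArea(
                        chromosome=str(chrom), population=pm.population,
                        start_idx=gi, end_idx=gj,
                        start_bp=int(pm.positions[gi]),
                        end_bp=int(pm.positions[gj]),
                        snp_count=gj - gi + 1,
                        extent=float(np.max(p0[idx][start:k])),
                        extent_bp=int(pm.positions[gj] - pm.positions[gi] + 1),
                    ))
                    start = None
    if not runs:
        return [], []
    candidates = []
    if pooled_quartiles:
        q1_snp = np.quantile([r.snp_count for r in runs], 0.25)
        q1_ext = np.quantile([r.extent for r in runs], 0.25)
        candidates = [r for r in runs
                      if r.snp_count > q1_snp and r.extent > q1_ext]
    else:
        for pop in {r.population for r in runs}:
            grp = [r for r in runs if r.population == pop]
            q1_snp = np.quantile([r.snp_count for r in grp], 0.25)
            q1_ext = np.quantile([r.extent for r in grp], 0.25)
            candidates += [r for r in grp
                           if r.snp_count > q1_snp and r.extent > q1_ext]
    return runs, candidates


# ---------------------------------------------------------------------------
# Recombination-rate annotation
# ---------------------------------------------------------------------------

@dataclass
class GeneticMap:
    """Monotone position -> cM table for one chromosome."""

    positions: np.ndarray
    cm: np.ndarray

    @classmethod
    def read_tsv(cls, path):
        df = pd.read_csv(path, sep="\t")
        return cls(df.iloc[:, 0].to_numpy(float), df.iloc[:, 1].to_numpy(float))

    def interp(self, bp):
        bp = np.asarray(bp, dtype=float)
        if np.any(bp < self.positions[0]) or np.any(bp > self.positions[-1]):
            raise ValueError("position outside genetic map coverage")
        return np.interp(bp, self.positions, self.cm)

    def rate(self, start_bp, end_bp):
        """Average recombination rate (cM/Mb) across [start_bp, end_bp]."""
        if end_bp <= start_bp:
            raise ValueError("empty window")
        dcm = float(np.diff(self.interp([start_bp, end_bp]))[0])
        return dcm / ((end_bp - start_bp) / 1e6)

    def bin_rates(self, bin_bp):
        """Rates over non-overlapping tiles of width ``bin_bp``."""
        lo, hi = self.positions[0], self.positions[-1]
        edges = np.arange(lo, hi, bin_bp)
        if edges.size < 2:
            edges = np.array([lo, hi])
        rates = []
        for a in edges[:-1]:
            b = min(a + bin_bp, hi)
            if b > a:
                rates.append(self.rate(a, b))
        return np.asarray(rates)


def nearest_bin(width_bp, grid=RATE_BIN_GRID):
    g = np.asarray(grid, dtype=float)
    return int(g[np.argmin(np.abs(g - width_bp))])


def peak_recombination(peak, track, genetic_map, bin_reference=None,
                       window_fraction=0.5):
    """Recombination rate and percentile across the peak's central window.

    The window centre is the midpoint of the loci whose ext_AUC lies in the
    peak's upper 25%; the window half-width is
    ``window_fraction/2 * peak width``. The rate is dcM/dMb across the window
    by linear interpolation of the map; the percentile is the rate's ECDF
    position among reference rates at the nearest bin width (precomputed
    ``bin_reference`` mapping bin width -> rates array, or derived by tiling
    the map)."""
    lo, hi = peak.low_valley_idx, peak.high_valley_idx
    v = track.ext_auc[lo:hi + 1]
    pos = track.positions[lo:hi + 1]
    thr = np.quantile(v, 0.75)
    top = pos[v >= thr]
    centre = 0.5 * (top.min() + top.max())
    half = 0.5 * window_fraction * peak.width_bp
    w_lo, w_hi = centre - half, centre + half
    rate = genetic_map.rate(w_lo, w_hi)
    width = w_hi - w_lo
    b = nearest_bin(width)
    if bin_reference is not None and b in bin_reference:
        ref = np.asarray(bin_reference[b], dtype=float)
    else:
        ref = genetic_map.bin_rates(b)
    peak.recomb_rate = rate
    peak.recomb_rate_percentile = float((ref <= rate).mean()) if ref.size else float("nan")
    return peak


# ---------------------------------------------------------------------------
# Driver + export
# ---------------------------------------------------------------------------

def find_peaks(track, merge_tolerance=0.10):
    """Smooth, delineate, and merge peaks for every chromosome of an
    ext_AUC track; then flag outliers. Returns the merged peak list."""
    merged = []
    for chrom in dict.fromkeys(track.chromosomes):
        idx = track.chrom_index(chrom)
        if idx.size < MIN_SMOOTH_LOCI:
            log.warning("find_peaks: %s has %d loci (< %d); skipped",
                        chrom, idx.size, MIN_SMOOTH_LOCI)
            continue
        sm, dv = smooth_track(track.ext_auc[idx], track.positions[idx])
        pks = detect_peaks(sm, dv, track.positions[idx], chromosome=chrom,
                           population=track.population,
                           index_offset=int(idx[0]))
        merged += merge_peaks(pks, merge_tolerance)
    return flag_outlier_peaks(merged)


def peaks_to_frame(peaks):
    rows = [{
        "population": p.population, "chromosome": p.chromosome,
        "position": p.apex_bp, "low_valley": p.low_valley_bp,
        "high_valley": p.high_valley_bp, "pk_ht": p.height,
        "snp_ct": p.snp_count, "w_bp": p.width_bp, "w_cm": p.width_cm,
        "outlier": p.outlier, "extent_min": p.extent_min, "p_max": p.p_max,
        "freq_hap_exp": p.freq_hap_exp, "freq_hap_max": p.freq_hap_max,
        "rank_self": p.rank_self,
        "recomb_rate": p.recomb_rate,
        "recomb_rate_percentile": p.recomb_rate_percentile,
        **{f"rank_{k}": v for k, v in sorted(p.rank_other.items())},
        **{f"fst_{k}": v for k, v in sorted(p.fst_mean.items())},
    } for p in peaks]
    return pd.DataFrame(rows)
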