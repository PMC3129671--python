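"""Segment-level statistics.

HPS (homozygosity probability score), MISL (minimum inclusive segment
length), the robust MAD autozygosity score, founder-haplotype frequency from
a phased panel, chromosome coverage curves, and generic interval
intersection.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotypes import HET, HOM_ALT, HOM_REF, MISSING

log = logging.getLogger("hzkit")

#: scale factor making the median absolute deviation a consistent estimator
#: of the standard deviation under normality
MAD_CONSISTENCY = 1.4826

MAD_AUTOZYGOUS_THRESHOLD = 10.0


@dataclass
class MislTable:
    """Per-chromosome minimum inclusive segment length: the minimum over
    individuals of each individual's longest segment. Using MISL as a length
    threshold guarantees every individual contributes at least one segment."""

    misl_chr: dict
    misl_gw: float
    misl_subset: dict = field(default_factory=dict)

    def to_frame(self):
        df = pd.DataFrame(sorted(self.misl_chr.items()),
                          columns=["chromosome", "misl_bp"])
        return df


@dataclass
class PhasedHaplotypePanel:
    """2*n_samples x n_loci alleles in {0,1} (-1 = missing); consecutive row
    pairs (2i, 2i+1) belong to diploid sample i."""

    haplotypes: np.ndarray
    sample_ids: list
    populations: list = None

    def __post_init__(self):
        self.haplotypes = np.asarray(self.haplotypes, dtype=np.int8)
        if self.haplotypes.shape[0] % 2:
            raise ValueError("haplotype row count must be even")
        if self.haplotypes.shape[0] != 2 * len(self.sample_ids):
            raise ValueError("need two haplotype rows per sample")

    def rows_for_population(self, population):
        if population is None or self.populations is None:
            return np.arange(self.haplotypes.shape[0])
        keep = [i for i, p in enumerate(self.populations) if p == population]
        return np.array([r for i in keep for r in (2 * i, 2 * i + 1)], dtype=int)


# ---------------------------------------------------------------------------
# HPS
# ---------------------------------------------------------------------------

def hps(segment, freq_hom, chrom_offset=0):
    """Homozygosity probability score: the product of the per-locus observed
    homozygosity frequencies across the segment's loci.

    Computed in log space (segments routinely span thousands of loci).
    ``freq_hom`` is the per-locus vector for the segment's chromosome —
    pooled across populations for HPS_ex, within-population for HPS_in.
    ``chrom_offset`` maps the segment's chromosome-local indices into
    ``freq_hom`` when a genome-wide vector is passed.
    """
    lo = segment.start_idx + chrom_offset
    hi = segment.end_idx + chrom_offset
    f = np.asarray(freq_hom[lo:hi + 1], dtype=float)
    if np.isnan(f).any():
        j = lo + int(np.where(np.isnan(f))[0][0])
        raise ValueError(f"Freq_HOM missing for locus index {j}")
    if (f < 0).any() or (f > 1).any():
        raise ValueError("Freq_HOM outside [0,1]")
    if (f == 0).any():
        return 0.0
    return float(np.exp(np.log(f).sum()))


def annotate_hps(segset, gm):
    """Fill hps_ex (pooled Freq_HOM) and hps_in (own population) in place."""
    from .genotypes import compute_freq_hom

    pooled = compute_freq_hom(gm, "pooled")
    per_pop = compute_freq_hom(gm, "per_population")
    pop_of = {s.id: s.population for s in gm.samples}
    chroms = gm.chromosomes
    offsets = {c: int(np.where(chroms == c)[0][0]) for c in dict.fromkeys(chroms)}
    for seg in segset.segments:
        off = offsets[seg.chromosome]
        seg.hps_ex = hps(seg, pooled, off)
        seg.hps_in = hps(seg, per_pop[pop_of[seg.sample_id]], off)
    return segset


# ---------------------------------------------------------------------------
# MISL
# ---------------------------------------------------------------------------

def compute_misl(segset, subsets=None):
    """Per-chromosome MISL = min over samples of (longest segment length);
    genome-wide MISL = min over chromosomes; optional named chromosome
    subsets take the min of their members' MISL_chr."""
    best = {}  # (chrom, sample) -> max length
    chrom_samples = {}
    all_samples = set()
    for s in segset.segments:
        key = (s.chromosome, s.sample_id)
        best[key] = max(best.get(key, 0), s.length_bp)
        chrom_samples.setdefault(s.chromosome, set()).add(s.sample_id)
        all_samples.add(s.sample_id)
    misl_chr = {}
    for chrom, present in chrom_samples.items():
        absent = all_samples - present
        if absent:
            log.warning("compute_misl: %d samples without segments on %s skipped",
                        len(absent), chrom)
        misl_chr[chrom] = min(best[(chrom, sid)] for sid in present)
    if not misl_chr:
        raise ValueError("no segments: MISL undefined")
    misl_gw = min(misl_chr.values())
    misl_subset = {}
    for name, chroms in (subsets or {}).items():
        members = [misl_chr[c] for c in chroms if c in misl_chr]
        if members:
            misl_subset[name] = min(members)
    return MislTable(misl_chr, misl_gw, misl_subset)


# ---------------------------------------------------------------------------
# MAD autozygosity score
# ---------------------------------------------------------------------------

def _adjacent_group_ids(block):
    """Group index per column, collapsing identical adjacent columns
    (ISLVs only change where some sample's segment starts or ends).
    NaNs compare equal for grouping purposes."""
    b = np.nan_to_num(block, nan=-1.0)
    change = np.any(b[:, 1:] != b[:, :-1], axis=0)
    return np.concatenate([[0], np.cumsum(change)])


def _column_med_mad(block, rep_cols):
    """Median and raw MAD of the non-zero entries of each representative
    column; NaN medians mark all-zero vectors (skipped)."""
    m = np.full(rep_cols.size, np.nan)
    d = np.full(rep_cols.size, np.nan)
    for k, j in enumerate(rep_cols):
        v = block[:, j]
        nz = v[~np.isnan(v)]
        nz = nz[nz > 0]
        if nz.size:
            m[k] = np.median(nz)
            d[k] = np.median(np.abs(nz - m[k]))
    return m, d


def _scores_from_moments(length, m, d):
    with np.errstate(divide="ignore", invalid="ignore"):
        s = (length - m) / (MAD_CONSISTENCY * d)
    zero_d = d == 0
    s[zero_d & (length > m)] = np.inf
    s[zero_d & (length <= m)] = 0.0
    return s


def mad_score(segment, islm_values, sample_rows=None):
    """Robust z-score of a segment's length against the local length
    distribution.

    ``islm_values`` is the samples x loci intersecting-segment-length matrix
    (same units as the segment length, bp here). The ISLVs under the segment
    are extracted, duplicate (identical) adjacent columns collapse to one
    representative, and for each representative the score is
    ``(L - median(ISLV_nz)) / (MAD_CONSISTENCY * mad(ISLV_nz))`` over the
    non-zero entries (zero raw MAD gives +inf above the median, 0 below;
    all-zero vectors are skipped). The segment score is the median of the
    per-vector scores.
    """
    cols = np.asarray(islm_values[:, segment.start_idx:segment.end_idx + 1],
                      dtype=float)
    if sample_rows is not None:
        cols = cols[sample_rows]
    gid = _adjacent_group_ids(cols)
    rep_cols = np.concatenate([[0], np.where(np.diff(gid))[0] + 1])
    m, d = _column_med_mad(cols, rep_cols)
    ok = ~np.isnan(m)
    if not ok.any():
        return float("nan")
    scores = _scores_from_moments(float(segment.length_bp), m[ok], d[ok])
    return float(np.median(scores))


def annotate_mad(segset, islm):
    """Fill mad_score for every segment and flag putative autozygosity.

    Scores are computed within each chromosome against that chromosome's
    ISLM block. Column medians/MADs are shared across segments (they depend
    only on the column), so each chromosome's moments are computed once.
    Segments with score > 10 get the ``putative_autozygous`` flag (used for
    masking; the autozygosity call set additionally requires
    founder_hap_freq == 0).
    """
    by_chrom = {}
    for seg in segset.segments:
        by_chrom.setdefault(seg.chromosome, []).append(seg)
    for chrom, segs in by_chrom.items():
        block = islm.chrom_block(chrom)
        gid = _adjacent_group_ids(block)
        rep_cols = np.concatenate([[0], np.where(np.diff(gid))[0] + 1])
        m_all, d_all = _column_med_mad(block, rep_cols)
        for seg in segs:
            g0, g1 = gid[seg.start_idx], gid[seg.end_idx]
            m = m_all[g0:g1 + 1]
            d = d_all[g0:g1 + 1]
            ok = ~np.isnan(m)
            if not ok.any():
                seg.mad_score = float("nan")
                continue
            scores = _scores_from_moments(float(seg.length_bp), m[ok], d[ok])
            seg.mad_score = float(np.median(scores))
            if seg.mad_score > MAD_AUTOZYGOUS_THRESHOLD:
                seg.flags.add("putative_autozygous")
    return segset


# ---------------------------------------------------------------------------
# Founder haplotype frequency
# ---------------------------------------------------------------------------

def founder_hap_freq(segment, panel, calls=None, locus_offset=0,
                     population=None, exclude_sample_index=None):
    """Frequency of the segment's founder haplotype in a phased panel.

    The founder haplotype is the homozygous allele string over the segment's
    loci (absorbed heterozygote and missing loci are excluded from the
    comparison); it is compared against the *other* haplotypes — pass the
    carrier's panel index as ``exclude_sample_index`` to drop its own two
    rows. A panel haplotype counts as a match when its mismatch count is at
    most ``max(0.01 * L, 1)`` with ``L`` the number of compared loci; missing
    panel alleles are excluded from the comparison at that haplotype.
    """
    lo = segment.start_idx + locus_offset
    hi = segment.end_idx + locus_offset
    if hi >= panel.haplotypes.shape[1]:
        raise ValueError("segment loci absent from panel")
    rows = panel.rows_for_population(population)
    if exclude_sample_index is not None:
        own = {2 * exclude_sample_index, 2 * exclude_sample_index + 1}
        rows = np.array([r for r in rows if r not in own], dtype=int)
    if rows.size == 0:
        return 0.0
    sub = panel.haplotypes[rows, lo:hi + 1]
    if calls is None:
        raise ValueError("segment call vector required to form the founder "
                         "haplotype")
    seg_calls = np.asarray(calls[lo:hi + 1])
    hom = (seg_calls == HOM_REF) | (seg_calls == HOM_ALT)
    if not hom.any():
        return 0.0
    founder = np.where(seg_calls[hom] == HOM_ALT, 1, 0).astype(np.int8)
    sub = sub[:, hom]
    L = int(hom.sum())
    tol = max(0.01 * L, 1.0)
    valid = sub >= 0
    mismatch = ((sub != founder[None, :]) & valid).sum(axis=1)
    return float((mismatch <= tol).mean())


def annotate_founder_freq(segset, gm, panel, within_population=True,
                          predicate=None):
    """Fill founder_hap_freq. ``predicate(segment)`` can restrict the
    (quadratic-ish) panel comparison to the segments that need it — e.g.
    putative autozygous calls and peak-scale segments."""
    chroms = gm.chromosomes
    offsets = {c: int(np.where(chroms == c)[0][0]) for c in dict.fromkeys(chroms)}
    sample_row = {s.id: i for i, s in enumerate(gm.samples)}
    pop_of = {s.id: s.population for s in gm.samples}
    panel_row = {sid: i for i, sid in enumerate(panel.sample_ids)}
    for seg in segset.segments:
        if predicate is not None and not predicate(seg):
            continue
        row = sample_row[seg.sample_id]
        pop = pop_of[seg.sample_id] if within_population else None
        seg.founder_hap_freq = founder_hap_freq(
            seg, panel, calls=gm.calls[row], locus_offset=offsets[seg.chromosome],
            population=pop, exclude_sample_index=panel_row.get(seg.sample_id))
    return segset


def autozygous_calls(segset):
    """The autozygosity call set: MAD score > 10 and founder frequency 0."""
    return [s for s in segset.segments
            if s.mad_score > MAD_AUTOZYGOUS_THRESHOLD and s.founder_hap_freq == 0]


# ---------------------------------------------------------------------------
# Coverage
# ---------------------------------------------------------------------------

def mappable_length(positions, max_gap_bp=500_000):
    """Span between first and last SNP minus inter-SNP gaps > ``max_gap_bp``."""
    positions = np.asarray(positions, dtype=np.int64)
    if positions.size < 2:
        raise ValueError("need at least 2 loci")
    gaps = np.diff(positions)
    return int(positions[-1] - positions[0] - gaps[gaps > max_gap_bp].sum())


def coverage_curves(segset, gm, cutoffs=None, max_hps_ex=0.01,
                    min_density=0.2, flagged_snp_limit=0.10):
    """Per-population median proportion of mappable chromosome covered by
    segments up to each length cutoff.

    Segments are pre-filtered to SNP density > ``min_density`` SNP/kb and
    HPS_ex <= ``max_hps_ex``. Per individual and chromosome, segment lengths
    are accumulated in ascending order and the cumulative sum is evaluated at
    the cutoffs (right-continuous step). An individual's chromosome is
    excluded when SNPs inside its CNV/abnormality-flagged segments exceed
    ``flagged_snp_limit`` of the chromosome's SNPs; below that, flagged
    segments are individually dropped.
    """
    if cutoffs is None:
        cutoffs = np.linspace(0, 1_000_000, 51)
    cutoffs = np.asarray(cutoffs, dtype=float)
    chroms = gm.chromosomes
    pos_all = gm.positions
    pop_of = {s.id: s.population for s in gm.samples}

    per_chrom = {}
    for chrom in dict.fromkeys(chroms):
        idx = np.where(chroms == chrom)[0]
        per_chrom[chrom] = (mappable_length(pos_all[idx]), len(idx))

    by_ind = {}
    flagged_snps = {}
    for s in segset.segments:
        key = (s.sample_id, s.chromosome)
        if "masked_cnv" in s.flags:
            flagged_snps[key] = flagged_snps.get(key, 0) + s.snp_count
        else:
            if s.hps_ex <= max_hps_ex and s.density_snp_per_kb > min_density:
                by_ind.setdefault(key, []).append(s.length_bp)

    rows = []
    for (sid, chrom), lengths in by_ind.items():
        mappable, n_snp = per_chrom[chrom]
        if flagged_snps.get((sid, chrom), 0) > flagged_snp_limit * n_snp:
            continue
        lengths = np.sort(np.asarray(lengths, dtype=float))
        csum = np.cumsum(lengths)
        k = np.searchsorted(lengths, cutoffs, side="right")
        cov = np.where(k > 0, csum[np.maximum(k - 1, 0)], 0.0) / mappable
        rows.append((pop_of[sid], chrom, sid, cov))

    out = []
    pops = sorted({r[0] for r in rows})
    for pop in pops:
        for chrom in dict.fromkeys(chroms):
            covs = [r[3] for r in rows if r[0] == pop and r[1] == chrom]
            if not covs:
                continue
            med = np.median(np.stack(covs), axis=0)
            for c, v in zip(cutoffs, med):
                out.append({"population": pop, "chromosome": chrom,
                            "cutoff_bp": c, "median_proportion": v})
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# Generic interval intersection
# ---------------------------------------------------------------------------

def intersect_segments(set_a, set_b):
    """For each interval in ``set_a``, the count and indices of intervals in
    ``set_b`` overlapping by at least 1 bp.

    Intervals are (chromosome, start, end) or (start, end) tuples, 1-based
    inclusive. Returns a list of (count, hit_index_list) aligned with
    ``set_a``; call with swapped arguments for the reverse comparison.
    """
    def norm(iv):
        return (None, iv[0], iv[1]) if len(iv) == 2 else (iv[0], iv[1], iv[2])

    b_by_chrom = {}
    for j, iv in enumerate(set_b):
        c, s, e = norm(iv)
        b_by_chrom.setdefault(c, []).append((s, e, j))
    for c in b_by_chrom:
        b_by_chrom[c].sort()

    results = []
    for iv in set_a:
        c, s, e = norm(iv)
        hits = []
        for (bs, be, j) in b_by_chrom.get(c, []):
            if bs > e:
                break
            if be >= s:
                hits.append(j)
        results.append((len(hits), hits))
    return results
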