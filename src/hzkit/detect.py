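"""Four-stage heuristic detection of homozygous segments.

Per sample and chromosome the stages are:

1. basic detection of maximal runs of homozygous genotypes (missing calls do
   not break a run; heterozygotes do);
2. splitting at large inter-SNP gaps, then joining back across a gap when the
   flanking runs are long enough relative to the gap and the combined SNP
   density is adequate (``gap_width_join_thresholds``) — long autozygous
   segments may span centromeres while short runs are truncated at gap edges;
3. absorbing isolated heterozygote 'error' while the segment-wide heterozygote
   proportion stays at or below ``max_het_proportion`` (1%);
4. a greedy left-to-right scan-ahead across heterogeneous gap/het structure
   that stops looking further once local heterozygosity over the scanned
   window exceeds ``scan_ahead_het_threshold`` (2%).

Emitted segments always satisfy the 1% overall heterozygote constraint, never
overlap within a sample-chromosome, and are bounded by homozygous SNPs.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field, replace

import numpy as np

from .genotypes import HET, HOM_ALT, HOM_REF, MISSING

log = logging.getLogger("hzkit")


@dataclass(frozen=True)
class GapRule:
    """One gap-size range: gaps up to ``gap_max_bp`` (and above the previous
    rule's maximum, or the lowest data-derived boundary for the first rule)
    may be spanned when each flanking run is at least
    ``min_flank_proportion * gap`` long and the joined span keeps at least
    ``min_density_snp_per_kb``."""

    gap_max_bp: float
    min_density_snp_per_kb: float
    min_flank_proportion: float


DEFAULT_GAP_RULES = (
    GapRule(250_000, 0.05, 0.1),
    GapRule(1_000_000, 0.02, 0.5),
    GapRule(5_000_000, 0.01, 1.0),
)


@dataclass
class DetectionParams:
    """Tuning knobs of the four-stage detector.

    ``lowest_gap_bp = None`` derives the lowest gap boundary per chromosome
    from the inter-SNP gap distribution (exp of the log-gap boxplot upper
    whisker); gaps at or below it are ordinary spacing and never split a run.
    """

    gap_width_scan_thresholds: tuple = DEFAULT_GAP_RULES
    gap_width_join_thresholds: tuple = DEFAULT_GAP_RULES
    lowest_gap_bp: float | None = None
    max_het_proportion: float = 0.01
    scan_ahead_het_threshold: float = 0.02
    min_snp_density: float = 0.2   # SNP/kb, downstream coverage filters
    max_nocall_rate: float = 0.05
    include_male_x: bool = False

    def __post_init__(self):
        if not 0 <= self.max_het_proportion <= self.scan_ahead_het_threshold <= 1:
            raise ValueError("need 0 <= max_het <= scan_ahead_het <= 1")
        for rules in (self.gap_width_scan_thresholds, self.gap_width_join_thresholds):
            maxes = [r.gap_max_bp for r in rules]
            if sorted(maxes) != maxes:
                raise ValueError("gap rule ranges must ascend in gap size")


@dataclass
class HomozygousSegment:
    sample_id: str
    chromosome: str
    start_bp: int
    end_bp: int
    start_idx: int          # locus index within the chromosome
    end_idx: int
    snp_count: int          # all loci in span (hom + het + missing)
    het_count: int
    nocall_count: int
    length_cm: float = float("nan")
    hps_ex: float = float("nan")
    hps_in: float = float("nan")
    mad_score: float = float("nan")
    founder_hap_freq: float = float("nan")
    flags: set = field(default_factory=set)

    @property
    def length_bp(self):
        return self.end_bp - self.start_bp + 1

    @property
    def density_snp_per_kb(self):
        return self.snp_count / (self.length_bp / 1000.0)


@dataclass
class SegmentSet:
    segments: list
    params: DetectionParams
    dataset_hash: str = ""

    def for_sample_chrom(self, sample_id, chromosome):
        return [s for s in self.segments
                if s.sample_id == sample_id and s.chromosome == chromosome]

    def filtered(self, max_hps_ex=None, min_density=None, exclude_flags=()):
        out = []
        for s in self.segments:
            if max_hps_ex is not None and not (s.hps_ex <= max_hps_ex):
                continue
            if min_density is not None and s.density_snp_per_kb <= min_density:
                continue
            if any(f in s.flags for f in exclude_flags):
                continue
            out.append(s)
        return SegmentSet(out, self.params, self.dataset_hash)


# ---------------------------------------------------------------------------
# Stage 0: gap threshold derivation
# ---------------------------------------------------------------------------

def compute_gap_thresholds(positions):
    """Lowest gap-range boundary: exp(Q3 + 1.5*IQR) of the natural-log
    inter-SNP gaps (boxplot upper whisker on the log scale)."""
    positions = np.asarray(positions, dtype=float)
    if positions.size < 3:
        raise ValueError("need at least 3 loci to derive gap thresholds")
    lg = np.log(np.diff(positions))
    q1, q3 = np.quantile(lg, [0.25, 0.75])
    return float(np.exp(q3 + 1.5 * (q3 - q1)))


# ---------------------------------------------------------------------------
# Stage machinery (index-span representation)
# ---------------------------------------------------------------------------

class _Chrom:
    """Per-sample-chromosome working state with prefix-sum counters."""

    def __init__(self, calls, positions, params):
        self.calls = calls
        self.pos = positions
        self.params = params
        self.is_het = calls == HET
        self.is_hom = (calls == HOM_REF) | (calls == HOM_ALT)
        self.is_mis = calls == MISSING
        self._het_ps = np.concatenate([[0], np.cumsum(self.is_het)])
        self._mis_ps = np.concatenate([[0], np.cumsum(self.is_mis)])
        if params.lowest_gap_bp is not None:
            self.lowest_gap = params.lowest_gap_bp
        elif len(positions) >= 3:
            self.lowest_gap = compute_gap_thresholds(positions)
        else:
            self.lowest_gap = float("inf")

    def hets(self, i, j):
        return int(self._het_ps[j + 1] - self._het_ps[i])

    def miss(self, i, j):
        return int(self._mis_ps[j + 1] - self._mis_ps[i])

    def span_bp(self, i, j):
        return int(self.pos[j] - self.pos[i] + 1)

    def het_frac(self, i, j):
        return self.hets(i, j) / (j - i + 1)

    def is_big_gap(self, gap_bp):
        # relative tolerance: exp(log(g)) may round just below g
        return gap_bp > self.lowest_gap * (1 + 1e-9)

    def gap_ok(self, gap_bp, rules, left_len_bp, right_len_bp,
               span_snps, span_bp):
        """May a span cross this inter-SNP gap?"""
        if not self.is_big_gap(gap_bp):
            return True
        prev_max = self.lowest_gap
        for rule in rules:
            if prev_max < gap_bp <= rule.gap_max_bp:
                if (left_len_bp < rule.min_flank_proportion * gap_bp
                        or right_len_bp < rule.min_flank_proportion * gap_bp):
                    return False
                return span_snps / (span_bp / 1000.0) >= rule.min_density_snp_per_kb
            prev_max = rule.gap_max_bp
        return False  # beyond the largest configured range

    def gaps_ok_between(self, left, right, rules):
        """Check every inter-SNP gap between span ``left=(i1,j1)`` and
        ``right=(i2,j2)`` under ``rules``; flanks are the two spans."""
        (i1, j1), (i2, j2) = left, right
        left_len = self.span_bp(i1, j1)
        right_len = self.span_bp(i2, j2)
        span_snps = j2 - i1 + 1
        span = self.span_bp(i1, j2)
        for k in range(j1, i2):
            gap = int(self.pos[k + 1] - self.pos[k])
            if not self.gap_ok(gap, rules, left_len, right_len, span_snps, span):
                return False
        return True


def detect_runs(calls, positions=None):
    """Stage 1: maximal runs of consecutive homozygous calls.

    Missing calls do not break a run (they are counted later); heterozygotes
    do. Runs are trimmed so that both ends are homozygous SNPs. Returns a list
    of (start_idx, end_idx) spans.
    """
    calls = np.asarray(calls)
    is_hom = (calls == HOM_REF) | (calls == HOM_ALT)
    is_het = calls == HET
    runs = []
    n = len(calls)
    i = 0
    while i < n:
        if is_het[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and not is_het[j + 1]:
            j += 1
        hom_idx = np.where(is_hom[i:j + 1])[0]
        if hom_idx.size:
            runs.append((i + int(hom_idx[0]), i + int(hom_idx[-1])))
        i = j + 1
    return runs


def split_at_gaps(runs, st):
    """Split runs at inter-SNP gaps above the lowest gap boundary."""
    out = []
    for i, j in runs:
        s = i
        for k in range(i, j):
            if st.is_big_gap(st.pos[k + 1] - st.pos[k]):
                # trim piece to homozygous ends
                piece = _trim(s, k, st)
                if piece:
                    out.append(piece)
                s = k + 1
        piece = _trim(s, j, st)
        if piece:
            out.append(piece)
    return out


def _trim(i, j, st):
    while i <= j and not st.is_hom[i]:
        i += 1
    while j >= i and not st.is_hom[j]:
        j -= 1
    return (i, j) if i <= j else None


def join_across_gaps(runs, st):
    """Stage 2: rejoin neighbouring runs across qualifying gaps (no
    intervening heterozygote) under ``gap_width_join_thresholds``."""
    rules = st.params.gap_width_join_thresholds
    runs = list(runs)
    changed = True
    while changed:
        changed = False
        out = []
        k = 0
        while k < len(runs):
            cur = runs[k]
            while (k + 1 < len(runs)
                   and st.hets(cur[1], runs[k + 1][0]) == 0
                   and st.gaps_ok_between(cur, runs[k + 1], rules)):
                cur = (cur[0], runs[k + 1][1])
                k += 1
                changed = True
            out.append(cur)
            k += 1
        runs = out
    return runs


def absorb_het_error(runs, st):
    """Stage 3: merge adjacent runs across isolated heterozygotes while the
    accumulated segment's het proportion stays <= max_het_proportion."""
    max_het = st.params.max_het_proportion
    rules = st.params.gap_width_join_thresholds
    out = []
    k = 0
    while k < len(runs):
        cur = runs[k]
        while k + 1 < len(runs):
            nxt = runs[k + 1]
            if st.hets(cur[1], nxt[0]) == 0:
                break  # pure-gap boundary: left for scan-ahead
            merged = (cur[0], nxt[1])
            if (st.het_frac(*merged) <= max_het
                    and st.gaps_ok_between(cur, nxt, rules)):
                cur = merged
                k += 1
            else:
                break
        out.append(cur)
        k += 1
    return out


def scan_ahead(segments, st):
    """Stage 4: greedy forward extension across heterogeneous gap/het
    structure. Scanning past the current segment stops once heterozygosity
    over the scanned window exceeds ``scan_ahead_het_threshold``; an
    extension is accepted when it keeps the overall het proportion within
    ``max_het_proportion`` and its gaps satisfy
    ``gap_width_scan_thresholds``. Never retracts earlier joins.

    The scanned window is the heterogeneous stretch between the current
    segment end and the candidate's first locus. The stop rule requires at
    least two heterozygotes in that window (a single isolated het cannot
    abort the scan; the 1% overall rule still gates its absorption) plus a
    window het proportion above the threshold."""
    p = st.params
    rules = p.gap_width_scan_thresholds
    out = []
    k = 0
    while k < len(segments):
        cur = segments[k]
        m = k + 1
        while m < len(segments):
            cand = segments[m]
            # scanned window: from current segment end to candidate start
            w_lo, w_hi = cur[1] + 1, cand[0] - 1
            w_hets = st.hets(w_lo, w_hi) if w_hi >= w_lo else 0
            if (w_hets >= 2
                    and w_hets / (w_hi - w_lo + 1) > p.scan_ahead_het_threshold):
                break
            merged = (cur[0], cand[1])
            if (st.het_frac(*merged) <= p.max_het_proportion
                    and st.gaps_ok_between(cur, cand, rules)):
                cur = merged
                k = m
            m += 1
        out.append(cur)
        k += 1
    return out


# ---------------------------------------------------------------------------
# Top-level driver
# ---------------------------------------------------------------------------

def _is_chrx(chrom):
    return str(chrom).removeprefix("chr").upper() in {"X", "23"}


def detect_segments(gm, params=None, mask=None):
    """Run the four detection stages for every sample and chromosome.

    Chromosome X uses female (and unknown-sex) samples only unless
    ``params.include_male_x``. Segments are flagged ``high_missing`` when the
    no-call rate exceeds ``max_nocall_rate``, ``low_density`` at or below
    ``min_snp_density`` SNP/kb, and ``masked_cnv`` when more than 50% of
    included loci fall in CNV/abnormality mask intervals.
    """
    params = params or DetectionParams()
    chroms = gm.chromosomes
    pos_all = gm.positions
    segments = []
    for chrom in dict.fromkeys(chroms):
        idx = np.where(chroms == chrom)[0]
        pos = pos_all[idx]
        mask_hit = _mask_hit_vector(chrom, pos, mask)
        x = _is_chrx(chrom)
        for si, sample in enumerate(gm.samples):
            if x and not params.include_male_x and sample.sex == "male":
                continue
            calls = gm.calls[si, idx]
            st = _Chrom(calls, pos, params)
            runs = detect_runs(calls)
            runs = split_at_gaps(runs, st)
            runs = join_across_gaps(runs, st)
            runs = absorb_het_error(runs, st)
            runs = scan_ahead(runs, st)
            for i, j in runs:
                if j - i + 1 < 2:
                    continue
                seg = HomozygousSegment(
                    sample_id=sample.id, chromosome=str(chrom),
                    start_bp=int(pos[i]), end_bp=int(pos[j]),
                    start_idx=i, end_idx=j,
                    snp_count=j - i + 1,
                    het_count=st.hets(i, j),
                    nocall_count=st.miss(i, j),
                )
                if seg.nocall_count / seg.snp_count > params.max_nocall_rate:
                    seg.flags.add("high_missing")
                if seg.density_snp_per_kb <= params.min_snp_density:
                    seg.flags.add("low_density")
                if mask_hit is not None:
                    frac = mask_hit[i:j + 1].mean()
                    if frac > 0.5:
                        seg.flags.add("masked_cnv")
                segments.append(seg)
    h = hashlib.sha1(gm.calls.tobytes()).hexdigest()[:12]
    return SegmentSet(segments, params, h)


def _mask_hit_vector(chrom, pos, mask):
    if mask is None or not mask.intervals:
        return None
    hit = np.zeros(len(pos), dtype=bool)
    for mchrom, start, end, kind, freq in mask.intervals:
        if mchrom == str(chrom) and kind in {"cnv", "abnormality"}:
            hit |= (pos >= start) & (pos <= end)
    return hit


def segments_to_frame(segset):
    """Segment table as a DataFrame (TSV-ready)."""
    import pandas as pd

    rows = [{
        "sample": s.sample_id, "chromosome": s.chromosome,
        "start_bp": s.start_bp, "end_bp": s.end_bp,
        "snp_count": s.snp_count, "het_count": s.het_count,
        "nocall_count": s.nocall_count, "length_bp": s.length_bp,
        "length_cm": s.length_cm, "hps_ex": s.hps_ex, "hps_in": s.hps_in,
        "mad_score": s.mad_score, "founder_hap_freq": s.founder_hap_freq,
        "flags": ";".join(sorted(s.flags)),
    } for s in segset.segments]
    return pd.DataFrame(rows)


def write_segments_tsv(segset, path):
    segments_to_frame(segset).to_csv(path, sep="\t", index=False)


def write_segments_bed(segset, path):
    """BED export (0-based half-open) with the sample id in the name field."""
    with open(path, "w") as fh:
        for s in segset.segments:
            fh.write(f"{s.chromosome}\t{s.start_bp - 1}\t{s.end_bp}\t{s.sample_id}\n")
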