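"""Intersecting-segment-length matrices and homozygous-extent statistics.

The ISLM records, for every sample (row) and SNP (column), the length of the
sample's homozygous segment covering that SNP (0 when uncovered). Columns are
summarised per population as percentile-extent matrices (PE_mat) and as
ext_AUC — the area under the ECDF of the sign-reversed column over its
negative support, a single-locus summary of how long and how frequent
overlapping homozygosity is.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

log = logging.getLogger("hzkit")

# cell states
OBSERVED, MASKED_MISSING, CAPPED = 0, 1, 2

PERCENTILE_LEVELS = np.linspace(0.0, 1.0, 101)


@dataclass
class ArmRateTable:
    """Chromosome-arm average recombination rates (cM/Mb).

    ``frame`` columns: chromosome, arm, start_bp, end_bp, cm_per_mb.
    """

    frame: pd.DataFrame

    @classmethod
    def read_tsv(cls, path):
        return cls(pd.read_csv(path, sep="\t", dtype={"chromosome": str}))

    def write_tsv(self, path):
        self.frame.to_csv(path, sep="\t", index=False)

    def rate(self, chromosome, arm):
        m = self.frame[(self.frame.chromosome == str(chromosome))
                       & (self.frame.arm == arm)]
        if m.empty:
            raise KeyError(f"no rate for {chromosome}{arm}")
        return float(m.cm_per_mb.iloc[0])

    def arms(self, chromosome):
        m = self.frame[self.frame.chromosome == str(chromosome)]
        if m.empty:
            raise KeyError(f"no arms for chromosome {chromosome}")
        return m.sort_values("start_bp")


def bp_to_cm(length_bp, chromosome, arm, arm_rates):
    """Physical length to genetic length via the arm's average rate."""
    return length_bp * arm_rates.rate(chromosome, arm) / 1e6


def span_cm(chromosome, start_bp, end_bp, arm_rates):
    """Genetic length of [start_bp, end_bp]; spans crossing an arm boundary
    are split proportionally by the bp in each arm."""
    total = 0.0
    covered = False
    for _, row in arm_rates.arms(chromosome).iterrows():
        lo = max(start_bp, row.start_bp)
        hi = min(end_bp, row.end_bp)
        if lo <= hi:
            covered = True
            total += (hi - lo + 1) * row.cm_per_mb / 1e6
    if not covered:
        raise KeyError(f"span {chromosome}:{start_bp}-{end_bp} outside arm table")
    return total


@dataclass
class ISLM:
    """samples x loci intersecting-segment lengths with per-cell state."""

    values: np.ndarray          # float, NaN where masked_missing
    state: np.ndarray           # uint8 over {OBSERVED, MASKED_MISSING, CAPPED}
    units: str                  # "bp" or "cM"
    chromosomes: np.ndarray
    positions: np.ndarray
    sample_ids: list
    populations: list

    def chrom_index(self, chromosome):
        return np.where(self.chromosomes == str(chromosome))[0]

    def chrom_block(self, chromosome):
        return self.values[:, self.chrom_index(chromosome)]

    def rows_for_population(self, population):
        if population is None:
            return np.arange(len(self.sample_ids))
        return np.array([i for i, p in enumerate(self.populations)
                         if p == population], dtype=int)

    def to_frame(self):
        return pd.DataFrame(self.values, index=self.sample_ids,
                            columns=[f"{c}:{p}" for c, p in
                                     zip(self.chromosomes, self.positions)])


def build_islm(segset, gm, units="bp", arm_rates=None, max_hps_ex=0.01):
    """Build the ISLM from a segment set.

    Segments with ``hps_ex > max_hps_ex`` — runs short enough to be likely
    under independent chance homozygosity — are excluded (pass ``None`` to
    keep everything). Without this filter the non-zero column distributions
    are dominated by few-SNP chance runs, which would both distort the
    percentile summaries and make the robust MAD denominator collapse.
    Segments carrying the ``masked_cnv`` flag contribute masked (missing)
    cells rather than lengths.
    """
    if units not in {"bp", "cM"}:
        raise ValueError("units must be 'bp' or 'cM'")
    if units == "cM" and arm_rates is None:
        raise ValueError("cM units require an arm rate table")
    n_s, n_l = gm.n_samples, gm.n_loci
    values = np.zeros((n_s, n_l))
    state = np.zeros((n_s, n_l), dtype=np.uint8)
    chroms = gm.chromosomes
    offsets = {c: int(np.where(chroms == c)[0][0]) for c in dict.fromkeys(chroms)}
    row = {s.id: i for i, s in enumerate(gm.samples)}
    for seg in segset.segments:
        if max_hps_ex is not None and not (np.isnan(seg.hps_ex)
                                           or seg.hps_ex <= max_hps_ex):
            continue
        off = offsets[seg.chromosome]
        sl = slice(off + seg.start_idx, off + seg.end_idx + 1)
        r = row[seg.sample_id]
        if "masked_cnv" in seg.flags:
            values[r, sl] = np.nan
            state[r, sl] = MASKED_MISSING
            continue
        if units == "bp":
            length = float(seg.length_bp)
        else:
            length = span_cm(seg.chromosome, seg.start_bp, seg.end_bp, arm_rates)
            seg.length_cm = length
        values[r, sl] = length
    return ISLM(values, state, units, chroms.copy(), gm.positions.copy(),
                [s.id for s in gm.samples], [s.population for s in gm.samples])


def mask_islm_autozygous(islm, segset, threshold=10.0):
    """Cap cells fed by putative autozygous segments (MAD score > threshold)
    at the highest non-autozygous length in the same column.

    Returns a new ISLM; capped cells are marked ``CAPPED``. A column whose
    positive mass is entirely autozygous is capped to 0 (logged).
    """
    values = islm.values.copy()
    state = islm.state.copy()
    chroms = islm.chromosomes
    offsets = {c: int(np.where(chroms == c)[0][0]) for c in dict.fromkeys(chroms)}
    row = {sid: i for i, sid in enumerate(islm.sample_ids)}
    auto = np.zeros_like(values, dtype=bool)
    for seg in segset.segments:
        if seg.mad_score > threshold:
            off = offsets[seg.chromosome]
            sl = slice(off + seg.start_idx, off + seg.end_idx + 1)
            auto[row[seg.sample_id], sl] = True
    n_zeroed = 0
    for j in np.where(auto.any(axis=0))[0]:
        col = values[:, j]
        nonauto = col[~auto[:, j] & ~np.isnan(col)]
        cap = float(nonauto.max()) if nonauto.size else 0.0
        if cap == 0.0 and not nonauto.size:
            n_zeroed += 1
        rows = auto[:, j] & ~np.isnan(col)
        values[rows, j] = cap
        state[rows, j] = CAPPED
    if n_zeroed:
        log.info("mask_islm_autozygous: %d columns had only autozygous values "
                 "(set to 0)", n_zeroed)
    return ISLM(values, state, islm.units, chroms, islm.positions,
                islm.sample_ids, islm.populations)


# ---------------------------------------------------------------------------
# Percentile-extent matrix
# ---------------------------------------------------------------------------

@dataclass
class PEMat:
    """loci x 101 percentile levels of the population's ISLV distributions."""

    values: np.ndarray
    population: str
    units: str
    chromosomes: np.ndarray
    positions: np.ndarray
    levels: np.ndarray = field(default_factory=lambda: PERCENTILE_LEVELS.copy())

    def chrom_index(self, chromosome):
        return np.where(self.chromosomes == str(chromosome))[0]

    def to_frame(self):
        df = pd.DataFrame(self.values,
                          columns=[f"p{int(round(l * 100))}" for l in self.levels])
        df.insert(0, "position_bp", self.positions)
        df.insert(0, "chromosome", self.chromosomes)
        return df


def pe_mat(islm, population):
    """Per-locus 101 quantiles (linear-interpolation / type-7 definition) of
    the population's ISLV. Masked cells are dropped; zeros are retained.
    All-masked columns yield a NaN row."""
    rows = islm.rows_for_population(population)
    if rows.size == 0:
        raise ValueError(f"population {population!r} has no samples")
    sub = islm.values[rows]
    n_loci = sub.shape[1]
    out = np.full((n_loci, 101), np.nan)
    ok = ~np.isnan(sub)
    full = ok.all(axis=0)
    if full.any():
        out[full] = np.quantile(sub[:, full], PERCENTILE_LEVELS, axis=0).T
    for j in np.where(~full)[0]:
        v = sub[ok[:, j], j]
        if v.size:
            out[j] = np.quantile(v, PERCENTILE_LEVELS)
    return PEMat(out, population, islm.units, islm.chromosomes.copy(),
                 islm.positions.copy())


# ---------------------------------------------------------------------------
# ext_AUC
# ---------------------------------------------------------------------------

@dataclass
class ExtAucTrack:
    population: str
    ext_auc: np.ndarray
    chromosomes: np.ndarray
    positions: np.ndarray
    rank: np.ndarray = None

    def chrom_index(self, chromosome):
        return np.where(self.chromosomes == str(chromosome))[0]

    def to_frame(self):
        return pd.DataFrame({"chromosome": self.chromosomes,
                             "position_bp": self.positions,
                             "ext_auc": self.ext_auc,
                             "rank": (self.rank if self.rank is not None
                                      else np.nan)})


def _ecdf_integral(values, lower, upper):
    """Exact integral of the right-continuous ECDF of ``values`` over
    [lower, upper] via step-function summation."""
    if upper <= lower:
        return 0.0
    x = np.sort(values)
    n = x.size
    # partition induced by ECDF jump points clipped to the bounds
    jumps = np.unique(x[(x > lower) & (x < upper)])
    pts = np.concatenate([[lower], jumps, [upper]])
    # F at left end of each sub-interval
    f = np.searchsorted(x, pts[:-1], side="right") / n
    return float(np.sum(f * np.diff(pts)))


def ext_auc(islm, population):
    """Per-locus ext_AUC for one population.

    The full (all-population) ISLV is sign-reversed to orient the rare long
    segments at the start of the ECDF; the integration bounds come from that
    combined reversed vector (lower = most negative value, upper = the value
    closest to zero from below). The population's ECDF (zeros retained,
    masked cells dropped) is then integrated exactly over those bounds. Loci
    with no intersecting segment anywhere score 0.
    """
    rows = islm.rows_for_population(population)
    if rows.size == 0:
        raise ValueError(f"population {population!r} has no samples")
    n_loci = islm.values.shape[1]
    out = np.zeros(n_loci)
    vals = islm.values
    for j in range(n_loci):
        col = vals[:, j]
        col = col[~np.isnan(col)]
        neg = -col[col > 0]
        if neg.size == 0:
            continue
        lower, upper = float(neg.min()), float(neg.max())
        pop_col = vals[rows, j]
        pop_col = -pop_col[~np.isnan(pop_col)]
        if pop_col.size == 0:
            continue
        out[j] = _ecdf_integral(pop_col, lower, upper)
    return ExtAucTrack(population, out, islm.chromosomes.copy(),
                       islm.positions.copy())


def ext_auc_rank(track):
    """ECDF rank of each ext_AUC value within its chromosome:
    rank(x) = #(values <= x) / n. Fills ``track.rank`` and returns it."""
    rank = np.empty_like(track.ext_auc)
    for chrom in dict.fromkeys(track.chromosomes):
        idx = track.chrom_index(chrom)
        v = track.ext_auc[idx]
        s = np.sort(v)
        rank[idx] = np.searchsorted(s, v, side="right") / v.size
    track.rank = rank
    return track
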