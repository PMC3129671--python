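"""Seeded synthetic genotype panels with planted truth.

The generator uses a founder-mosaic model: a small pool of chromosome-length
founder haplotypes with known frequencies, and every chromosome copy is a
mosaic of founder blocks whose boundaries follow a per-copy renewal process
with a two-scale block-length mixture (``block_mix``). Homozygous runs arise
where a sample's two copies ride the same founder, so run lengths vary
continuously across samples — the block structure directly controls the
quantities the analysis measures (haplotype frequency, homozygous extent,
fixation) without simulating demography or recombination maps.

Three feature types can be planted with recorded truth:

* an autozygous tract — one sample receives a novel haplotype copied onto
  both chromosomes over an interval (founder frequency zero by construction);
* an extended haplotype — carrier copies ride founder 0 across the whole
  interval (sharp edges; non-carriers never touch founder 0 inside it) at a
  configured per-population carrier frequency;
* a fixed region — every copy (optionally of one population) rides founder 0
  over the interval.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .annotate import PhasedHaplotypePanel
from .extent import ArmRateTable
from .genotypes import GenotypeMatrix, LocusInfo, SampleInfo
from .peaks import GeneticMap


@dataclass
class PlantedAutozygousTract:
    sample_id: str
    start_locus: int   # 0-based locus indices, inclusive
    end_locus: int


@dataclass
class PlantedExtendedHaplotype:
    start_locus: int
    end_locus: int
    frequency: dict    # population -> carrier frequency of the planted founder
    #: decay of the haplotype past each core edge: most copies end sharply at
    #: the core boundary, the rest persist geometrically (mean ``tail_loci``)
    tail_loci: int = 150
    tail_zero_prob: float = 0.85
    #: frequency-graded core: one homozygous carrier per population spans only
    #: the inner sub-interval (this many loci inside each edge), the way a
    #: real extended haplotype's frequency decays toward its edges
    indent_loci: int = 250


@dataclass
class PlantedFixedRegion:
    start_locus: int
    end_locus: int
    population: str | None = None   # None = all populations; population-
    # restricted fixation is the scientifically interesting (and, through
    # pooled Freq_HOM, HPS-detectable) case


@dataclass
class SimConfig:
    populations: dict = field(default_factory=lambda: {"POPA": 50, "POPB": 50})
    n_loci: int = 5000
    #: founder-block length mixture: (mean_loci, probability) components;
    #: the long component gives ISLV columns a realistic length dispersion
    block_mix: tuple = ((60, 0.85), (250, 0.15))
    chromosome: str = "1"
    base_spacing_bp: int = 1000
    big_gap_prob: float = 0.002
    big_gap_scale_bp: float = 30_000.0
    n_founders: int = 8
    founder_concentration: float = 2.0   # Dirichlet parameter for pool freqs
    het_error_rate: float = 0.001
    missing_rate: float = 0.01
    planted: list = field(default_factory=list)
    cm_per_mb_p: float = 1.2             # arm-average recombination rates
    cm_per_mb_q: float = 1.0
    seed: int = 0

    def __post_init__(self):
        for r in (self.het_error_rate, self.missing_rate, self.big_gap_prob):
            if not 0 <= r <= 1:
                raise ValueError("rates must lie in [0,1]")
        for f in self.planted:
            if not (0 <= f.start_locus <= f.end_locus < self.n_loci):
                raise ValueError("planted interval outside [0, n_loci)")
            if isinstance(f, PlantedExtendedHaplotype):
                if any(not 0 <= v <= 1 for v in f.frequency.values()):
                    raise ValueError("infeasible planted frequency")


@dataclass
class TruthTable:
    planted: list
    tract_spans_bp: dict       # sample_id -> (start_bp, end_bp)
    realized_hap_freq: list    # per planted extended hap: {pop: realized freq}
    fixed_spans_bp: list
    ext_spans_bp: list = field(default_factory=list)
    founder_freqs: np.ndarray = None


def simulate_panel(cfg):
    """Draw a diploid panel from the founder-mosaic model.

    Returns (GenotypeMatrix, PhasedHaplotypePanel, TruthTable); the panel
    holds the realized pre-error haplotypes (two rows per sample).
    """
    rng = np.random.default_rng(cfg.seed)
    n_loci = cfg.n_loci

    # --- positions -------------------------------------------------------
    # planted features sit in uniformly assayed regions: no big inter-SNP
    # gaps inside (or immediately flanking) a planted interval
    gaps = np.full(n_loci - 1, cfg.base_spacing_bp, dtype=np.int64)
    big = rng.random(n_loci - 1) < cfg.big_gap_prob
    for f in cfg.planted:
        big[max(0, f.start_locus - 2):f.end_locus + 2] = False
    gaps[big] += rng.exponential(cfg.big_gap_scale_bp, big.sum()).astype(np.int64)
    positions = np.concatenate([[1], 1 + np.cumsum(gaps)])

    samples = []
    for pop, n in cfg.populations.items():
        samples += [SampleInfo(f"{pop}_{i:03d}", pop) for i in range(n)]
    n_s = len(samples)
    pop_rows = {pop: np.array([i for i, s in enumerate(samples)
                               if s.population == pop]) for pop in cfg.populations}

    K = cfg.n_founders
    founders = rng.integers(0, 2, size=(K, n_loci)).astype(np.int8)
    freqs = rng.dirichlet(np.full(K, cfg.founder_concentration))

    # --- founder mosaic per chromosome copy ------------------------------
    means = np.array([m for m, _ in cfg.block_mix], dtype=float)
    probs = np.array([p for _, p in cfg.block_mix], dtype=float)
    probs = probs / probs.sum()
    cdf = np.cumsum(freqs)
    cdf[-1] = 1.0
    idx = np.empty((2 * n_s, n_loci), dtype=np.int16)
    for c in range(2 * n_s):
        pos = 0
        while pos < n_loci:
            mean = means[np.searchsorted(np.cumsum(probs), rng.random(),
                                         side="right")]
            length = 1 + rng.geometric(1.0 / mean)
            founder = int(np.searchsorted(cdf, rng.random(), side="right"))
            idx[c, pos:pos + length] = founder
            pos += length

    ext_feats = [f for f in cfg.planted if isinstance(f, PlantedExtendedHaplotype)]
    fix_feats = [f for f in cfg.planted if isinstance(f, PlantedFixedRegion)]
    tracts = [f for f in cfg.planted if isinstance(f, PlantedAutozygousTract)]

    # planted founder is index 0; carrier copies ride it across the whole
    # interval plus geometric decay tails, non-carriers are rerouted off it
    # inside the interval
    ext_carrier = []
    for f in ext_feats:
        # conditional-on-frequency assignment: exactly round(2nf) carrier
        # copies per population, with the Hardy-Weinberg-expected number of
        # carrier homozygotes (round(n f^2)) realized exactly
        carrier = np.zeros(2 * n_s, dtype=bool)
        for pop, target in f.frequency.items():
            members = pop_rows[pop]
            n_pop = members.size
            total = int(round(2 * n_pop * target))
            n_hom = min(int(round(n_pop * target * target)), total // 2)
            order = rng.permutation(members)
            hom = order[:n_hom]
            n_single = total - 2 * n_hom
            single = order[n_hom:n_hom + n_single]
            carrier[np.concatenate([[2 * i, 2 * i + 1] for i in hom])
                    if n_hom else []] = True
            which = rng.integers(0, 2, size=n_single)
            carrier[2 * single + which] = True
        ext_carrier.append(carrier)
        span = f.end_locus - f.start_locus + 1
        indented = set()
        if f.indent_loci and 2 * f.indent_loci < span:
            # graded core: one additional homozygous sample per population
            # with carriers spans only the inner sub-interval, the way a real
            # extended haplotype's frequency decays toward its edges
            for pop, target in f.frequency.items():
                if target * target * pop_rows[pop].size < 0.5:
                    continue  # no homozygotes expected in this population
                free = [i for i in pop_rows[pop]
                        if not carrier[2 * i] and not carrier[2 * i + 1]]
                if not free:
                    continue
                i = free[int(rng.integers(len(free)))]
                for c in (2 * i, 2 * i + 1):
                    carrier[c] = True
                    indented.add(c)
                    idx[c, f.start_locus + f.indent_loci:
                         f.end_locus - f.indent_loci + 1] = 0
        spans = {}
        for c in np.where(carrier)[0]:
            if c in indented:
                spans[c] = (f.start_locus + f.indent_loci,
                            f.end_locus - f.indent_loci)
                continue  # the indented anchor keeps its inner span
            tail_l = tail_r = 0
            if f.tail_loci:
                if rng.random() >= f.tail_zero_prob:
                    tail_l = rng.geometric(1.0 / f.tail_loci)
                if rng.random() >= f.tail_zero_prob:
                    tail_r = rng.geometric(1.0 / f.tail_loci)
            lo = max(0, f.start_locus - tail_l)
            hi = min(n_loci - 1, f.end_locus + tail_r)
            idx[c, lo:hi + 1] = 0
            spans[c] = (lo, hi)
        if K >= 3:
            # the haplotype ends at its (possibly tailed) boundary: carrier
            # chromosome pairs recombine onto distinct backgrounds there, so
            # a homozygote's run cannot drift past the planted span on a
            # shared background block
            for i in range(n_s):
                c1, c2 = 2 * i, 2 * i + 1
                if c1 not in spans or c2 not in spans:
                    continue
                lo = max(spans[c1][0], spans[c2][0])
                hi = min(spans[c1][1], spans[c2][1])
                for zone in (slice(max(0, lo - 400), lo),
                             slice(hi + 1, min(n_loci, hi + 401))):
                    zo = np.arange(zone.start, zone.stop)
                    if zo.size == 0:
                        continue
                    v1 = idx[c1, zone].copy()
                    v2 = idx[c2, zone].copy()
                    eq = v1 == v2
                    # a copy keeps founder 0 where its own planted span
                    # (core + tail) covers the locus; its partner diverges
                    prot2 = (zo >= spans[c2][0]) & (zo <= spans[c2][1])
                    m2 = eq & ~prot2
                    m1 = eq & prot2
                    idx[c2, zone][m2] = v1[m2] % (K - 1) + 1
                    idx[c1, zone][m1] = v2[m1] % (K - 1) + 1
        if K > 1:
            alt_cdf = np.cumsum(freqs[1:] / freqs[1:].sum())
            alt_cdf[-1] = 1.0
            for c in np.where(~carrier)[0]:
                sl = idx[c, f.start_locus:f.end_locus + 1]
                if (sl == 0).any():
                    repl = 1 + int(np.searchsorted(alt_cdf, rng.random(),
                                                   side="right"))
                    sl[sl == 0] = repl
    for f in fix_feats:
        sl = slice(f.start_locus, f.end_locus + 1)
        if f.population is None:
            idx[:, sl] = 0
        else:
            rows = np.concatenate([[2 * i, 2 * i + 1]
                                   for i in pop_rows[f.population]])
            idx[rows, sl] = 0
        # population-restricted fixation is only observable (and its boundary
        # only defined at SNP resolution) where the panel as a whole remains
        # polymorphic: balance the founder alleles over the region and the
        # two loci flanking each edge so no MAF filter can erode it
        lo = max(0, f.start_locus - 2)
        hi = min(n_loci - 1, f.end_locus + 2)
        founders[:, lo:hi + 1] = (np.arange(K) % 2)[:, None]

    hap = founders[idx, np.arange(n_loci)[None, :]]

    # autozygous tracts: a novel haplotype on both copies
    sample_row = {s.id: i for i, s in enumerate(samples)}
    tract_spans = {}
    for f in tracts:
        i = sample_row[f.sample_id]
        novel = rng.integers(0, 2, size=f.end_locus - f.start_locus + 1,
                             dtype=np.int8)
        hap[2 * i, f.start_locus:f.end_locus + 1] = novel
        hap[2 * i + 1, f.start_locus:f.end_locus + 1] = novel
        tract_spans[f.sample_id] = (int(positions[f.start_locus]),
                                    int(positions[f.end_locus]))

    realized = []
    for f, carrier in zip(ext_feats, ext_carrier):
        realized.append({pop: float(carrier[np.concatenate(
            [[2 * i, 2 * i + 1] for i in pop_rows[pop]])].mean())
            for pop in f.frequency})

    # --- genotypes from haplotype pairs ---------------------------------
    ha, hb = hap[0::2], hap[1::2]
    calls = np.where(ha == hb, np.where(ha == 1, 2, 0), 1).astype(np.uint8)
    hom = calls != 1
    flip = (rng.random(calls.shape) < cfg.het_error_rate) & hom
    calls[flip] = 1
    miss = rng.random(calls.shape) < cfg.missing_rate
    calls[miss] = 3

    arm_split = positions[n_loci // 2]
    loci = [LocusInfo(f"rs{j + 1}", cfg.chromosome, int(positions[j]),
                      ("A", "G"), arm="p" if positions[j] < arm_split else "q")
            for j in range(n_loci)]
    gm = GenotypeMatrix(calls, loci, samples, validate=False)
    panel = PhasedHaplotypePanel(hap, [s.id for s in samples],
                                 [s.population for s in samples])
    truth = TruthTable(
        planted=list(cfg.planted), tract_spans_bp=tract_spans,
        realized_hap_freq=realized,
        fixed_spans_bp=[(int(positions[f.start_locus]),
                         int(positions[f.end_locus])) for f in fix_feats],
        ext_spans_bp=[(int(positions[f.start_locus]),
                       int(positions[f.end_locus])) for f in ext_feats],
        founder_freqs=freqs)
    return gm, panel, truth


def simulate_two_group_shift(cfg, interval, shift=3.0, base_frequency=0.2):
    """Two-group panel with a planted segment-length shift in one window.

    Within ``interval`` (locus indices), both groups carry an extended
    haplotype, but the second population carries it at ``min(0.95,
    base_frequency * shift)`` versus ``base_frequency`` in the first —
    lengthening that group's overlapping homozygous segments there. Truth
    records the window."""
    if shift <= 0:
        raise ValueError("shift must be > 0")
    pops = list(cfg.populations)
    if len(pops) != 2:
        raise ValueError("two populations required")
    freq = {pops[0]: base_frequency,
            pops[1]: min(0.95, base_frequency * shift)}
    planted = list(cfg.planted) + [
        PlantedExtendedHaplotype(interval[0], interval[1], freq)]
    cfg2 = SimConfig(**{**cfg.__dict__, "planted": planted})
    return simulate_panel(cfg2)


def simulate_genetic_map(cfg, hotspots=(), base_rate=1.0, end_bp=None):
    """Piecewise-constant cM/Mb map with optional hotspots plus the
    consistent arm-average rate table.

    ``hotspots``: iterable of (start_bp, end_bp, cm_per_mb). Returns
    (GeneticMap, ArmRateTable)."""
    if end_bp is None:
        end_bp = cfg.n_loci * cfg.base_spacing_bp + 1
    edges = {1, end_bp}
    for a, b, _ in hotspots:
        edges.update((a, b))
    edges = np.array(sorted(edges), dtype=float)
    rates = np.full(edges.size - 1, base_rate)
    for a, b, r in hotspots:
        rates[(edges[:-1] >= a) & (edges[1:] <= b)] = r
    cm = np.concatenate([[0.0], np.cumsum(rates * np.diff(edges) / 1e6)])
    gmap = GeneticMap(edges, cm)

    mid = float(edges[0] + (edges[-1] - edges[0]) / 2)
    rows = []
    for arm, lo, hi in (("p", edges[0], mid), ("q", mid, edges[-1])):
        w = np.clip(np.minimum(edges[1:], hi) - np.maximum(edges[:-1], lo), 0, None)
        avg = float((rates * w).sum() / w.sum())
        rows.append({"chromosome": cfg.chromosome, "arm": arm,
                     "start_bp": int(lo), "end_bp": int(hi), "cm_per_mb": avg})
    return gmap, ArmRateTable(pd.DataFrame(rows))


def panel_arm_rates(cfg, gm):
    """Arm-average rate table aligned with a simulated panel's arm labels."""
    pos = gm.positions
    arms = np.array([lc.arm for lc in gm.loci])
    rows = []
    for arm, rate in (("p", cfg.cm_per_mb_p), ("q", cfg.cm_per_mb_q)):
        sel = arms == arm
        if not sel.any():
            continue
        rows.append({"chromosome": cfg.chromosome, "arm": arm,
                     "start_bp": int(pos[sel].min()) if arm == "q" else 1,
                     "end_bp": int(pos[sel].max()) if arm == "q"
                     else int(pos[sel].max()),
                     "cm_per_mb": rate})
    # make arm intervals abut so every bp in between is covered
    if len(rows) == 2:
        rows[0]["end_bp"] = rows[1]["start_bp"] - 1
        rows[1]["end_bp"] = int(pos.max()) + 10 ** 9
    return ArmRateTable(pd.DataFrame(rows))


def truth_to_frame(truth):
    rows = []
    for f in truth.planted:
        rows.append({"feature": type(f).__name__,
                     "start_locus": f.start_locus, "end_locus": f.end_locus,
                     "detail": getattr(f, "sample_id",
                                       getattr(f, "frequency",
                                               getattr(f, "population", "")))})
    return pd.DataFrame(rows)
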