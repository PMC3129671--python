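# Methods

hzkit detects and quantifies **contiguous homozygosity** in dense diploid
SNP panels: runs of homozygous genotypes (ROH), their population-scale
summary statistics, locally extended haplotypes, candidate fixed regions,
population differentiation over those regions, and a two-group comparison
of segment-length distributions. This note documents the models,
parameters, numerical choices, and the synthetic study conditions behind
the validation suite.

## Segment detection

Detection is a four-stage heuristic, run per sample and chromosome:

1. **Basic runs.** Maximal runs of homozygous calls. Missing calls neither
   break a run nor count toward heterozygosity; they accumulate in the
   segment's no-call count (segments with a no-call rate above 5% are
   flagged `high_missing`, not deleted).
2. **Gap handling.** Runs are split at inter-SNP gaps larger than the
   lowest gap boundary, then rejoined when a gap-size-dependent rule
   allows: a gap in range *r* may be spanned if each flanking run is at
   least `min_flank_proportion[r] x gap` long and the joined span keeps
   `min_density_snp_per_kb[r]`. This lets a multi-megabase autozygous
   segment span a centromere while truncating short runs at gap edges. The
   lowest boundary is derived per chromosome as `exp(Q3 + 1.5 IQR)` of the
   natural-log inter-SNP gaps (the boxplot upper whisker on the log scale);
   the default ranges are `(<=250 kb: density 0.05/kb, proportion 0.1)`,
   `(<=1 Mb: 0.02, 0.5)`, `(<=5 Mb: 0.01, 1.0)`. These ranges are explicit
   configuration, not a claim about any other implementation's defaults.
3. **Heterozygote 'error' absorption.** Adjacent runs separated by
   isolated heterozygotes merge greedily left-to-right while the
   accumulated segment keeps `het_count / snp_count <= 1%`.
4. **Scan-ahead.** Greedy forward extension across heterogeneous gap/het
   structure: an extension is accepted when the overall 1% constraint and
   the scan gap rules hold; scanning stops once the window between the
   current segment end and the next candidate contains at least two
   heterozygotes at a proportion above 2%. Requiring two hets means a
   single isolated genotyping error can never abort the scan — the 1%
   overall rule still decides whether it is absorbed. Extension never
   retracts earlier joins, and proceeds left-to-right.

With single-range gap parameters and the scan window rule disabled, the
detector is extensionally equal to the exhaustive leftmost-maximal
enumeration under the 1% rule on fixtures of up to ~200 SNPs (tested
against an independent brute-force enumerator); beyond that size the
staged greedy construction can legitimately differ from global
maximality in rare het configurations.

## Segment statistics

* **HPS** (homozygosity probability score): the product of the per-locus
  observed homozygosity frequencies (`Freq_HOM`) across a segment's loci,
  computed in log space to avoid underflow. `HPS_ex` uses pooled
  frequencies across all populations; `HPS_in` the sample's own
  population. Pooling is what keeps population-restricted fixed regions
  visible: loci fixed in one population but polymorphic elsewhere still
  contribute factors well below 1. Segments with `HPS_ex <= 0.01` are the
  "unlikely by chance" set used downstream.
* **MISL**: per chromosome, the minimum over individuals of each
  individual's longest segment — a length threshold at which every
  individual still contributes.
* **ISLM**: samples x loci matrix holding, per cell, the length (bp or cM)
  of the sample's segment covering that locus. Built from HPS-filtered
  segments: without the filter, the non-zero column distributions are
  dominated by few-SNP chance runs, which distorts the percentile
  summaries and collapses the robust MAD denominator. cM lengths use
  chromosome-arm average recombination rates; arm-spanning segments are
  split proportionally by bp.
* **MAD score**: for the ISLVs under a segment (identical adjacent columns
  collapsed), the robust z-score `(L - median(ISLV_nz)) /
  (1.4826 * MAD(ISLV_nz))` over non-zero entries; the segment's score is
  the median over its representative columns. A zero raw MAD yields +inf
  above the median and 0 at/below it. Scores > 10 flag putative
  autozygosity for masking; the autozygosity *call* set additionally
  requires a founder-haplotype frequency of zero. The
  `(x - median)/(1.4826 MAD)` standardization is this package's
  formulation of the robust score (the threshold then reads as a robust
  z-score).
* **Founder haplotype frequency**: the homozygous allele string over the
  segment's loci, compared against the *other* phased haplotypes of the
  sample's population (the carrier's own two rows are excluded —
  otherwise a novel autozygous haplotype could never score zero). A panel
  haplotype matches when its mismatch count is at most `max(0.01 L, 1)`;
  missing panel alleles are excluded from the comparison.

## Extent statistics

* Putative autozygous segments (MAD > 10) are masked in the ISLM by
  capping their cells at the highest non-autozygous value in the same
  column; CNV/abnormality-masked segments instead contribute missing
  cells, which are dropped from all distributions.
* **PE_mat**: per population and locus, the 101 percentiles (0..100,
  linear-interpolation/type-7 definition) of the ISLV.
* **ext_AUC**: per locus, the ISLV is sign-reversed (so rare long segments
  lead the distribution), integration bounds are taken from the combined
  all-population vector (lower = most negative value, upper = the value
  closest to zero from below — the empty interval up to zero is excluded
  as noise), and the population's ECDF is integrated over those bounds.
  The integral is computed exactly as a step-function sum over the ECDF
  jump points (an adaptive-quadrature cross-check is kept as a test
  oracle). ext_AUC is zero iff the population has no positive ISLV mass in
  bounds, scales linearly with length units, and is invariant to sample
  order and duplication.
* **Rank values**: within each chromosome and population, ext_AUC values
  are mapped to their ECDF position `P(X <= x)`.

## Peaks

Tracks are smoothed with a cubic least-squares spline whose knot count is
3% of the loci (knots at position quantiles); peaks and valleys are the
derivative sign changes, with chromosome ends treated as valleys. The knot
count is the resolution control; no additional penalty is applied (on
noiseless tracks a cross-validated penalty tends to zero anyway, and on
real tracks the downstream merge/outlier steps absorb small ripples).
Features narrower than the knot spacing can ripple — unimodal recovery is
only guaranteed for features wider than the spacing.

Adjacent peaks merge when both the height difference and the rise from the
intervening valley are below 10% of the taller peak (iterated to a
fixpoint); outliers per chromosome and population are peaks above
`Q3 + 1.5 IQR` of merged-peak heights (at least four peaks required);
directly adjoining outlier peaks whose intervening valley exceeds half the
smaller height merge into peak regions. Denominator choices (max of the
heights for merging, min for region separation) are configurable design
decisions.

Per peak, the pairs `(Extent, Pr) = (PE_mat value, 1 - percentile/100)`
over the peak's loci are searched for the maximum `Extent x Pr`; ties
resolve toward larger Extent. `Freq_hap-exp = sqrt(p_max)` is the expected
frequency of a single underlying haplotype, and `Freq_hap-max` is the
largest founder-haplotype frequency among peak-intersecting segments with
genetic length at least `Extent_min` less a 1% tolerance — the tolerance
is the interpolation resolution of the 101-level quantile grid, which can
otherwise land marginally above the very lengths that define the optimum.

**Fixed areas (RCL_0)**: maximal runs of loci whose 0th-percentile extent
is positive — every individual of the population carries an overlapping
segment. Candidate areas additionally exceed the first quartile of run SNP
counts and extents (quartiles pooled across populations by default).

Peak recombination rates come from a genetic map by linear interpolation
over a window centred on the midpoint of the peak's upper-25% ext_AUC loci
with half-width of half the configured window fraction (default 0.5) of
the peak width; percentile ranks compare against rates tiled at the
nearest reference bin width (5 kb .. 10 Mb grid).

## Population differentiation

θ is the two-population Weir–Cockerham genotype-frequency moment estimator
(observed heterozygosity enters the `b` and `c` components; the `n_c` term
adjusts for unequal sample sizes), reported per locus as `a/(a+b+c)` and
aggregated as the ratio of sums. Negative estimates are kept as computed.
Differentiated peaks require a maximum ext_AUC rank of at least 0.90 in
both populations plus a mean θ above 0.0360 (autosomes) or 0.0538
(chromosome X) — plain configuration values; per-peak haplotype
frequencies are the average minor-allele-oriented frequencies across the
extreme-θ loci.

## Two-group comparison (AHA)

Per locus, the discrete two-sample Cramér–von Mises statistic
`ω² = Σ (F_A(x) - F_B(x))²` over the unique combined values (unweighted —
only the permutation calibration matters, not an asymptotic reference);
zero lengths are retained in the ECDFs, masked cells dropped. Significance
is a label-permutation test: `ASL = #{ω²_perm >= ω²_obs} / n_perm`
(a `+1` convention is available), vectorised over permutations and exactly
reproducible under a seed. A screening threshold can restrict permutation
to high-ω² loci.

## Synthetic data: the founder-mosaic model

The generator draws a pool of chromosome-length founder haplotypes
(default 8, Dirichlet(2) frequencies) and builds every chromosome copy as
a mosaic of founder blocks from a renewal process with a two-scale block
mixture (means 60 and 250 loci at 85%/15%) — the long component gives the
ISLV columns the continuous length dispersion real panels have. Homozygous
runs arise where a sample's two copies ride the same founder. Genotyping
error flips homozygotes to heterozygotes (default 0.1%), and calls go
missing at 1%. Inter-SNP spacing is 1 kb with occasional exponential gaps
(mean 30 kb at 0.2%), suppressed inside planted intervals so planted
features sit in uniformly assayed regions.

Planted features:

* **Autozygous tract** — one sample carries a novel haplotype on both
  copies (founder frequency zero by construction).
* **Extended haplotype** — carrier copies ride founder 0 across a core
  interval. Assignment is conditional on frequency: exactly `round(2nf)`
  carrier copies with the Hardy–Weinberg-expected homozygote count
  realized exactly, removing binomial noise from the planted truth. Most
  copies end sharply at the core edge; 15% decay geometrically (mean 150
  loci). One extra homozygote per population spans only an inner
  sub-interval (the frequency-graded core of a real extended haplotype),
  and carrier chromosome pairs recombine onto distinct backgrounds at
  their span boundaries so a homozygote's run cannot drift past the
  planted span on a shared background block.
* **Fixed region** — every copy (of one population, in the interesting
  case) rides founder 0 over the interval; founder alleles over the region
  and its two flanking loci are balanced, since population-restricted
  fixation is only observable where the pooled panel remains polymorphic.

What the generator does **not** emulate: recombination-driven LD decay,
demographic history, allele-frequency spectra, genotyping batch structure.
Passing the recovery experiments therefore demonstrates the machinery —
detection, masking, extent summaries, peak logic — under controlled block
structure, not performance on real panels.

## Validation study conditions

Two populations of 50 diploid samples, ~1 kb spacing, MAF > 0.05 QC,
20 seeds per experiment:

* tract: 2000 loci planted in one sample on a 3500-locus panel
  (recovered with >= 99% single-segment coverage, MAD > 10, founder
  frequency 0);
* extended haplotype: 1200-locus core at carrier frequency 0.3 or 0.6 on
  a 6000-locus panel (one outlier ext_AUC peak covering the planted
  midpoint; Freq_hap-max within ±0.05 of the planted frequency). The
  estimator's attainable ceiling is `(2nf - 2)/(2n - 2)` because a
  segment's own two haplotypes are excluded, so estimates centre slightly
  below f;
* fixed region: 80-locus population-restricted core on a 2500-locus
  clean panel (RCL_0 boundary error <= 1 post-QC SNP). The core is kept
  short because the 1% absorption budget grows with segment length: a
  long core legitimately accretes several SNPs of absorbed shoulder
  coverage, so SNP-exact boundary recovery is a property of short cores.
  The panel is simulated without genotyping error because the
  0th-percentile extent is a minimum over samples — any single miscalled
  genotype legitimately truncates the run, and sub-SNP boundary recovery
  is not a claim the method makes for noisy assays;
* θ calibration: two-deme Balding–Nichols island model at FST 0.1,
  5000 loci, ratio-of-averages estimate within ±0.02;
* AHA: type-I error at α = 0.05 within ±0.01 under the null (999
  permutations per locus); planted segment-length shifts localized by the
  genome-wide ω² argmax.

Problem sizes throughout were chosen so the full validation suite and the
acceptance script each run in a few minutes.

## Known limitations

* The staged detector is greedy; it does not globally maximise segment
  coverage under the het constraint (equivalence holds only at small
  scale).
* Arm-average cM conversion ignores fine-scale rate variation by design;
  fine maps enter only through peak recombination annotation.
* The boxplot outlier rule needs enough peaks per chromosome (>= 4) and
  sits close to the detectability limit for low-frequency extended
  haplotypes (carrier frequency ~0.3 is near the whisker at these panel
  sizes).
* θ cross-checks against an independently coded transcription of the same
  estimator, not a second estimator family; multi-population (k > 2)
  variance components are out of scope.
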