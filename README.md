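# hzkit

Detection, quantification and population comparison of **contiguous
homozygosity** in dense diploid SNP genotype panels.

Runs of homozygous genotypes (ROH) carry population-genetic signal at
every length scale: long runs mark autozygosity (both homologues inherited
from a recent common ancestor), intermediate runs mark extended haplotypes
at high frequency (a footprint of selection or drift), and runs shared by
*every* individual mark regions at or near fixation. hzkit implements a
complete toolchain for geneticists working with such panels:

* a four-stage heuristic **segment detector** — maximal homozygous runs
  with gap-aware joining (long autozygous segments may span centromeres,
  short runs truncate at gap edges) and a bounded heterozygote-'error'
  allowance (1% per segment, 2% scan-ahead window);
* **segment scores**: the homozygosity probability score
  HPS = Π Freq_HOM(locus) (external/pooled and within-population
  versions), the minimum inclusive segment length (MISL), a robust MAD
  score (x − median)/(1.4826·MAD) over intersecting-segment-length
  vectors for putative-autozygosity calling, and founder-haplotype
  frequencies from a phased panel (≤1% dissimilarity matching);
* **homozygous-extent statistics** over the samples × loci
  intersecting-segment-length matrix (ISLM): per-locus percentile-extent
  matrices (PE_mat) and ext_AUC — the exact area under the ECDF of the
  sign-reversed ISLV over its negative support;
* **peak analysis** of ext_AUC tracks: spline smoothing (knots = 3% of
  loci), derivative-sign peak delineation, 10% merge rules, boxplot
  outlier peaks and peak regions, per-peak haplotype parameters
  (Extent_min, p_max, Freq_hap-exp = √p_max, Freq_hap-max), RCL_0
  candidate fixed areas, and recombination-rate annotation;
* **population differentiation**: the two-population Weir–Cockerham
  genotype-frequency θ with unequal-sample-size correction, peak-level
  aggregation, and extraction of differentiated high-homozygosity peaks;
* **AHA** (agglomerative haplotype analysis): a per-locus two-sample
  Cramér–von Mises ω² on segment-length distributions with a seeded
  label-permutation significance procedure — the building block for
  homozygosity-based case-control comparisons;
* a **synthetic-data generator** (founder-mosaic model) that plants
  autozygous tracts, frequency-controlled extended haplotypes and fixed
  regions with recorded truth, used throughout the validation suite.

Genotypes are read from HapMap-style tab-delimited text or VCF; region
masks from BED; genetic maps and arm-rate tables from TSV. See
`docs/methods.md` for the full model description and the validation study
conditions.

## Worked example

Plant a 1.2-Mb autozygous tract in one sample of a two-population panel,
then detect and call it:

```python
import dataclasses
import numpy as np
from hzkit import SimConfig, simulate_panel, detect_segments, PlantedAutozygousTract
from hzkit.annotate import (annotate_hps, annotate_mad, annotate_founder_freq,
                            autozygous_calls, compute_misl)
from hzkit.extent import build_islm
from hzkit.genotypes import filter_maf

cfg = SimConfig(n_loci=3000, populations={"POPA": 30, "POPB": 30}, seed=4,
                planted=[PlantedAutozygousTract("POPA_000", 1000, 2199)])
gm, panel, truth = simulate_panel(cfg)
gm = filter_maf(gm, 0.05)
segset = detect_segments(gm)
annotate_hps(segset, gm)
misl = compute_misl(segset)
islm = build_islm(segset, gm, "bp")
annotate_mad(segset, islm)
keep = np.array([int(lc.id.removeprefix("rs")) - 1 for lc in gm.loci])
panel = dataclasses.replace(panel, haplotypes=panel.haplotypes[:, keep])
annotate_founder_freq(segset, gm, panel, predicate=lambda s: s.mad_score > 10)
for s in autozygous_calls(segset):
    print(f"autozygous call: {s.sample_id} {s.chromosome}:"
          f"{s.start_bp:,}-{s.end_bp:,} ({s.length_bp/1e6:.2f} Mb, "
          f"MAD={s.mad_score:.1f}, founder freq={s.founder_hap_freq})")
```

This prints:

```
autozygous call: POPA_000 1:930,001-2,210,221 (1.28 Mb, MAD=15.3, founder freq=0.0)
```

— the planted tract (1:1,004,221–2,203,221) recovered as a single
segment, extended slightly into the sample's own flanking background
homozygosity. The MAD score of 15.3 says the segment is ~15 robust
standard deviations longer than other samples' segments in the same
coordinates (threshold 10), and a founder-haplotype frequency of 0 means
no other phased haplotype in the population matches it — the signature of
autozygosity rather than a shared extended haplotype.

The same objects feed the rest of the chain (`extent.pe_mat`,
`extent.ext_auc`, `peaks.find_peaks`, `popdiff.locus_theta_track`,
`aha.scan_chromosome`), or run everything at once:

```sh
hzkit run --out results/ --seed 7            # full pipeline on a synthetic panel
hzkit detect --genotypes panel.txt --out segments.tsv
hzkit aha --islm-a A.tsv --islm-b B.tsv --perms 1000 --seed 7 --out aha.tsv
```

`hzkit run` writes per-stage TSVs (segments, MISL, coverage, PE matrices,
ext_AUC tracks, peaks, peak regions, fixed areas, θ, ω²) plus a
`manifest.json` with parameters and output hashes; two runs with the same
seed are byte-identical.

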