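"""Genotype data model, readers, and pre-detection QC filters.

Calls are coded as small integers: 0 = homozygous reference (first allele),
1 = heterozygous, 2 = homozygous alternate (second allele), 3 = missing.
Coordinates are 1-based inclusive throughout; BED input is converted on read.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

log = logging.getLogger("hzkit")

HOM_REF, HET, HOM_ALT, MISSING = 0, 1, 2, 3

#: columns preceding the sample genotypes in the HapMap text dialect
HAPMAP_META_COLS = [
    "rs#", "alleles", "chrom", "pos", "strand", "assembly#",
    "center", "protLSID", "assayLSID", "panelLSID", "QCcode",
]


@dataclass(frozen=True)
class LocusInfo:
    id: str
    chromosome: str
    position_bp: int
    alleles: tuple[str, str]
    arm: str = "p"

    def __post_init__(self):
        if self.position_bp < 1:
            raise ValueError(f"locus {self.id}: position_bp must be >= 1")
        if self.alleles[0] == self.alleles[1]:
            raise ValueError(f"locus {self.id}: alleles must be distinct")


@dataclass(frozen=True)
class SampleInfo:
    id: str
    population: str = "POP"
    sex: str = "unknown"


@dataclass
class RegionMask:
    """Interval masks: CNV gain/loss regions (with population frequency),
    immunoglobulin variable regions, and gross chromosomal abnormalities."""

    intervals: list = field(default_factory=list)  # (chrom, start, end, kind, freq)

    def add(self, chromosome, start_bp, end_bp, kind, cnv_frequency=0.0):
        if start_bp > end_bp:
            raise ValueError("mask interval start > end")
        if not 0.0 <= cnv_frequency <= 1.0:
            raise ValueError("cnv_frequency outside [0,1]")
        if kind not in {"cnv", "igv", "abnormality"}:
            raise ValueError(f"unknown mask kind {kind!r}")
        self.intervals.append((str(chromosome), int(start_bp), int(end_bp), kind,
                               float(cnv_frequency)))

    @classmethod
    def from_bed(cls, path, kind="cnv"):
        """Read a BED file (0-based half-open) into 1-based inclusive intervals.

        Column 5 (score), when present, is interpreted as the CNV population
        frequency in [0,1].
        """
        mask = cls()
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith(("track", "browser", "#")):
                    continue
                parts = line.split("\t")
                chrom, start, end = parts[0], int(parts[1]) + 1, int(parts[2])
                freq = float(parts[4]) if len(parts) > 4 and kind == "cnv" else 0.0
                k = parts[3] if len(parts) > 3 and parts[3] in {"cnv", "igv", "abnormality"} else kind
                mask.add(chrom, start, end, k, freq)
        return mask


class GenotypeMatrix:
    """samples x loci diploid calls plus locus / sample metadata.

    ``calls`` is uint8 over {0,1,2,3}; loci are strictly ordered by
    (chromosome, position) with unique positions per chromosome.
    """

    def __init__(self, calls, loci, samples, validate=True):
        self.calls = np.asarray(calls, dtype=np.uint8)
        self.loci = list(loci)
        self.samples = list(samples)
        if validate:
            self._validate()

    def _validate(self):
        n_s, n_l = self.calls.shape
        if n_s != len(self.samples) or n_l != len(self.loci):
            raise ValueError("calls shape inconsistent with loci/samples")
        if self.calls.size and self.calls.max() > 3:
            raise ValueError("call values must be in {0,1,2,3}")
        ids = [s.id for s in self.samples]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate sample ids")
        prev = None
        for lc in self.loci:
            key = (lc.chromosome, lc.position_bp)
            if prev is not None and prev[0] == key[0] and prev[1] >= key[1]:
                raise ValueError(
                    f"loci not strictly ordered at {lc.chromosome}:{lc.position_bp}")
            prev = key

    # -- basic accessors -------------------------------------------------
    @property
    def n_samples(self):
        return self.calls.shape[0]

    @property
    def n_loci(self):
        return self.calls.shape[1]

    @property
    def positions(self):
        return np.array([lc.position_bp for lc in self.loci], dtype=np.int64)

    @property
    def chromosomes(self):
        return np.array([lc.chromosome for lc in self.loci])

    def sample_index(self, population=None):
        """Row indices, optionally restricted to one population."""
        if population is None:
            return np.arange(self.n_samples)
        return np.array([i for i, s in enumerate(self.samples)
                         if s.population == population], dtype=int)

    def populations(self):
        return sorted({s.population for s in self.samples})

    def subset_loci(self, keep_idx):
        keep_idx = np.asarray(keep_idx, dtype=int)
        return GenotypeMatrix(self.calls[:, keep_idx],
                              [self.loci[i] for i in keep_idx],
                              self.samples, validate=False)

    def chromosome_slice(self, chromosome):
        idx = np.where(self.chromosomes == str(chromosome))[0]
        return idx

    def loci_frame(self):
        return pd.DataFrame({
            "id": [lc.id for lc in self.loci],
            "chromosome": [lc.chromosome for lc in self.loci],
            "position_bp": [lc.position_bp for lc in self.loci],
            "allele_a": [lc.alleles[0] for lc in self.loci],
            "allele_b": [lc.alleles[1] for lc in self.loci],
            "arm": [lc.arm for lc in self.loci],
        })


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def _chrom_sort_key(c):
    c = str(c).removeprefix("chr")
    return (0, int(c)) if c.isdigit() else (1, c)


def read_genotypes(path, format="hapmap_txt", sample_populations=None):
    """Read a genotype panel from HapMap-style text or VCF.

    Multi-allelic and indel records are skipped (count logged). Loci are
    sorted by (chromosome, position); duplicate positions on a chromosome
    raise a validation error.
    """
    if format == "hapmap_txt":
        gm = _read_hapmap_txt(path, sample_populations)
    elif format == "vcf":
        gm = _read_vcf(path, sample_populations)
    else:
        raise ValueError(f"unknown format {format!r}")
    return gm


def _finalise(records, samples):
    """records: list of (LocusInfo, call_vector). Sort, check duplicates."""
    records.sort(key=lambda r: (_chrom_sort_key(r[0].chromosome), r[0].position_bp))
    seen = set()
    for lc, _ in records:
        key = (lc.chromosome, lc.position_bp)
        if key in seen:
            raise ValueError(f"duplicate position {lc.chromosome}:{lc.position_bp}")
        seen.add(key)
    if records:
        calls = np.stack([v for _, v in records], axis=1)
    else:
        calls = np.zeros((len(samples), 0), dtype=np.uint8)
    return GenotypeMatrix(calls, [lc for lc, _ in records], samples, validate=False)


def _read_hapmap_txt(path, sample_populations=None):
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:4] != ["rs#", "alleles", "chrom", "pos"]:
            raise ValueError(f"{path}: not a HapMap genotype header")
        n_meta = len(HAPMAP_META_COLS) if header[:11] == HAPMAP_META_COLS else 5
        sample_ids = header[n_meta:]
        records, n_skipped = [], 0
        for ln, line in enumerate(fh, start=2):
            parts = line.rstrip("\n").split("\t")
            if len(parts) != n_meta + len(sample_ids):
                raise ValueError(f"{path}:{ln}: malformed record "
                                 f"({len(parts)} fields)")
            rsid, alleles, chrom, pos = parts[0], parts[1], parts[2], int(parts[3])
            al = alleles.split("/")
            if len(al) != 2 or any(len(a) != 1 for a in al):
                n_skipped += 1
                continue
            a, b = al
            vec = np.empty(len(sample_ids), dtype=np.uint8)
            bad = 0
            for i, g in enumerate(parts[n_meta:]):
                if g == a + a:
                    vec[i] = HOM_REF
                elif g == b + b:
                    vec[i] = HOM_ALT
                elif g in (a + b, b + a):
                    vec[i] = HET
                else:
                    if g != "NN":
                        bad += 1
                    vec[i] = MISSING
            if bad:
                log.warning("%s:%d: %d non-allele genotype tokens mapped to missing",
                            path, ln, bad)
            records.append((LocusInfo(rsid, chrom, pos, (a, b)), vec))
    if n_skipped:
        log.info("%s: skipped %d non-biallelic-SNP records", path, n_skipped)
    pops = sample_populations or {}
    samples = [SampleInfo(s, pops.get(s, "POP")) for s in sample_ids]
    return _finalise(records, samples)


def _read_vcf(path, sample_populations=None):
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)  # gt_types: 0 homref,1 het,2 homalt,3 unknown
    sample_ids = list(vcf.samples)
    records, n_skipped = [], 0
    for var in vcf:
        if len(var.ALT) != 1 or not var.is_snp:
            n_skipped += 1
            continue
        vec = var.gt_types.astype(np.uint8)  # already matches our coding
        lc = LocusInfo(var.ID or f"{var.CHROM}:{var.POS}", var.CHROM, var.POS,
                       (var.REF, var.ALT[0]))
        records.append((lc, vec))
    if n_skipped:
        log.info("%s: skipped %d multi-allelic/indel records", path, n_skipped)
    pops = sample_populations or {}
    samples = [SampleInfo(s, pops.get(s, "POP")) for s in sample_ids]
    return _finalise(records, samples)


def write_hapmap_txt(gm, path):
    """Write the HapMap-style tab-delimited genotype dialect read back by
    :func:`read_genotypes`."""
    sym = {HOM_REF: lambda a, b: a + a, HET: lambda a, b: a + b,
           HOM_ALT: lambda a, b: b + b, MISSING: lambda a, b: "NN"}
    with open(path, "w") as fh:
        fh.write("\t".join(HAPMAP_META_COLS + [s.id for s in gm.samples]) + "\n")
        for j, lc in enumerate(gm.loci):
            a, b = lc.alleles
            meta = [lc.id, f"{a}/{b}", lc.chromosome, str(lc.position_bp),
                    "+", "ncbi", "hzkit", "-", "-", "-", "QC+"]
            row = [sym[int(c)](a, b) for c in gm.calls[:, j]]
            fh.write("\t".join(meta + row) + "\n")


def write_vcf(gm, path):
    """Write a minimal uncompressed VCF v4.2 with GT fields only."""
    gt = {HOM_REF: "0/0", HET: "0/1", HOM_ALT: "1/1", MISSING: "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in dict.fromkeys(lc.chromosome for lc in gm.loci):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(s.id for s in gm.samples) + "\n")
        for j, lc in enumerate(gm.loci):
            row = [lc.chromosome, str(lc.position_bp), lc.id,
                   lc.alleles[0], lc.alleles[1], ".", "PASS", ".", "GT"]
            row += [gt[int(c)] for c in gm.calls[:, j]]
            fh.write("\t".join(row) + "\n")


# ---------------------------------------------------------------------------
# QC filters
# ---------------------------------------------------------------------------

def locus_maf(gm):
    """Pooled minor-allele frequency per locus from non-missing calls."""
    calls = gm.calls
    n_ref = (calls == HOM_REF).sum(axis=0)
    n_het = (calls == HET).sum(axis=0)
    n_alt = (calls == HOM_ALT).sum(axis=0)
    n_called = n_ref + n_het + n_alt
    with np.errstate(invalid="ignore", divide="ignore"):
        p_alt = (2 * n_alt + n_het) / (2 * n_called)
    maf = np.minimum(p_alt, 1.0 - p_alt)
    maf[n_called == 0] = np.nan
    return maf


def filter_maf(gm, min_maf=0.05):
    """Remove loci with pooled MAF <= ``min_maf`` (and zero-call loci)."""
    if not 0.0 <= min_maf <= 0.5:
        raise ValueError("min_maf must be in [0, 0.5]")
    maf = locus_maf(gm)
    n_nan = int(np.isnan(maf).sum())
    if n_nan:
        log.info("filter_maf: %d loci with zero non-missing calls removed", n_nan)
    keep = np.where(np.nan_to_num(maf, nan=-1.0) > min_maf)[0]
    return gm.subset_loci(keep)


def hwe_exact_test(n_hom_ref, n_het, n_hom_alt):
    """Two-sided exact test of Hardy-Weinberg equilibrium.

    Wigginton-Cutler-Abecasis formulation: conditional on the allele counts,
    sum the probabilities of all heterozygote counts whose conditional
    probability does not exceed that of the observed count.
    """
    a, b, c = int(n_hom_ref), int(n_het), int(n_hom_alt)
    if a < 0 or b < 0 or c < 0 or a + b + c < 1:
        raise ValueError("genotype counts must be non-negative with sum >= 1")
    n = a + b + c
    n_rare = 2 * min(a, c) + b  # rare-allele count
    # het counts share the parity of the rare-allele count
    hets = range(n_rare % 2, min(n_rare, 2 * n - n_rare) + 1, 2)
    # log conditional probability up to a constant
    lg = math.lgamma

    def logp(h):
        hom_r = (n_rare - h) // 2
        hom_c = n - hom_r - h
        return (h * math.log(2) - lg(h + 1) - lg(hom_r + 1) - lg(hom_c + 1))

    lps = np.array([logp(h) for h in hets])
    probs = np.exp(lps - lps.max())
    probs /= probs.sum()
    obs = list(hets).index(b)
    return float(min(1.0, probs[probs <= probs[obs] * (1 + 1e-12)].sum()))


def hwe_pvalues(gm):
    """Per-locus HWE exact p-values (pooled genotype counts)."""
    calls = gm.calls
    n_ref = (calls == HOM_REF).sum(axis=0)
    n_het = (calls == HET).sum(axis=0)
    n_alt = (calls == HOM_ALT).sum(axis=0)
    out = np.ones(gm.n_loci)
    for j in range(gm.n_loci):
        if n_ref[j] + n_het[j] + n_alt[j] >= 1:
            out[j] = hwe_exact_test(n_ref[j], n_het[j], n_alt[j])
    return out


def filter_hwe(gm, max_p=1e-6):
    """Remove loci failing HWE at ``p < max_p`` (default 1e-6)."""
    p = hwe_pvalues(gm)
    keep = np.where(p >= max_p)[0]
    if len(keep) < gm.n_loci:
        log.info("filter_hwe: removed %d loci at p < %g", gm.n_loci - len(keep), max_p)
    return gm.subset_loci(keep)


def apply_region_mask(gm, mask, cnv_freq_threshold=0.05):
    """Drop loci inside immunoglobulin / abnormality intervals or inside CNV
    intervals whose population frequency is >= ``cnv_freq_threshold``."""
    if not mask.intervals:
        return gm
    chroms = gm.chromosomes
    pos = gm.positions
    drop = np.zeros(gm.n_loci, dtype=bool)
    counts = {"cnv": 0, "igv": 0, "abnormality": 0}
    for chrom, start, end, kind, freq in mask.intervals:
        if kind == "cnv" and freq < cnv_freq_threshold:
            continue
        hit = (chroms == chrom) & (pos >= start) & (pos <= end)
        counts[kind] += int((hit & ~drop).sum())
        drop |= hit
    for kind, n in counts.items():
        if n:
            log.info("apply_region_mask: removed %d loci (%s)", n, kind)
    return gm.subset_loci(np.where(~drop)[0])


def compute_freq_hom(gm, scope="pooled"):
    """Per-locus fraction of non-missing calls that are homozygous.

    ``pooled`` returns one vector over all samples (basis of HPS_ex);
    ``per_population`` returns a dict of vectors (basis of HPS_in). Loci with
    no calls in scope are NaN.
    """
    def _freq(rows):
        calls = gm.calls[rows]
        hom = ((calls == HOM_REF) | (calls == HOM_ALT)).sum(axis=0)
        called = (calls != MISSING).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            f = hom / called
        f = np.asarray(f, dtype=float)
        f[called == 0] = np.nan
        return f

    if scope == "pooled":
        return _freq(np.arange(gm.n_samples))
    if scope == "per_population":
        return {p: _freq(gm.sample_index(p)) for p in gm.populations()}
    raise ValueError(f"unknown scope {scope!r}")


def qc_report(gm, mask=None, cnv_freq_threshold=0.05):
    """Per-locus QC table: MAF, HWE p, mask flags. Returned as a DataFrame."""
    df = gm.loci_frame()
    df["maf"] = locus_maf(gm)
    df["hwe_p"] = hwe_pvalues(gm)
    flag = np.array([""] * gm.n_loci, dtype=object)
    if mask is not None:
        chroms, pos = gm.chromosomes, gm.positions
        for chrom, start, end, kind, freq in mask.intervals:
            if kind == "cnv" and freq < cnv_freq_threshold:
                continue
            hit = (chroms == chrom) & (pos >= start) & (pos <= end)
            flag[hit] = np.where(flag[hit] == "", kind, flag[hit] + ";" + kind)
    df["mask_flags"] = flag
    return df
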