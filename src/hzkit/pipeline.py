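"""End-to-end orchestration: QC -> detection -> annotation -> extent ->
peaks -> differentiation -> AHA, with TSV outputs and a provenance manifest.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import aha as aha_mod
from . import annotate, detect, extent, genotypes, peaks as peaks_mod, popdiff
from .synth import SimConfig, panel_arm_rates, simulate_panel

log = logging.getLogger("hzkit")


@dataclass
class PipelineConfig:
    genotype_path: str | None = None
    genotype_format: str = "hapmap_txt"
    sample_populations: dict = field(default_factory=dict)
    mask_bed: str | None = None
    arm_rates_tsv: str | None = None   # chromosome-arm cM/Mb table
    sim: SimConfig | None = None          # used when genotype_path is None
    min_maf: float = 0.05
    hwe_max_p: float = 1e-6
    cnv_freq_threshold: float = 0.05
    detection: detect.DetectionParams = field(default_factory=detect.DetectionParams)
    max_hps_ex: float = 0.01
    mad_threshold: float = 10.0
    peak_merge_tolerance: float = 0.10
    fst_rank_min: float = 0.90
    aha_n_perm: int = 200
    aha_screen_omega2: float | None = None
    seed: int = 0

    @classmethod
    def from_json(cls, path):
        with open(path) as fh:
            raw = json.load(fh)
        if "detection" in raw:
            det = raw.pop("detection")
            rules = [detect.GapRule(**r) for r in det.pop("gap_rules", [])]
            params = detect.DetectionParams(**det)
            if rules:
                params.gap_width_scan_thresholds = tuple(rules)
                params.gap_width_join_thresholds = tuple(rules)
            raw["detection"] = params
        if "sim" in raw and raw["sim"] is not None:
            raw["sim"] = SimConfig(**raw["sim"])
        return cls(**raw)


@dataclass
class PipelineResult:
    gm: object
    segset: object
    misl: object
    islm_bp: object
    islm_cm: object
    islm_bp_masked: object
    islm_cm_masked: object
    pemats: dict
    tracks: dict
    peaks: dict
    regions: dict
    fixed_areas: list
    fixed_candidates: list
    theta: np.ndarray
    differentiated: list
    aha_results: list
    coverage: pd.DataFrame
    panel: object = None
    truth: object = None


def run_pipeline(cfg, outdir=None):
    """Execute every stage in order; optionally write TSV outputs and a
    provenance manifest to ``outdir``. Deterministic for a fixed config."""
    # --- stage: inputs ---------------------------------------------------
    panel = truth = None
    if cfg.genotype_path is not None:
        gm = genotypes.read_genotypes(cfg.genotype_path, cfg.genotype_format,
                                      cfg.sample_populations)
        arm_rates = (extent.ArmRateTable.read_tsv(cfg.arm_rates_tsv)
                     if cfg.arm_rates_tsv else None)
    else:
        sim = cfg.sim or SimConfig(seed=cfg.seed)
        gm, panel, truth = simulate_panel(sim)
        arm_rates = panel_arm_rates(sim, gm)
    _stage("inputs", f"{gm.n_samples} samples x {gm.n_loci} loci")

    # --- stage: qc -------------------------------------------------------
    n0 = gm.n_loci
    gm = genotypes.filter_maf(gm, cfg.min_maf)
    gm = genotypes.filter_hwe(gm, cfg.hwe_max_p)
    if cfg.mask_bed:
        mask = genotypes.RegionMask.from_bed(cfg.mask_bed)
        gm = genotypes.apply_region_mask(gm, mask, cfg.cnv_freq_threshold)
    else:
        mask = None
    if panel is not None:
        # keep the phased panel aligned with surviving loci
        keep = _surviving_loci(panel, gm)
        panel = dataclasses.replace(panel, haplotypes=panel.haplotypes[:, keep])
    _stage("qc", f"{n0} -> {gm.n_loci} loci")

    # --- stage: detect ---------------------------------------------------
    segset = detect.detect_segments(gm, cfg.detection, mask)
    _stage("detect", f"{len(segset.segments)} segments")
    if not segset.segments:
        raise RuntimeError("stage detect: no segments found")

    # --- stage: annotate -------------------------------------------------
    annotate.annotate_hps(segset, gm)
    misl = annotate.compute_misl(segset)
    islm_bp = extent.build_islm(segset, gm, "bp", max_hps_ex=cfg.max_hps_ex)
    annotate.annotate_mad(segset, islm_bp)
    if panel is not None:
        annotate.annotate_founder_freq(segset, gm, panel)
    coverage = annotate.coverage_curves(segset, gm, max_hps_ex=cfg.max_hps_ex,
                                        min_density=cfg.detection.min_snp_density)
    _stage("annotate", f"MISL_gw={misl.misl_gw}")

    # --- stage: extent ---------------------------------------------------
    if arm_rates is not None:
        islm_cm = extent.build_islm(segset, gm, "cM", arm_rates,
                                    max_hps_ex=cfg.max_hps_ex)
    else:
        islm_cm = islm_bp
    islm_bp_m = extent.mask_islm_autozygous(islm_bp, segset, cfg.mad_threshold)
    islm_cm_m = extent.mask_islm_autozygous(islm_cm, segset, cfg.mad_threshold)
    pops = gm.populations()
    pemats = {p: extent.pe_mat(islm_cm_m, p) for p in pops}
    tracks = {p: extent.ext_auc_rank(extent.ext_auc(islm_cm_m, p)) for p in pops}
    _stage("extent", f"{len(pops)} populations")

    # --- stage: peaks ----------------------------------------------------
    peak_map, region_map = {}, {}
    for p in pops:
        pk = peaks_mod.find_peaks(tracks[p], cfg.peak_merge_tolerance)
        for q in pk:
            peaks_mod.peak_haplotype_params(q, pemats[p], segset.segments)
            peaks_mod.cross_population_rank(q, tracks)
        peak_map[p] = pk
        region_map[p] = peaks_mod.merge_outlier_regions(
            [q for q in pk if q.outlier])
    fixed_all, fixed_cand = peaks_mod.detect_fixed_areas(list(pemats.values()))
    _stage("peaks", f"{sum(len(v) for v in peak_map.values())} merged peaks")

    # --- stage: differentiation -------------------------------------------
    theta = np.full(gm.n_loci, np.nan)
    differentiated = []
    if len(pops) >= 2:
        pa, pb = pops[0], pops[1]
        theta, _, _ = popdiff.locus_theta_track(gm, pa, pb)
        for p in (pa, pb):
            for q in peak_map[p]:
                other = pb if p == pa else pa
                q.fst_mean[other] = popdiff.peak_fst(q, theta, None)
        differentiated = popdiff.differentiated_peaks(
            peak_map[pa], peak_map[pb], tracks, gm, pa, pb, cfg.fst_rank_min)
    _stage("fst", f"{len(differentiated)} differentiated peaks")

    # --- stage: aha --------------------------------------------------------
    aha_results = []
    if len(pops) >= 2:
        ra = islm_cm_m.rows_for_population(pops[0])
        rb = islm_cm_m.rows_for_population(pops[1])
        aha_results = aha_mod.scan_chromosome(
            islm_cm_m.values[ra], islm_cm_m.values[rb],
            n_perm=cfg.aha_n_perm, seed=cfg.seed,
            screen_omega2=cfg.aha_screen_omega2,
            locus_ids=[lc.id for lc in gm.loci])
    _stage("aha", f"{len(aha_results)} loci scanned")

    result = PipelineResult(
        gm=gm, segset=segset, misl=misl,
        islm_bp=islm_bp, islm_cm=islm_cm,
        islm_bp_masked=islm_bp_m, islm_cm_masked=islm_cm_m,
        pemats=pemats, tracks=tracks, peaks=peak_map, regions=region_map,
        fixed_areas=fixed_all, fixed_candidates=fixed_cand,
        theta=theta, differentiated=differentiated, aha_results=aha_results,
        coverage=coverage, panel=panel, truth=truth)
    if outdir is not None:
        write_outputs(result, cfg, Path(outdir))
    return result


def _surviving_loci(panel, gm):
    # loci ids are unique within the simulated panel; map by id index
    return np.array([int(lc.id.removeprefix("rs")) - 1 for lc in gm.loci])


def _stage(name, msg):
    log.info("stage %-9s %s", name, msg)


def write_outputs(result, cfg, outdir):
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    detect.write_segments_tsv(result.segset, outdir / "segments.tsv")
    result.misl.to_frame().to_csv(outdir / "misl.tsv", sep="\t", index=False)
    result.coverage.to_csv(outdir / "coverage.tsv", sep="\t", index=False)
    for pop in sorted(result.pemats):
        result.pemats[pop].to_frame().to_csv(
            outdir / f"pemat_{pop}.tsv", sep="\t", index=False)
        result.tracks[pop].to_frame().to_csv(
            outdir / f"extauc_{pop}.tsv", sep="\t", index=False)
        peaks_mod.peaks_to_frame(result.peaks[pop]).to_csv(
            outdir / f"peaks_{pop}.tsv", sep="\t", index=False)
        pd.DataFrame([{
            "chromosome": r.chromosome, "start_bp": r.start_bp,
            "end_bp": r.end_bp, "n_peaks": len(r.members),
            "max_height": r.max_height,
        } for r in result.regions[pop]]).to_csv(
            outdir / f"peak_regions_{pop}.tsv", sep="\t", index=False)
    pd.DataFrame([{
        "population": r.population, "chromosome": r.chromosome,
        "start_bp": r.start_bp, "end_bp": r.end_bp,
        "snp_count": r.snp_count, "extent": r.extent,
        "candidate": r in result.fixed_candidates,
    } for r in result.fixed_areas]).to_csv(
        outdir / "fixed_areas.tsv", sep="\t", index=False)
    popdiff.theta_to_frame(result.gm, result.theta).to_csv(
        outdir / "theta.tsv", sep="\t", index=False)
    aha_mod.results_to_frame(result.aha_results,
                             result.gm.positions if result.aha_results else None
                             ).to_csv(outdir / "aha.tsv", sep="\t", index=False)
    manifest = {
        "package": "hzkit",
        "seed": cfg.seed,
        "params": _jsonable(cfg),
        "n_samples": result.gm.n_samples,
        "n_loci": result.gm.n_loci,
        "dataset_hash": result.segset.dataset_hash,
        "output_hashes": {p.name: _sha1(p) for p in sorted(outdir.glob("*.tsv"))},
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)


def _sha1(path):
    return hashlib.sha1(Path(path).read_bytes()).hexdigest()


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    if isinstance(obj, (str, int, float, bool)) or obj is None:
        return obj
    return str(obj)
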