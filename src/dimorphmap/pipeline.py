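"""End-to-end replay of the dimorphism analysis chain on synthetic data.

Stages mirror the analysis sequence of a longitudinal morphometry study:
simulate -> structure tests -> voxel-wise mapping -> age-centered maps ->
trajectory clustering -> expression enrichment -> individualization ->
cortical thickness -> report.  Every stage reads its inputs from, and
writes its outputs to, declared files inside the run directory, so any
stage can be re-run in isolation; the config (seeds included) is
serialized alongside, making identical configs reproduce identical
outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import (dimorphism, expression, individualization, simulate,
               thickness, trajectories, volumes)

log = logging.getLogger("dimorphmap")

__all__ = ["RunConfig", "run_pipeline", "STAGES"]


@dataclasses.dataclass
class RunConfig:
    seed: int = 0
    outdir: str = "dimorphmap_run"
    n_per_sex: int = 14
    grid_shape: tuple = (24, 24, 24)
    amplitude: float = 0.06
    sigma_mouse: float = 0.015
    sigma_noise: float = 0.015
    dropout_rate: float = 0.05
    q_threshold: float = 0.1
    k_clusters: int = 4
    n_genes: int = 200
    n_perm: int = 1000
    target_time: float = 36.0
    stages: tuple = ("simulate", "structure", "voxel", "cluster", "enrich",
                     "individualize", "thickness", "report")
    growth_model: str = "linear"
    time_coding: str = "actual"
    random_slope: bool = False

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "grid_shape" in raw:
            raw["grid_shape"] = tuple(raw["grid_shape"])
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        return cls(**raw)

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        d["grid_shape"] = list(self.grid_shape)
        d["stages"] = list(self.stages)
        return json.dumps(d, indent=2, sort_keys=True)


def _cohort_config(cfg: RunConfig) -> simulate.CohortConfig:
    return simulate.CohortConfig(
        n_per_sex=cfg.n_per_sex, sigma_mouse=cfg.sigma_mouse,
        sigma_noise=cfg.sigma_noise, dropout_rate=cfg.dropout_rate, seed=cfg.seed,
    )


def _archetypes_with_rois(cfg: RunConfig):
    archs = simulate.default_archetypes(amplitude=cfg.amplitude)
    g = cfg.grid_shape
    c = g[0] // 2
    b = max(2, g[0] // 8)  # ROI box edge, scaled to the grid
    lo, hi = c - b - 1, c + 1
    corners = [(lo, lo, lo), (hi, lo, lo), (lo, hi, lo), (lo, lo, hi)]
    for arch, corner in zip(archs, corners):
        arch.roi = simulate.box_roi(g, corner, (b, b, b))
    return archs


def stage_simulate(cfg: RunConfig, outdir: Path) -> None:
    cc = _cohort_config(cfg)
    archs = _archetypes_with_rois(cfg)
    table = simulate.generate_cohort(cc, archs)
    volumes.write_volume_table(table, outdir / "cohort.csv")
    fields, atlas = simulate.generate_determinant_fields(
        cc, grid_shape=cfg.grid_shape, archetypes=archs)
    volumes.write_atlas(atlas, outdir / "atlas.nii.gz", outdir / "atlas_names.tsv")
    fdir = outdir / "fields"
    fdir.mkdir(exist_ok=True)
    manifest = []
    for i, f in enumerate(fields):
        name = f"scan{i:04d}_{f.kind}.nii.gz"
        volumes.write_field(f, fdir / name)
        manifest.append(name)
    (outdir / "fields_manifest.json").write_text(json.dumps(manifest))


def _load_fields(outdir: Path, kind: str):
    names = json.loads((outdir / "fields_manifest.json").read_text())
    fields = [volumes.read_field(outdir / "fields" / n) for n in names]
    return [f for f in fields if f.kind == kind]


def stage_structure(cfg: RunConfig, outdir: Path) -> None:
    table = volumes.read_volume_table(outdir / "cohort.csv")
    rows = []
    for structure in sorted(table["structure"].unique()):
        for response in ("absolute", "relative"):
            res = dimorphism.structure_sex_test(table, structure, response)
            timing = dimorphism.earliest_dimorphic_timepoint(table, structure, response)
            rows.append((structure, response, res.lrt.statistic, res.lrt.df,
                         res.lrt.pvalue, timing.earliest_age))
    out = pd.DataFrame(rows, columns=["structure", "response", "lrt_stat",
                                      "df", "pvalue", "earliest_age"])
    from .mixedlm import fdr_bh

    # q-values are computed within each response family
    qs = np.empty(len(out))
    for r in ("absolute", "relative"):
        m = (out["response"] == r).to_numpy()
        qs[m] = fdr_bh(out.loc[m, "pvalue"].to_numpy())
    out["qvalue"] = qs
    out.to_csv(outdir / "structure_tests.csv", index=False)


def stage_voxel(cfg: RunConfig, outdir: Path) -> None:
    import nibabel as nib

    fields = _load_fields(outdir, "relative")
    atlas = volumes.read_atlas(outdir / "atlas.nii.gz", outdir / "atlas_names.tsv")
    vmap = dimorphism.voxelwise_sex_test(
        fields, mask=atlas.brain_mask, time_coding=cfg.time_coding,
        growth=cfg.growth_model, random_slope=cfg.random_slope)
    aff = np.eye(4)
    for name, arr in (("stat", vmap.statistic), ("p", vmap.pvalues), ("q", vmap.qvalues)):
        nib.save(nib.Nifti1Image(arr, aff), str(outdir / f"voxel_{name}.nii.gz"))
    sig = vmap.significant(cfg.q_threshold)
    summary = {"n_voxels": int(vmap.mask.sum()),
               "n_significant": int(sig.sum()),
               "n_failed": vmap.n_failed,
               "df": vmap.df, "model": vmap.model}
    (outdir / "voxel_summary.json").write_text(json.dumps(summary, indent=2))


def stage_cluster(cfg: RunConfig, outdir: Path) -> None:
    import nibabel as nib

    fields = _load_fields(outdir, "relative")
    q = np.asarray(nib.load(str(outdir / "voxel_q.nii.gz")).dataobj)
    sig = np.nan_to_num(q, nan=np.inf) < cfg.q_threshold
    summary = {"n_dimorphic": int(sig.sum())}
    if sig.sum() < cfg.k_clusters:
        summary["status"] = "too few dimorphic voxels to cluster"
        (outdir / "cluster_summary.json").write_text(json.dumps(summary, indent=2))
        return
    mat = trajectories.effect_size_matrix(fields, sig)
    res = trajectories.cluster_trajectories(mat, k=cfg.k_clusters, seed=cfg.seed)
    labels = np.zeros(sig.shape, dtype=np.int32)
    labels[tuple(mat.voxel_coords.T)] = res.labels
    nib.save(nib.Nifti1Image(labels, np.eye(4)), str(outdir / "cluster_labels.nii.gz"))
    cent = pd.DataFrame(res.centroids, columns=[f"d_p{int(a)}" for a in mat.ages])
    cent.insert(0, "cluster", np.arange(1, cfg.k_clusters + 1))
    cent.to_csv(outdir / "cluster_centroids.csv", index=False)
    # growth-rate summaries over (a deterministic subsample of) member voxels
    growth_mask = sig.copy()
    if sig.sum() > 600:
        coords = np.argwhere(sig)[::int(np.ceil(sig.sum() / 600))]
        growth_mask = np.zeros_like(sig)
        growth_mask[tuple(coords.T)] = True
    growth = trajectories.growth_rate_curves(fields, growth_mask)
    sub = growth_mask[sig]  # member voxels retained in the growth subsample
    sub_matrix = trajectories.EffectSizeMatrix(
        values=mat.values[sub], ages=mat.ages, voxel_coords=mat.voxel_coords[sub])
    sub_result = trajectories.ClusterResult(
        labels=res.labels[sub], centroids=res.centroids,
        inertia=res.inertia, wss_curve=res.wss_curve)
    summ = trajectories.cluster_summaries(sub_result, sub_matrix, growth, fields)
    summ.volume_effect.to_csv(outdir / "cluster_volume_effect.csv", index=False)
    summ.growth_effect.to_csv(outdir / "cluster_growth_effect.csv", index=False)
    summ.per_subject.to_csv(outdir / "cluster_per_subject.csv", index=False)
    summary["wss_curve"] = res.wss_curve
    (outdir / "cluster_summary.json").write_text(json.dumps(summary, indent=2))


def stage_enrich(cfg: RunConfig, outdir: Path) -> None:
    import nibabel as nib

    atlas = volumes.read_atlas(outdir / "atlas.nii.gz", outdir / "atlas_names.tsv")
    qpath = outdir / "voxel_q.nii.gz"
    if qpath.exists():
        q = np.asarray(nib.load(str(qpath)).dataobj)
        roi = np.nan_to_num(q, nan=np.inf) < cfg.q_threshold
    else:
        roi = np.zeros(atlas.labels.shape, dtype=bool)
    if not roi.any():
        (outdir / "enrichment_summary.json").write_text(
            json.dumps({"status": "no dimorphic ROI; enrichment skipped"}))
        return
    rng = np.random.default_rng(cfg.seed + 1)
    # plant enrichment for a handful of sex-chromosome genes in the ROI
    n_sex = max(int(0.05 * cfg.n_genes), 20)
    f_max = 0.5 * atlas.brain_mask.sum() / max(roi.sum(), 1)
    enriched = [(i, roi, min(3.0, f_max)) for i in range(n_sex // 2)]
    panel = simulate.generate_expression_panel(
        atlas, cfg.n_genes, enriched=enriched, seed=int(rng.integers(2**31)),
        sex_chrom_fraction=n_sex / cfg.n_genes)
    tab = expression.fold_change_table(panel, roi, atlas.brain_mask)
    tab.to_csv(outdir / "fold_changes.csv", index=False)
    ks = expression.sexchrom_bias_test(tab)
    report = expression.ranked_gene_report({"dimorphic": tab})
    report.head(25).to_csv(outdir / "top_genes.csv", index=False)
    (outdir / "enrichment_summary.json").write_text(json.dumps({
        "d_minus": ks.d_minus, "pvalue": ks.pvalue,
        "n_sex_genes": ks.n_sex_genes}, indent=2))


def stage_individualize(cfg: RunConfig, outdir: Path) -> None:
    table = volumes.read_volume_table(outdir / "cohort.csv")
    accessed = tuple(a for a in sorted(table["age_days"].unique()) if a < cfg.target_time)
    curves = individualization.accuracy_curve(table, cfg.target_time, accessed)
    curves.to_csv(outdir / "accuracy_curves.csv", index=False)
    preds = individualization.predict_all_subjects(table, cfg.target_time, accessed[-1])
    preds.to_csv(outdir / "predictions.csv", index=False)
    spec = individualization.specificity_analysis(preds)
    pd.DataFrame(spec.centered, index=spec.subjects, columns=spec.subjects).to_csv(
        outdir / "specificity_matrix.csv")
    timing = individualization.individualization_timing(
        curves, n_perm=cfg.n_perm, seed=cfg.seed)
    (outdir / "individualization_summary.json").write_text(json.dumps({
        "specificity_d_plus": spec.d_plus,
        "specificity_pvalue": spec.pvalue,
        "specificity_probability": spec.specificity_probability,
        "window": timing.window,
        "observed_zrmsd_diff": timing.observed_diff,
        "perm_pvalue": timing.perm_pvalue,
        "status": timing.status}, indent=2))


def stage_thickness(cfg: RunConfig, outdir: Path) -> None:
    # shell scaled to the run's grid (radii 5/8 of the default 24 grid)
    scale = min(cfg.grid_shape) / 24.0
    ribbon, inner, outer = simulate.generate_cortex_phantom(
        "shell", {"r_in": 5 * scale, "r_out": 8 * scale}, grid_shape=cfg.grid_shape)
    pot = thickness.solve_laplace(ribbon, inner, outer)
    tmap = thickness.streamline_thickness(pot)
    tmap.to_frame().to_csv(outdir / "thickness.csv", index=False)
    (outdir / "thickness_summary.json").write_text(json.dumps({
        "median_thickness": float(np.nanmedian(tmap.thickness)),
        "n_points": int(len(tmap.thickness)),
        "n_flagged": tmap.n_flagged,
        "sor_iterations": pot.iterations}, indent=2))


def stage_report(cfg: RunConfig, outdir: Path) -> None:
    report = {}
    for name in ("voxel_summary", "cluster_summary", "enrichment_summary",
                 "individualization_summary", "thickness_summary"):
        p = outdir / f"{name}.json"
        if p.exists():
            report[name] = json.loads(p.read_text())
    sp = outdir / "structure_tests.csv"
    if sp.exists():
        st = pd.read_csv(sp)
        rel = st[st.response == "relative"]
        report["dimorphic_structures"] = sorted(
            rel.loc[rel.qvalue < cfg.q_threshold, "structure"].tolist())
    (outdir / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))


STAGES = {
    "simulate": stage_simulate,
    "structure": stage_structure,
    "voxel": stage_voxel,
    "cluster": stage_cluster,
    "enrich": stage_enrich,
    "individualize": stage_individualize,
    "thickness": stage_thickness,
    "report": stage_report,
}


def run_pipeline(cfg: RunConfig) -> Path:
    """Run the configured stages in dependency order; returns the run dir."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "config.json").write_text(cfg.to_json())
    timings = {}
    for name in cfg.stages:
        if name not in STAGES:
            raise ValueError(f"unknown stage {name!r}")
        t0 = time.perf_counter()
        log.info("stage %s ...", name)
        try:
            STAGES[name](cfg, outdir)
        except Exception as exc:  # partial outputs are retained on failure
            raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
        timings[name] = round(time.perf_counter() - t0, 3)
        log.info("stage %s done in %.2fs", name, timings[name])
    (outdir / "manifest.json").write_text(json.dumps(
        {"config": json.loads(cfg.to_json()), "stage_seconds": timings},
        indent=2, sort_keys=True))
    return outdir
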