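"""End-to-end analysis pipeline.

Chains the stages over a cohort: motion QC and exclusion, preprocessing,
per-subject degree-centrality and seed Granger maps, Monte-Carlo corrected
one-sample and covariate-adjusted two-sample inference, and clinical
correlations.  The file-based entry point :func:`run_pipeline` mirrors the
in-memory :func:`analyze_cohort`; output is a pure function of
(inputs, config, seed).
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable

import numpy as np
import pandas as pd
from scipy import stats

from .clusters import ClusterTable, McResult, apply_correction, estimate_cluster_threshold
from .config import StudyConfig
from .degree import DegreeCentralityModel
from .granger import SeedGrangerModel
from .grids import BinaryMask, BoldSeries, ScalarMap, VolumeGrid
from .group import (
    build_design,
    combine_group_masks,
    correlation_report,
    cluster_mean_values,
    demographics_table,
    glm_dof,
    one_sample_map,
    two_sample_glm_map,
)
from .io import read_motion_trace, read_subjects_table, read_volume, write_volume
from .preprocess import MotionTrace, gm_mask_from_prob, motion_qc, preprocess_bold

__all__ = ["CohortResults", "analyze_cohort", "run_pipeline", "SEED_CENTERS"]

logger = logging.getLogger("hubcausal")

#: superior-frontal seed coordinates (MNI mm), left and right
SEED_CENTERS = ((-18.0, 42.0, 27.0), (18.0, 42.0, 27.0))


@dataclass
class SeedGroupResult:
    """Group inference for one seed and one direction."""

    seed_center: tuple
    direction: str  # "xy" (seed -> voxel) or "yx"
    tmap: ScalarMap
    clusters: ClusterTable
    corrected: ScalarMap


@dataclass
class CohortResults:
    subjects: pd.DataFrame
    excluded_ids: list[str]
    gm_mask: BinaryMask
    dc_z_maps: list[ScalarMap]
    gc_z_maps: dict  # (seed_idx, direction) -> list[ScalarMap]
    dc_one_sample: dict  # group -> t ScalarMap
    combined_mask: BinaryMask
    mc_gm: McResult
    mc_combined: McResult
    mc_gc: McResult
    dc_tmap: ScalarMap
    dc_clusters: ClusterTable
    dc_corrected: ScalarMap
    gc_group: list[SeedGroupResult]
    correlations: pd.DataFrame
    demographics: pd.DataFrame
    summary: dict = field(default_factory=dict)

    def summary_json(self) -> str:
        return json.dumps(self.summary, sort_keys=True, indent=2)


def _cluster_records(table: ClusterTable) -> list[dict]:
    return [
        {
            "label": int(r.label),
            "n_voxels": int(r.n_voxels),
            "peak_stat": round(float(r.peak_stat), 6),
            "peak_mni": [float(r.peak_x), float(r.peak_y), float(r.peak_z)],
        }
        for r in table.df.itertuples()
    ]


def analyze_cohort(
    grid: VolumeGrid,
    gm_prob: ScalarMap,
    subjects: pd.DataFrame,
    bold_provider: Callable[[str], BoldSeries],
    config: StudyConfig,
    motion_provider: Callable[[str], MotionTrace] | None = None,
    seed_centers: tuple = SEED_CENTERS,
) -> CohortResults:
    """Run the full analysis on an in-memory cohort.

    ``bold_provider`` maps subject_id -> BoldSeries (raw, pre-discard);
    ``motion_provider`` maps subject_id -> MotionTrace for QC (optional).
    """
    t0 = time.perf_counter()
    subjects = subjects.copy().reset_index(drop=True)
    if "excluded" not in subjects.columns:
        subjects["excluded"] = False

    # ---- motion QC -------------------------------------------------------
    excluded = []
    if motion_provider is not None:
        for sid in subjects["subject_id"]:
            qc = motion_qc(
                motion_provider(sid), config.motion_limit_mm, config.motion_limit_deg
            )
            if not qc.passed:
                subjects.loc[subjects["subject_id"] == sid, "excluded"] = True
                excluded.append(str(sid))
                logger.warning(
                    "subject %s excluded: max translation %.2f mm, max rotation %.2f deg",
                    sid, qc.max_translation_mm, qc.max_rotation_deg,
                )
    excluded += [
        str(s) for s in subjects.loc[subjects["excluded"], "subject_id"]
        if str(s) not in excluded
    ]
    included = subjects[~subjects["excluded"]].reset_index(drop=True)
    n_pat = int((included["group"] == "tinnitus").sum())
    n_ctl = int((included["group"] == "control").sum())
    logger.info("cohort: %d tinnitus + %d control included, %d excluded",
                n_pat, n_ctl, len(excluded))

    gm_mask = gm_mask_from_prob(gm_prob, config.gm_prob_threshold)

    # ---- per-subject maps ------------------------------------------------
    t_stage = time.perf_counter()
    dc_z_maps: list[ScalarMap] = []
    gc_z_maps: dict = {
        (i, d): [] for i in range(len(seed_centers)) for d in ("xy", "yx")
    }
    for sid in included["subject_id"]:
        bold = bold_provider(sid)
        if not bold.grid.matches(grid):
            raise ValueError(f"subject {sid} is on a different grid")
        pre = preprocess_bold(
            bold,
            discard=config.discard_volumes,
            fwhm_mm=config.fwhm_mm,
            band=(config.band_low_hz, config.band_high_hz),
        )
        dc = DegreeCentralityModel(
            pre, gm_mask, config.r_threshold, config.dc_flavor
        ).fit(block_size=512, dtype=np.float32)
        dc_z_maps.append(dc.z)
        for i, center in enumerate(seed_centers):
            gc = SeedGrangerModel(
                pre, gm_mask, center, config.seed_radius_mm, config.gc_order
            ).fit()
            gc_z_maps[(i, "xy")].append(gc.z_xy)
            gc_z_maps[(i, "yx")].append(gc.z_yx)
    logger.info("per-subject maps: %.1f s", time.perf_counter() - t_stage)

    # ---- degree-centrality group inference -------------------------------
    t_stage = time.perf_counter()
    rng = np.random.default_rng(config.rng_seed)
    mc_gm = estimate_cluster_threshold(
        gm_mask, config.voxel_p, config.corrected_alpha, config.n_mc_sims,
        config.fwhm_mm, config.connect_radius_mm, rng=rng,
    )
    groups = ("tinnitus", "control")
    dc_one_sample = {}
    thresholds = []
    for g in groups:
        idx = np.flatnonzero((included["group"] == g).to_numpy())
        maps_g = [dc_z_maps[i] for i in idx]
        dc_one_sample[g] = one_sample_map(maps_g, gm_mask)
        thresholds.append(float(stats.t.isf(config.voxel_p, len(idx) - 1)))
    combined_mask = combine_group_masks(
        [dc_one_sample[g] for g in groups], gm_mask, mc_gm, thresholds,
        config.connect_radius_mm,
    )
    mc_combined = estimate_cluster_threshold(
        combined_mask, config.voxel_p, config.corrected_alpha, config.n_mc_sims,
        config.fwhm_mm, config.connect_radius_mm, rng=rng,
    )
    design = build_design(included)
    t_thr_glm = float(stats.t.isf(config.voxel_p, glm_dof(design)))
    dc_tmap = two_sample_glm_map(dc_z_maps, design, combined_mask)
    dc_clusters, dc_corrected = apply_correction(
        dc_tmap, combined_mask, t_thr_glm, mc_combined,
        config.connect_radius_mm, sign="two_sided",
    )
    logger.info("DC group inference: %.1f s (min cluster %d voxels)",
                time.perf_counter() - t_stage, mc_combined.min_cluster_size)

    # ---- Granger group inference -----------------------------------------
    t_stage = time.perf_counter()
    gc_mask_data = gm_mask.data.copy()
    for center in seed_centers:  # seed spheres excluded: no self-prediction
        gc_mask_data &= ~grid.sphere(center, config.seed_radius_mm)
    gc_mask = BinaryMask(grid, gc_mask_data)
    mc_gc = estimate_cluster_threshold(
        gc_mask, config.voxel_p, config.corrected_alpha, config.n_mc_sims,
        config.fwhm_mm, config.connect_radius_mm, rng=rng,
    )
    gc_group: list[SeedGroupResult] = []
    for i, center in enumerate(seed_centers):
        for d in ("xy", "yx"):
            tmap = two_sample_glm_map(gc_z_maps[(i, d)], design, gc_mask)
            clusters, corrected = apply_correction(
                tmap, gc_mask, t_thr_glm, mc_gc,
                config.connect_radius_mm, sign="two_sided",
            )
            gc_group.append(SeedGroupResult(tuple(center), d, tmap, clusters, corrected))
    logger.info("GC group inference: %.1f s", time.perf_counter() - t_stage)

    # ---- clinical correlations -------------------------------------------
    t_stage = time.perf_counter()
    pat_rows = included["group"] == "tinnitus"
    pat_idx = np.flatnonzero(pat_rows.to_numpy())
    covs = np.column_stack(
        [
            included.loc[pat_rows, "age"].to_numpy(dtype=float),
            np.where(included.loc[pat_rows, "sex"].astype(str).str.lower()
                     .isin(("male", "m", "1")), 1.0, 0.0),
            included.loc[pat_rows, "education"].to_numpy(dtype=float),
        ]
    )
    clinical = {}
    if included.loc[pat_rows, "thq"].notna().any():
        clinical["THQ"] = included.loc[pat_rows, "thq"].to_numpy(dtype=float)
    if "tinnitus_duration" in included.columns and included.loc[
        pat_rows, "tinnitus_duration"
    ].notna().any():
        clinical["duration"] = included.loc[pat_rows, "tinnitus_duration"].to_numpy(dtype=float)

    cluster_values: dict[str, np.ndarray] = {}
    for r in dc_clusters.df.itertuples():
        cmask = BinaryMask(grid, dc_clusters.labels.data == r.label)
        vals = cluster_mean_values(dc_z_maps, cmask)
        cluster_values[f"dc_cluster_{int(r.label)}"] = vals[pat_idx]
    for sg in gc_group:
        if sg.direction != "xy":
            continue
        side = "left" if sg.seed_center[0] < 0 else "right"
        for r in sg.clusters.df.itertuples():
            cmask = BinaryMask(grid, sg.clusters.labels.data == r.label)
            seed_i = 0 if side == "left" else 1
            vals = cluster_mean_values(gc_z_maps[(seed_i, "xy")], cmask)
            cluster_values[f"gc_{side}_xy_cluster_{int(r.label)}"] = vals[pat_idx]
    if cluster_values and clinical and len(pat_idx) > covs.shape[1] + 2:
        correlations = correlation_report(cluster_values, clinical, covs)
    else:
        correlations = pd.DataFrame(
            columns=["cluster_id", "clinical_variable", "r", "p_raw",
                     "p_bonferroni", "n", "n_tests"]
        )
    demographics = demographics_table(included)
    logger.info("correlations: %.1f s", time.perf_counter() - t_stage)

    summary = {
        "config": {
            "r_threshold": config.r_threshold,
            "voxel_p": config.voxel_p,
            "corrected_alpha": config.corrected_alpha,
            "n_mc_sims": config.n_mc_sims,
            "fwhm_mm": config.fwhm_mm,
            "connect_radius_mm": config.connect_radius_mm,
            "gc_order": config.gc_order,
            "dc_flavor": config.dc_flavor,
            "rng_seed": config.rng_seed,
        },
        "n_included": {"tinnitus": n_pat, "control": n_ctl},
        "excluded_subjects": sorted(excluded),
        "gm_mask_voxels": gm_mask.n_true,
        "combined_mask_voxels": combined_mask.n_true,
        "min_cluster_size": {
            "gm": mc_gm.min_cluster_size,
            "combined": mc_combined.min_cluster_size,
            "gc": mc_gc.min_cluster_size,
        },
        "dc_clusters": _cluster_records(dc_clusters),
        "gc_clusters": {
            f"{'left' if sg.seed_center[0] < 0 else 'right'}_{sg.direction}":
                _cluster_records(sg.clusters)
            for sg in gc_group
        },
        "correlations": [
            {
                "cluster_id": r.cluster_id,
                "clinical_variable": r.clinical_variable,
                "r": round(float(r.r), 6),
                "p_raw": round(float(r.p_raw), 6),
                "p_bonferroni": round(float(r.p_bonferroni), 6),
                "n": int(r.n),
            }
            for r in correlations.itertuples()
        ],
    }
    logger.info("total analysis: %.1f s", time.perf_counter() - t0)
    return CohortResults(
        subjects=subjects,
        excluded_ids=sorted(excluded),
        gm_mask=gm_mask,
        dc_z_maps=dc_z_maps,
        gc_z_maps=gc_z_maps,
        dc_one_sample=dc_one_sample,
        combined_mask=combined_mask,
        mc_gm=mc_gm,
        mc_combined=mc_combined,
        mc_gc=mc_gc,
        dc_tmap=dc_tmap,
        dc_clusters=dc_clusters,
        dc_corrected=dc_corrected,
        gc_group=gc_group,
        correlations=correlations,
        demographics=demographics,
        summary=summary,
    )


def recovery_report(res: CohortResults, cohort) -> dict:
    """Compare pipeline results against a synthetic cohort's ground truth.

    Returns the three recovery indicators for an effect-bearing cohort:
    whether the largest corrected DC cluster overlaps an injected hub
    sphere, whether a positive corrected seed->voxel Granger contrast
    cluster covers an injected coupling target, and whether the strongest
    Granger-cluster THQ partial correlation has the sign of the generator's
    target correlation.
    """
    grid = cohort.grid
    eff = cohort.effects
    hub = np.zeros(grid.dims, dtype=bool)
    for c in eff.hub_centers:
        hub |= grid.sphere(c, eff.hub_radius_mm)

    df = res.dc_clusters.df
    hub_ok = False
    if len(df):
        largest = df.iloc[0]
        hub_ok = bool(
            largest["peak_stat"] > 0  # recovered as *increased* centrality
            and ((res.dc_clusters.labels.data == int(largest["label"])) & hub).any()
        )

    gc_ok = False
    for sg in res.gc_group:
        if sg.direction != "xy":
            continue
        seed_i = 0 if sg.seed_center[0] < 0 else 1
        target = grid.sphere(eff.coupling_targets[seed_i], eff.coupling_radius_mm)
        for r in sg.clusters.df.itertuples():
            if r.peak_stat > 0 and ((sg.clusters.labels.data == r.label) & target).any():
                gc_ok = True

    cr = res.correlations
    thq_ok = False
    thq_r = float("nan")
    if len(cr):
        gc_thq = cr[
            cr["cluster_id"].str.startswith("gc_") & (cr["clinical_variable"] == "THQ")
        ]
        if len(gc_thq):
            thq_r = float(gc_thq.loc[gc_thq["r"].abs().idxmax(), "r"])
            thq_ok = bool(np.sign(thq_r) == np.sign(eff.thq_coupling_r)) if eff.thq_coupling_r != 0 else True
    return {
        "hub_largest_cluster": hub_ok,
        "gc_target_positive": gc_ok,
        "thq_sign_match": thq_ok,
        "thq_strongest_r": thq_r,
        "n_dc_clusters": int(len(df)),
    }


def run_pipeline(
    config: StudyConfig,
    subjects_csv: str | Path,
    data_dir: str | Path,
    out_dir: str | Path,
    write_subject_maps: bool = False,
    seed_centers: tuple = SEED_CENTERS,
) -> Path:
    """File-based pipeline: read a cohort directory, write all results.

    Expects ``<data_dir>/gm_prob.nii.gz``, ``<data_dir>/bold/<sid>.nii.gz``
    and optional ``<data_dir>/motion/<sid>.txt``.  Writes group maps,
    cluster tables, the correlation and demographics reports and a
    machine-readable ``summary.json`` under ``out_dir``.
    """
    data_dir, out_dir = Path(data_dir), Path(out_dir)
    subjects = read_subjects_table(subjects_csv)
    gm_path = data_dir / "gm_prob.nii.gz"
    if not gm_path.exists():
        raise FileNotFoundError(f"gray-matter map not found: {gm_path}")
    gm_prob = read_volume(gm_path, kind="gm_prob")
    grid = gm_prob.grid

    def bold_provider(sid: str) -> BoldSeries:
        path = data_dir / "bold" / f"{sid}.nii.gz"
        if not path.exists():
            raise FileNotFoundError(f"missing BOLD file for subject {sid}: {path}")
        return read_volume(path)

    motion_dir = data_dir / "motion"
    motion_provider = None
    if motion_dir.exists():
        def motion_provider(sid: str) -> MotionTrace:
            return MotionTrace(*read_motion_trace(motion_dir / f"{sid}.txt"))

    res = analyze_cohort(
        grid, gm_prob, subjects, bold_provider, config, motion_provider,
        seed_centers=seed_centers,
    )

    out_dir.mkdir(parents=True, exist_ok=True)
    maps_dir = out_dir / "maps"
    for g, tmap in res.dc_one_sample.items():
        write_volume(tmap, maps_dir / f"dc_one_sample_{g}.nii.gz")
    write_volume(res.dc_tmap, maps_dir / "dc_two_sample_t.nii.gz")
    write_volume(res.dc_corrected, maps_dir / "dc_two_sample_t_corrected.nii.gz")
    for sg in res.gc_group:
        side = "left" if sg.seed_center[0] < 0 else "right"
        write_volume(sg.tmap, maps_dir / f"gc_{side}_{sg.direction}_t.nii.gz")
        write_volume(sg.corrected, maps_dir / f"gc_{side}_{sg.direction}_t_corrected.nii.gz")
    if write_subject_maps:
        subj_dir = out_dir / "subject_maps"
        included = res.subjects[~res.subjects["excluded"]]
        for i, sid in enumerate(included["subject_id"]):
            write_volume(res.dc_z_maps[i], subj_dir / f"{sid}_dc_z.nii.gz",
                         sidecar={"flavor": config.dc_flavor})
    res.dc_clusters.to_csv(out_dir / "dc_clusters.csv")
    for sg in res.gc_group:
        side = "left" if sg.seed_center[0] < 0 else "right"
        sg.clusters.to_csv(out_dir / f"gc_{side}_{sg.direction}_clusters.csv")
    res.correlations.to_csv(out_dir / "correlations.csv", index=False)
    res.demographics.to_csv(out_dir / "demographics.csv", index=False)
    (out_dir / "summary.json").write_text(res.summary_json())
    logger.info("results written to %s", out_dir)
    return out_dir
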