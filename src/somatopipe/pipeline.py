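"""End-to-end pipeline driver: simulate -> GLM -> group stats -> decoding."""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from somatopipe import design as design_mod
from somatopipe import glm as glm_mod
from somatopipe import mvpa as mvpa_mod
from somatopipe import physio as physio_mod
from somatopipe import synthetic_data as synth
from somatopipe import univariate_stats as ustats
from somatopipe.config import (PipelineConfig, config_to_dict, save_config)

#: home condition of each nucleus ROI, for planned contrasts
ROI_TARGETS = {
    "left_cuneate": "left_hand",
    "right_cuneate": "right_hand",
    "spinal_trigeminal_left": "face",
    "spinal_trigeminal_right": "face",
    "vpl_left": "right_hand",
    "vpl_right": "left_hand",
    "vpm": "face",
    "s1_hand_left": "right_hand",
    "s1_hand_right": "left_hand",
    "s1_face": "face",
}


def effect_from_config(sim) -> synth.EffectSpec:
    return synth.EffectSpec(
        snr_s1=sim.snr_s1, snr_thalamus=sim.snr_thalamus,
        snr_brainstem=sim.snr_brainstem, pattern_overlap=sim.pattern_overlap,
        subject_variability=sim.subject_variability, amplitude=sim.amplitude)


def fit_run(
    image: np.ndarray,
    schedule: design_mod.BlockSchedule,
    trace: synth.PhysioTrace,
    physio_config: physio_mod.RetroicorConfig = physio_mod.PNM_CONFIG,
    smooth_fwhm_mm: float = 2.0,
    voxel_size_mm=1.0,
    highpass_s: float | None = 90.0,
    basis: design_mod.HRFBasis | None = None,
) -> glm_mod.GLMResult:
    """Smooth one run, build its design (task + physio nuisance + drift),
    and fit the voxelwise GLM."""
    t_vol = (np.arange(schedule.n_volumes) + 0.5) * schedule.tr_s
    phases = physio_mod.phase_series(trace, t_vol)
    nuisance = physio_mod.retroicor_regressors(phases, physio_config,
                                               trace=trace)
    dmat = design_mod.build_design_matrix(schedule, basis=basis,
                                          nuisance=nuisance,
                                          highpass_s=highpass_s)
    if smooth_fwhm_mm > 0:
        image = glm_mod.smooth_volume(image, smooth_fwhm_mm, voxel_size_mm)
    return glm_mod.fit_glm(image, dmat)


@dataclass
class CohortGLM:
    """First-level results for a cohort: per subject, per run."""

    beta_maps: dict[str, list[dict[str, np.ndarray]]]  # canonical betas
    contrasts: dict[str, list[dict[str, glm_mod.ContrastMap]]]
    retained_runs: dict[str, list[int]]
    exclusion_report: pd.DataFrame


def fit_cohort(
    cohort: list[synth.SubjectDataset],
    physio_config: physio_mod.RetroicorConfig = physio_mod.PNM_CONFIG,
    smooth_fwhm_mm: float = 2.0,
    highpass_s: float | None = 90.0,
    exclusion_threshold_mm: float = 1.0,
) -> CohortGLM:
    """First-level GLM for every run of every subject.

    Canonical beta maps (decoding features) are kept for all runs; the
    motion exclusion rule applies only to the univariate (fixed-effects)
    path, recorded in ``retained_runs``.
    """
    retained, report = glm_mod.exclude_runs(cohort, exclusion_threshold_mm)
    beta_maps: dict[str, list[dict[str, np.ndarray]]] = {}
    contrasts: dict[str, list[dict[str, glm_mod.ContrastMap]]] = {}
    basis_cache: dict[float, design_mod.HRFBasis] = {}
    for subject in cohort:
        vs = subject.grid.voxel_size_mm
        runs_b, runs_c = [], []
        for run in subject.runs:
            tr = run.schedule.tr_s
            if tr not in basis_cache:
                basis_cache[tr] = design_mod.hrf_basis(tr)
            res = fit_run(run.image, run.schedule, run.physio,
                          physio_config=physio_config,
                          smooth_fwhm_mm=smooth_fwhm_mm, voxel_size_mm=vs,
                          highpass_s=highpass_s, basis=basis_cache[tr])
            betas = {c: res.canonical_beta(c) for c in design_mod.CONDITIONS}
            cmaps = {c: glm_mod.contrast_z(
                         res, glm_mod.condition_vs_rest_weights(res.design, c))
                     for c in design_mod.CONDITIONS}
            runs_b.append(betas)
            runs_c.append(cmaps)
        beta_maps[subject.subject_id] = runs_b
        contrasts[subject.subject_id] = runs_c
    return CohortGLM(beta_maps=beta_maps, contrasts=contrasts,
                     retained_runs=retained, exclusion_report=report)


def subject_fixed_effects(cohort_glm: CohortGLM) -> dict[str, dict[str, glm_mod.ContrastMap]]:
    """Fixed-effects combination across each subject's retained runs."""
    out: dict[str, dict[str, glm_mod.ContrastMap]] = {}
    for subject, run_contrasts in cohort_glm.contrasts.items():
        keep = cohort_glm.retained_runs[subject]
        if not keep:
            continue
        out[subject] = {
            cond: glm_mod.fixed_effects_combine(
                [run_contrasts[i][cond] for i in keep])
            for cond in design_mod.CONDITIONS}
    return out


def run_pipeline(config: PipelineConfig, out_dir=None) -> dict:
    """Execute the full pipeline and write a machine-readable summary.

    Stages: simulate -> first-level GLM with physiological nuisance and
    run exclusion -> fixed effects -> ROI statistics and sign-flip group
    test -> ROI decoding with permutation null -> searchlight with
    cluster correction. Returns the summary dict; writes ``summary.tsv``,
    ``log.jsonl`` and the fully resolved config under ``out_dir``.
    """
    out = Path(out_dir or config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_dict = config_to_dict(config)
    cfg_dict.pop("out_dir", None)  # hash the scientific config only
    cfg_hash = hashlib.sha256(
        json.dumps(cfg_dict, sort_keys=True).encode()).hexdigest()[:12]
    log_path = out / "log.jsonl"
    log_fh = open(log_path, "w")

    def log(stage: str, **kw):
        rec = {"stage": stage, "config_hash": cfg_hash,
               "elapsed_s": round(time.perf_counter() - t0, 2), **kw}
        log_fh.write(json.dumps(rec) + "\n")
        log_fh.flush()

    t0 = time.perf_counter()
    summary: dict = {"seed": config.seed, "config_hash": cfg_hash}
    save_config(config, out / "resolved_config.yaml")

    stage = "simulate"
    try:
        sim, des = config.simulate, config.design
        grid = synth.VolumeGrid.centered(sim.grid_shape, sim.voxel_size_mm)
        atlas = synth.build_phantom_atlas(grid)
        effect = effect_from_config(sim)
        noise = synth.NoiseConfig(cardiac_amplitude=sim.cardiac_amplitude,
                                  respiratory_amplitude=sim.respiratory_amplitude)
        cohort = synth.generate_cohort(
            n_subjects=sim.n_subjects, atlas=atlas, effect=effect,
            seed=config.seed, n_runs=sim.n_runs, noise=noise,
            tr_s=des.tr_s, n_volumes=des.n_volumes,
            blocks_per_condition=des.blocks_per_condition)
        schedules = [r.schedule for r in cohort[0].runs]
        counts = design_mod.nominal_volume_counts(schedules)
        summary["task_structure_s"] = design_mod.schedule_duration(schedules[0])
        summary["trials_per_condition"] = (des.blocks_per_condition
                                           * sim.n_runs)
        summary["movement_volumes_per_condition"] = counts["left_hand"]
        summary["rest_volumes"] = counts["rest"]
        log(stage, n_subjects=sim.n_subjects, n_runs=sim.n_runs)

        stage = "glm"
        pcfg = physio_mod.RetroicorConfig(
            config.physio.cardiac_order, config.physio.resp_order,
            config.physio.interaction_order, tuple(config.physio.extras))
        summary["n_physio_regressors"] = pcfg.n_columns
        cohort_glm = fit_cohort(
            cohort, physio_config=pcfg,
            smooth_fwhm_mm=config.glm.smooth_fwhm_mm,
            highpass_s=des.highpass_s,
            exclusion_threshold_mm=config.glm.exclusion_threshold_mm)
        summary["n_excluded_runs"] = len(cohort_glm.exclusion_report)
        cohort_glm.exclusion_report.to_csv(out / "excluded_runs.tsv",
                                           sep="\t", index=False)
        log(stage, n_excluded=summary["n_excluded_runs"])

        stage = "fixed_effects"
        fixed = subject_fixed_effects(cohort_glm)
        log(stage, n_subjects_retained=len(fixed))

        stage = "roi_stats"
        z_maps = {s: {c: cm.z for c, cm in conds.items()}
                  for s, conds in fixed.items()}
        roi_table = ustats.extract_roi_means(z_maps, atlas, config.stats.rois)
        roi_table.to_csv(out / "roi_means.tsv", sep="\t", index=False)
        roi_reports = {}
        for roi in config.stats.rois:
            rep = ustats.rm_anova_with_gates(roi_table, roi,
                                             ROI_TARGETS[roi])
            roi_reports[roi] = rep
            summary[f"roi_{roi}_method"] = rep.method
            summary[f"roi_{roi}_stat"] = round(rep.statistic, 3)
            summary[f"roi_{roi}_p"] = rep.p_value
        log(stage, rois=list(config.stats.rois))

        stage = "group_test"
        cond = config.stats.group_test_condition
        mask = atlas.mask(config.stats.group_test_mask)
        effect_maps = np.stack([fixed[s][cond].effect for s in fixed])
        gres = ustats.sign_flip_group_test(
            effect_maps, mask, n_perm=config.stats.n_perm,
            variance_smooth_mm=config.stats.variance_smooth_mm,
            voxel_size_mm=grid.voxel_size_mm, seed=config.seed)
        n_sig = int(np.sum(gres.corrected_p[mask] < config.stats.alpha_fwe))
        summary["group_test_condition"] = cond
        summary["group_test_n_sig_voxels"] = n_sig
        log(stage, n_sig_voxels=n_sig)

        stage = "decode"
        for mask_name in config.mvpa.masks:
            samples = mvpa_mod.assemble_beta_samples(cohort_glm.beta_maps,
                                                     atlas.mask(mask_name))
            if mask_name == config.mvpa.masks[0]:
                summary["n_beta_samples"] = samples.n_samples
            result = mvpa_mod.loso_decode(samples)
            null = mvpa_mod.permutation_pvalue(
                samples, n_perm=config.mvpa.n_perm, seed=config.seed,
                observed=result.accuracy)
            summary[f"decode_{mask_name}_accuracy_pct"] = round(
                result.accuracy, 1)
            summary[f"decode_{mask_name}_p"] = null.p_value
            summary[f"decode_{mask_name}_null_mean_pct"] = round(
                float(null.null_accuracies.mean()), 1)
            result.confusion.to_csv(out / f"confusion_{mask_name}.tsv",
                                    sep="\t")
        log(stage, masks=list(config.mvpa.masks))

        if config.mvpa.run_searchlight:
            stage = "searchlight"
            sl_mask = atlas.mask(config.mvpa.searchlight_mask)
            samples = mvpa_mod.assemble_beta_samples(cohort_glm.beta_maps,
                                                     np.ones(grid.shape, bool))
            stack = samples.X.reshape(samples.n_samples, *grid.shape)
            obs = mvpa_mod.searchlight_map(
                stack, samples.labels, samples.groups, sl_mask,
                radius_mm=config.mvpa.radius_mm,
                voxel_size_mm=grid.voxel_size_mm)
            perms = mvpa_mod.searchlight_permutation_maps(
                stack, samples.labels, samples.groups, sl_mask,
                n_perm=config.mvpa.n_perm_searchlight, seed=config.seed,
                radius_mm=config.mvpa.radius_mm,
                voxel_size_mm=grid.voxel_size_mm)
            sl = mvpa_mod.cluster_correct_searchlight(
                obs, perms, sl_mask, alpha_voxel=config.mvpa.alpha_voxel,
                alpha_cluster=config.mvpa.alpha_cluster,
                radius_mm=config.mvpa.radius_mm)
            summary["searchlight_accuracy_cutoff_pct"] = round(
                sl.accuracy_cutoff, 1)
            summary["searchlight_cluster_size_cutoff"] = sl.cluster_size_cutoff
            summary["searchlight_n_clusters"] = len(sl.clusters)
            sl.cluster_table().to_csv(out / "searchlight_clusters.tsv",
                                      sep="\t", index=False)
            log(stage, n_clusters=len(sl.clusters))
    except Exception as exc:
        log_fh.write(json.dumps({"stage": stage, "error": str(exc),
                                 "config_hash": cfg_hash}) + "\n")
        log_fh.close()
        raise RuntimeError(f"pipeline failed at stage {stage!r} "
                           f"(config {cfg_hash}): {exc}") from exc

    rows = [{"quantity": k, "value": v} for k, v in summary.items()]
    pd.DataFrame(rows).to_csv(out / "summary.tsv", sep="\t", index=False)
    log("done")
    log_fh.close()
    return summary
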