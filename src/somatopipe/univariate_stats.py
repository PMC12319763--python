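"""ROI-level statistics and nonparametric group voxelwise inference.

ROI analysis: per-subject mean z within anatomical masks, single-pass
outlier replacement (mean ± 2.5 sd), then a normality-gated repeated
measures pipeline — RM-ANOVA with Greenhouse–Geisser correction when
Mauchly's test rejects sphericity and Bonferroni-corrected planned
contrasts, or Friedman's ANOVA with Kendall's W and Dunn's post-hoc when
Shapiro-Wilk rejects normality.

Group voxelwise inference: one-sample sign-flip permutation test with
variance smoothing (pseudo-t) and threshold-free cluster enhancement
(TFCE), FWE-corrected against the max-statistic null.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pingouin as pg
from scipy import ndimage, stats

from somatopipe.design import CONDITIONS
from somatopipe.glm import FWHM_TO_SIGMA

CONNECTIVITY_26 = np.ones((3, 3, 3), dtype=bool)
CONNECTIVITY_6 = ndimage.generate_binary_structure(3, 1)


def _structure(connectivity: int) -> np.ndarray:
    if connectivity == 26:
        return CONNECTIVITY_26
    if connectivity == 6:
        return CONNECTIVITY_6
    if connectivity == 18:
        return ndimage.generate_binary_structure(3, 2)
    raise ValueError("connectivity must be 6, 18, or 26")


# --- ROI tables ----------------------------------------------------------------


def extract_roi_means(subject_z_maps, atlas, roi_names) -> pd.DataFrame:
    """Mean z per (subject, ROI, condition).

    ``subject_z_maps`` maps subject id to {condition: 3-D z map}. Returns a
    tidy table with columns subject, roi, condition, mean_z.
    """
    rows = []
    for roi in roi_names:
        mask = atlas.mask(roi)
        if not mask.any():
            raise ValueError(f"ROI {roi!r} has an empty mask")
        for subject, cond_maps in subject_z_maps.items():
            for cond, zmap in cond_maps.items():
                if zmap.shape != mask.shape:
                    raise ValueError("z map and atlas grids differ")
                rows.append({"subject": subject, "roi": roi,
                             "condition": cond,
                             "mean_z": float(zmap[mask].mean())})
    return pd.DataFrame(rows)


def roi_wide(table: pd.DataFrame, roi: str) -> pd.DataFrame:
    """Subject x condition view of one ROI."""
    sub = table[table["roi"] == roi]
    return sub.pivot(index="subject", columns="condition", values="mean_z")


def replace_outliers(values) -> tuple[np.ndarray, int]:
    """Single-pass replacement of values beyond mean ± 2.5 sd by the mean.

    Mean and sd are computed once on the full cell; the replacement does
    not iterate.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 3:
        raise ValueError("need at least 3 values per cell")
    mean, sd = v.mean(), v.std(ddof=1)
    out = np.abs(v - mean) > 2.5 * sd
    adjusted = np.where(out, mean, v)
    return adjusted, int(out.sum())


# --- Repeated-measures testing --------------------------------------------------


@dataclass
class TestReport:
    roi: str
    method: str  # "rm_anova" or "friedman"
    statistic: float
    p_value: float
    effect_size: float
    effect_size_name: str  # "eta_squared_partial" or "kendall_w"
    contrasts: pd.DataFrame  # contrast, statistic, p_uncorrected, p_corrected
    normality: dict[str, float]  # condition -> Shapiro-Wilk p
    sphericity_w: float | None = None
    sphericity_p: float | None = None
    gg_corrected: bool = False
    outlier_count: int = 0


def _dunn_contrasts(wide: pd.DataFrame, target: str) -> pd.DataFrame:
    """Dunn's post-hoc for Friedman: target condition vs each non-target.

    z = (Rbar_target - Rbar_other) / sqrt(k(k+1) / (6n)), two-sided normal
    p, corrected for the number of planned contrasts.
    """
    ranks = wide.rank(axis=1)
    n, k = wide.shape
    se = np.sqrt(k * (k + 1) / (6.0 * n))
    rows = []
    others = [c for c in wide.columns if c != target]
    for other in others:
        z = (ranks[target].mean() - ranks[other].mean()) / se
        p = 2 * stats.norm.sf(abs(z))
        rows.append({"contrast": f"{target} vs {other}", "statistic": z,
                     "p_uncorrected": p,
                     "p_corrected": min(1.0, p * len(others))})
    return pd.DataFrame(rows)


def _paired_t_contrasts(wide: pd.DataFrame, target: str) -> pd.DataFrame:
    rows = []
    others = [c for c in wide.columns if c != target]
    for other in others:
        t, p = stats.ttest_rel(wide[target], wide[other])
        rows.append({"contrast": f"{target} vs {other}", "statistic": float(t),
                     "p_uncorrected": float(p),
                     "p_corrected": min(1.0, float(p) * len(others))})
    return pd.DataFrame(rows)


def rm_anova_with_gates(
    table: pd.DataFrame,
    roi: str,
    target_condition: str,
    alpha_gate: float = 0.05,
    handle_outliers: bool = True,
) -> TestReport:
    """Normality-gated repeated-measures analysis of one ROI.

    ``table`` is the tidy output of :func:`extract_roi_means`. Each
    condition cell is Shapiro-Wilk tested; if any cell departs from
    normality the Friedman / Kendall's W / Dunn path is taken, otherwise
    RM-ANOVA with Mauchly's sphericity gate (Greenhouse–Geisser correction
    on violation) and Bonferroni-corrected planned paired contrasts of the
    target condition against each non-target.
    """
    wide = roi_wide(table, roi)
    if wide.shape[1] < 2:
        raise ValueError("need at least 2 conditions")
    if wide.shape[0] < 3:
        raise ValueError("need at least 3 subjects")

    outlier_count = 0
    if handle_outliers:
        for cond in wide.columns:
            adjusted, c = replace_outliers(wide[cond].to_numpy())
            wide[cond] = adjusted
            outlier_count += c

    normality: dict[str, float] = {}
    for cond in wide.columns:
        vals = wide[cond].to_numpy()
        if np.ptp(vals) == 0:
            normality[cond] = 1.0  # degenerate cell; Shapiro undefined
        else:
            normality[cond] = float(stats.shapiro(vals).pvalue)
    normal = all(p >= alpha_gate for p in normality.values())

    long = wide.reset_index().melt(id_vars="subject", var_name="condition",
                                   value_name="mean_z")
    if normal:
        spher = pg.sphericity(long, dv="mean_z", within="condition",
                              subject="subject")
        aov = pg.rm_anova(data=long, dv="mean_z", within="condition",
                          subject="subject", correction=True, detailed=True)
        row = aov.iloc[0]
        gg = not bool(spher.spher)
        p_unc = "p_unc" if "p_unc" in aov.columns else "p-unc"
        p_gg = "p_GG_corr" if "p_GG_corr" in aov.columns else "p-GG-corr"
        eta = "ng2" if "ng2" in aov.columns else "np2"
        p = float(row[p_gg]) if gg and p_gg in aov.columns else float(row[p_unc])
        f_stat = float(row["F"])
        if not np.isfinite(f_stat):  # zero between- and within-variance
            f_stat, p = 0.0, 1.0
        report = TestReport(
            roi=roi, method="rm_anova",
            statistic=f_stat, p_value=p,
            effect_size=float(row[eta]),
            effect_size_name="eta_squared",
            contrasts=_paired_t_contrasts(wide, target_condition),
            normality=normality,
            sphericity_w=float(spher.W), sphericity_p=float(spher.pval),
            gg_corrected=gg, outlier_count=outlier_count)
    else:
        fried = pg.friedman(data=long, dv="mean_z", within="condition",
                            subject="subject")
        frow = fried.iloc[0]
        stat_col = "Q" if "Q" in fried.columns else "F"
        p_unc = "p_unc" if "p_unc" in fried.columns else "p-unc"
        q_stat, q_p = float(frow[stat_col]), float(frow[p_unc])
        w = float(frow["W"])
        if not np.isfinite(q_stat):  # fully tied ranks: no effect
            q_stat, q_p, w = 0.0, 1.0, 0.0
        report = TestReport(
            roi=roi, method="friedman",
            statistic=q_stat, p_value=q_p,
            effect_size=w, effect_size_name="kendall_w",
            contrasts=_dunn_contrasts(wide, target_condition),
            normality=normality, outlier_count=outlier_count)
    return report


# --- TFCE and sign-flip group inference -----------------------------------------


def tfce(
    stat_map: np.ndarray,
    mask: np.ndarray | None = None,
    E: float = 0.5,
    H: float = 2.0,
    dh: float | None = None,
    connectivity: int = 26,
) -> np.ndarray:
    """Threshold-free cluster enhancement of the positive part of a map.

    For each voxel, sums extent(h)^E * h^H * dh over thresholds h = dh,
    2*dh, ... up to the map maximum, where extent(h) is the size of the
    suprathreshold connected component containing the voxel.
    """
    m = np.asarray(stat_map, dtype=float)
    if mask is not None:
        m = np.where(mask, m, 0.0)
    vmax = m.max(initial=0.0)
    out = np.zeros_like(m)
    if vmax <= 0:
        return out
    if dh is None:
        dh = vmax / 100.0
    if dh <= 0:
        raise ValueError("dh must be positive")
    structure = _structure(connectivity)
    n_steps = int(np.floor(vmax / dh + 1e-9))
    for step in range(1, n_steps + 1):
        h = step * dh
        supra = m >= h
        labels, n_comp = ndimage.label(supra, structure=structure)
        if n_comp == 0:
            continue
        sizes = np.bincount(labels.reshape(-1))
        sizes[0] = 0
        out += np.where(supra, (sizes[labels] ** E) * (h ** H) * dh, 0.0)
    return out


@dataclass
class GroupPermutationResult:
    observed_stat: np.ndarray  # pseudo-t map
    tfce_map: np.ndarray
    corrected_p: np.ndarray
    n_permutations: int
    null_max_tfce: np.ndarray
    mask: np.ndarray


def _masked_smooth(volume: np.ndarray, mask: np.ndarray,
                   sigma_vox: np.ndarray) -> np.ndarray:
    num = ndimage.gaussian_filter(np.where(mask, volume, 0.0), sigma_vox,
                                  mode="reflect")
    den = ndimage.gaussian_filter(mask.astype(float), sigma_vox,
                                  mode="reflect")
    with np.errstate(invalid="ignore", divide="ignore"):
        sm = np.where(den > 1e-12, num / den, 0.0)
    return np.where(mask, sm, 0.0)


def sign_flip_group_test(
    subject_effect_maps: np.ndarray,
    mask: np.ndarray,
    n_perm: int = 5000,
    variance_smooth_mm: float = 5.0,
    voxel_size_mm=1.0,
    seed: int = 0,
    tfce_e: float = 0.5,
    tfce_h: float = 2.0,
    tfce_dh: float | None = None,
    connectivity: int = 26,
) -> GroupPermutationResult:
    """One-sample group test by random sign flips of subject effect maps.

    The statistic is a pseudo-t with Gaussian-smoothed variance; inference
    enhances each permutation's map with TFCE and corrects family-wise
    error against the null distribution of the maximum TFCE value. The
    first permutation is the identity, so corrected p values are bounded
    below by 1/n_perm.
    """
    import warnings as _warnings

    maps = np.asarray(subject_effect_maps, dtype=float)
    n_subj = maps.shape[0]
    if n_subj < 2:
        raise ValueError("need at least 2 subjects")
    if maps.shape[1:] != mask.shape:
        raise ValueError("effect maps and mask grids differ")
    if n_perm < 100:
        _warnings.warn("fewer than 100 permutations: p values are coarse",
                       stacklevel=2)
    vs = np.broadcast_to(np.asarray(voxel_size_mm, dtype=float), 3)
    sigma_vox = (variance_smooth_mm * FWHM_TO_SIGMA) / vs

    flat = maps.reshape(n_subj, -1)
    ss = (flat ** 2).sum(axis=0)
    rng = np.random.default_rng(seed)
    shape = mask.shape

    def pseudo_t(signs: np.ndarray) -> np.ndarray:
        mean = (signs @ flat) / n_subj
        var = (ss - n_subj * mean ** 2) / (n_subj - 1)
        var = np.clip(var, 0.0, None).reshape(shape)
        svar = _masked_smooth(var, mask, sigma_vox)
        with np.errstate(invalid="ignore", divide="ignore"):
            t = np.where(svar > 0, mean.reshape(shape) / np.sqrt(svar / n_subj),
                         0.0)
        return np.where(mask, t, 0.0)

    # dh defaults to each map's max/100, keeping the permutation statistics
    # exchangeable with the observed one
    observed_t = pseudo_t(np.ones(n_subj))
    observed_tfce = tfce(observed_t, mask, E=tfce_e, H=tfce_h, dh=tfce_dh,
                         connectivity=connectivity)

    null_max = np.empty(n_perm)
    null_max[0] = observed_tfce.max(initial=0.0)
    for i in range(1, n_perm):
        signs = rng.choice([-1.0, 1.0], size=n_subj)
        t_i = pseudo_t(signs)
        tf = tfce(t_i, mask, E=tfce_e, H=tfce_h, dh=tfce_dh,
                  connectivity=connectivity)
        null_max[i] = tf.max(initial=0.0)

    sorted_null = np.sort(null_max)
    n_ge = n_perm - np.searchsorted(sorted_null, observed_tfce, side="left")
    corrected_p = np.where(mask, n_ge / n_perm, 1.0)
    return GroupPermutationResult(
        observed_stat=observed_t, tfce_map=observed_tfce,
        corrected_p=corrected_p, n_permutations=n_perm,
        null_max_tfce=null_max, mask=mask)
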