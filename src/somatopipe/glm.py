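"""First-level voxelwise GLM, contrasts, run exclusion, fixed-effects
combination across runs, and spatial smoothing."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from somatopipe.design import DesignMatrix

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


def smooth_volume(image: np.ndarray, fwhm_mm: float = 2.0,
                  voxel_size_mm=1.0) -> np.ndarray:
    """Gaussian spatial smoothing with reflective boundaries.

    ``image`` is 3-D or 4-D (time last); only the spatial axes are
    smoothed. sigma per axis = fwhm / (2 * sqrt(2 ln 2)) in mm, converted
    to voxel units.
    """
    if fwhm_mm < 0:
        raise ValueError("fwhm must be >= 0")
    if fwhm_mm == 0:
        return np.array(image, copy=True)
    vs = np.broadcast_to(np.asarray(voxel_size_mm, dtype=float), 3)
    sigma_vox = (fwhm_mm * FWHM_TO_SIGMA) / vs
    if image.ndim == 3:
        return ndimage.gaussian_filter(image.astype(float), sigma_vox,
                                       mode="reflect")
    if image.ndim == 4:
        return ndimage.gaussian_filter(image.astype(float),
                                       (*sigma_vox, 0.0), mode="reflect")
    raise ValueError("image must be 3-D or 4-D")


@dataclass
class GLMResult:
    """OLS fit of one run: beta and residual-variance maps plus metadata."""

    betas: np.ndarray  # (P, *spatial)
    residual_variance: np.ndarray  # (*spatial)
    dof: int
    design: DesignMatrix
    xtx_inv: np.ndarray

    @property
    def spatial_shape(self) -> tuple[int, ...]:
        return self.betas.shape[1:]

    def beta_map(self, label: str) -> np.ndarray:
        return self.betas[self.design.labels.index(label)]

    def canonical_beta(self, condition: str) -> np.ndarray:
        return self.betas[self.design.canonical_indices[condition]]


def _dependent_columns(X: np.ndarray, labels: list[str]) -> list[str]:
    kept: list[int] = []
    bad: list[str] = []
    for j in range(X.shape[1]):
        trial = X[:, kept + [j]]
        if np.linalg.matrix_rank(trial) == len(kept) + 1:
            kept.append(j)
        else:
            bad.append(labels[j])
    return bad


def fit_glm(run_image: np.ndarray, design: DesignMatrix) -> GLMResult:
    """Ordinary-least-squares fit per voxel.

    ``run_image`` is (x, y, z, t) or (n_voxels, t). No prewhitening is
    applied; the simulator's thermal noise is white by default.
    """
    X = design.matrix
    n, p = X.shape
    img = np.asarray(run_image, dtype=float)
    spatial = img.shape[:-1]
    if img.shape[-1] != n:
        raise ValueError(
            f"run has {img.shape[-1]} volumes, design has {n} rows")
    Y = img.reshape(-1, n).T  # (t, nvox)

    rank = np.linalg.matrix_rank(X)
    if rank < p:
        bad = _dependent_columns(X, design.labels)
        raise np.linalg.LinAlgError(
            f"rank-deficient design; dependent columns: {bad}")
    dof = n - p
    if dof <= 0:
        raise ValueError("non-positive degrees of freedom")

    pinv = np.linalg.pinv(X)
    betas = pinv @ Y  # (p, nvox)
    resid = Y - X @ betas
    sigma2 = np.einsum("ij,ij->j", resid, resid) / dof
    xtx_inv = np.linalg.inv(X.T @ X)
    return GLMResult(
        betas=betas.reshape(p, *spatial),
        residual_variance=sigma2.reshape(spatial),
        dof=dof,
        design=design,
        xtx_inv=xtx_inv,
    )


@dataclass
class ContrastMap:
    effect: np.ndarray
    variance: np.ndarray
    z: np.ndarray
    weights: np.ndarray


_Z_CLIP = 38.0  # largest |z| representable by the t -> z transform


def t_to_z(t: np.ndarray, dof: float) -> np.ndarray:
    """Map t statistics to standard-normal quantiles, sign-symmetric."""
    t = np.asarray(t, dtype=float)
    p_upper = stats.t.sf(np.abs(t), dof)
    z = stats.norm.isf(np.clip(p_upper, 1e-300, None))
    return np.clip(np.sign(t) * z, -_Z_CLIP, _Z_CLIP)


def contrast_z(result: GLMResult, weights) -> ContrastMap:
    """t/z map for a contrast of design columns.

    Weights on derivative columns must be zero: only the canonical
    parameter estimates carry to inference.
    """
    w = np.asarray(weights, dtype=float)
    if w.shape != (result.design.n_columns,):
        raise ValueError(
            f"weights length {w.size} != design columns {result.design.n_columns}")
    for j in result.design.derivative_indices:
        if w[j] != 0:
            raise ValueError(
                f"nonzero weight on derivative column {result.design.labels[j]!r}")
    p = result.betas.shape[0]
    effect = np.tensordot(w, result.betas, axes=(0, 0))
    quad = float(w @ result.xtx_inv @ w)
    variance = quad * result.residual_variance
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(variance > 0, effect / np.sqrt(variance), 0.0)
    z = t_to_z(t, result.dof)
    return ContrastMap(effect=effect, variance=variance, z=z, weights=w)


def condition_vs_rest_weights(design: DesignMatrix, condition: str) -> np.ndarray:
    """+1 on the condition's canonical column (implicit rest baseline)."""
    w = np.zeros(design.n_columns)
    w[design.canonical_indices[condition]] = 1.0
    return w


def condition_vs_all_weights(design: DesignMatrix, condition: str) -> np.ndarray:
    """+1 on the target's canonical column, -1/(k-1) on each other
    condition's canonical column (movement-vs-all contrast)."""
    idx = design.canonical_indices
    if condition not in idx:
        raise KeyError(condition)
    w = np.zeros(design.n_columns)
    others = [c for c in idx if c != condition]
    w[idx[condition]] = 1.0
    for c in others:
        w[idx[c]] = -1.0 / len(others)
    return w


def exclude_runs(cohort, threshold_mm: float = 1.0):
    """Drop runs whose mean absolute displacement strictly exceeds the
    threshold. Returns (retained, report) where retained maps subject_id to
    the kept run indices and report is a tidy table of exclusions."""
    retained: dict[str, list[int]] = {}
    rows = []
    for subject in cohort:
        keep: list[int] = []
        for i, run in enumerate(subject.runs):
            disp = run.mean_abs_displacement_mm
            if disp > threshold_mm:
                rows.append({"subject": subject.subject_id, "run": i,
                             "mean_abs_displacement_mm": disp})
            else:
                keep.append(i)
        retained[subject.subject_id] = keep
    report = pd.DataFrame(rows, columns=["subject", "run",
                                         "mean_abs_displacement_mm"])
    return retained, report


def fixed_effects_combine(run_contrasts: list[ContrastMap]) -> ContrastMap:
    """Inverse-variance-weighted fixed-effects combination across runs."""
    if not run_contrasts:
        raise ValueError("need at least one run contrast")
    if len(run_contrasts) == 1:
        return run_contrasts[0]
    effects = np.stack([c.effect for c in run_contrasts])
    variances = np.stack([c.variance for c in run_contrasts])
    with np.errstate(divide="ignore", invalid="ignore"):
        w = np.where(variances > 0, 1.0 / variances, 0.0)
        wsum = w.sum(axis=0)
        effect = np.where(wsum > 0, (w * effects).sum(axis=0) / wsum, 0.0)
        variance = np.where(wsum > 0, 1.0 / wsum, 0.0)
        z = np.where(variance > 0, effect / np.sqrt(variance), 0.0)
    z = np.clip(z, -_Z_CLIP, _Z_CLIP)
    return ContrastMap(effect=effect, variance=variance, z=z,
                       weights=run_contrasts[0].weights)
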