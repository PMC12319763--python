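"""Across-participant multiclass decoding and searchlight mapping.

Decoding follows the convention of across-subject MVPA studies: one
canonical-HRF beta image per (subject, run, condition) is the sample; a
linear multiclass support vector machine (L2 regularisation, C = 1, no
tuning) is evaluated with leave-one-subject-out cross-validation.
Inference is by permutation: condition labels are shuffled within subject
(the exchangeable unit under LOSO) and the decoder refit. The searchlight
variant assigns each voxel the accuracy of a decoder restricted to a
spherical neighbourhood, and is corrected with a permutation
cluster-size procedure: a pooled voxelwise accuracy cutoff from the
permutation maps, then a maximum-cluster-size null.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from sklearn.model_selection import LeaveOneGroupOut
from sklearn.svm import LinearSVC

from somatopipe.univariate_stats import _structure

CLASSIFIER_CONFIG = {"kernel": "linear", "C": 1.0, "penalty": "l2"}


def _make_classifier():
    return LinearSVC(C=1.0, penalty="l2", random_state=0, max_iter=20_000)


@dataclass
class BetaSampleSet:
    """(subject, run, condition)-labelled beta vectors over a mask."""

    X: np.ndarray  # (n_samples, n_features)
    labels: np.ndarray  # condition per sample
    groups: np.ndarray  # subject per sample
    runs: np.ndarray
    mask: np.ndarray | None = None  # boolean 3-D feature mask

    def __post_init__(self):
        n = self.X.shape[0]
        if not (len(self.labels) == len(self.groups) == len(self.runs) == n):
            raise ValueError("labels, groups and runs must match sample count")
        if not np.all(np.isfinite(self.X)):
            raise ValueError("feature matrix contains missing values")
        all_classes = set(np.unique(self.labels))
        for subject in np.unique(self.groups):
            sel = self.groups == subject
            classes, counts = np.unique(self.labels[sel], return_counts=True)
            if set(classes) != all_classes or len(set(counts)) != 1:
                raise ValueError(
                    f"unbalanced condition labels within subject {subject!r}")

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    @property
    def classes(self) -> np.ndarray:
        return np.unique(self.labels)


def assemble_beta_samples(cohort_beta_maps, mask: np.ndarray) -> BetaSampleSet:
    """Stack canonical-HRF beta maps into the decoding feature table.

    ``cohort_beta_maps`` maps subject id to a sequence of per-run
    {condition: 3-D beta map} dicts. All mask voxels are retained
    regardless of intensity. With the default cohort (20 subjects x 4 runs
    x 3 conditions) this yields 240 samples.
    """
    X_rows, labels, groups, runs = [], [], [], []
    for subject, run_maps in cohort_beta_maps.items():
        for run_idx, cond_maps in enumerate(run_maps):
            for cond, beta in cond_maps.items():
                if beta.shape != mask.shape:
                    raise ValueError("beta map and mask grids differ")
                X_rows.append(np.asarray(beta, dtype=float)[mask])
                labels.append(cond)
                groups.append(subject)
                runs.append(run_idx)
    return BetaSampleSet(
        X=np.asarray(X_rows), labels=np.asarray(labels),
        groups=np.asarray(groups), runs=np.asarray(runs), mask=mask)


@dataclass
class DecodingResult:
    accuracy: float  # percent, mean over held-out folds
    fold_accuracies: np.ndarray
    confusion: pd.DataFrame  # rows true, columns predicted, counts
    classifier_config: dict = field(default_factory=lambda: dict(CLASSIFIER_CONFIG))

    def accuracy_from_confusion(self) -> float:
        c = self.confusion.to_numpy()
        return 100.0 * np.trace(c) / c.sum()


def _loso_predictions(X, y, groups):
    """Held-out predictions per LOSO fold; yields (test_idx, predictions)."""
    logo = LeaveOneGroupOut()
    for train, test in logo.split(X, y, groups):
        if len(np.unique(y[train])) < len(np.unique(y)):
            raise ValueError("a class is absent from the training folds")
        clf = _make_classifier()
        clf.fit(X[train], y[train])
        yield test, clf.predict(X[test])


def loso_decode(samples: BetaSampleSet) -> DecodingResult:
    """Leave-one-subject-out multiclass decoding.

    Folds are subjects: the classifier trains on all other subjects'
    samples and tests on the held-out subject. Returns mean fold accuracy
    (percent), per-fold accuracies, and the pooled confusion matrix.
    """
    if len(np.unique(samples.groups)) < 2:
        raise ValueError("need at least 2 subjects for LOSO")
    classes = samples.classes
    X, y, groups = samples.X, samples.labels, samples.groups
    fold_acc = []
    confusion = np.zeros((len(classes), len(classes)), dtype=int)
    class_idx = {c: i for i, c in enumerate(classes)}
    for test, pred in _loso_predictions(X, y, groups):
        fold_acc.append(float(np.mean(pred == y[test])) * 100.0)
        for yt, yp in zip(y[test], pred):
            confusion[class_idx[yt], class_idx[yp]] += 1
    conf = pd.DataFrame(confusion, index=classes, columns=classes)
    return DecodingResult(accuracy=float(np.mean(fold_acc)),
                          fold_accuracies=np.asarray(fold_acc),
                          confusion=conf)


def shuffle_labels_within_subject(labels, groups,
                                  rng: np.random.Generator) -> np.ndarray:
    """Permute condition labels within each subject (the exchangeable unit)."""
    labels = np.asarray(labels)
    shuffled = labels.copy()
    for subject in np.unique(groups):
        idx = np.flatnonzero(groups == subject)
        shuffled[idx] = labels[idx[rng.permutation(len(idx))]]
    return shuffled


@dataclass
class PermutationNull:
    null_accuracies: np.ndarray
    n_permutations: int
    seed: int
    observed_accuracy: float
    p_value: float  # proportion of null >= observed, floored at 1/n_perm

    @property
    def p_raw(self) -> float:
        return float(np.mean(self.null_accuracies >= self.observed_accuracy))

    def p_string(self) -> str:
        raw = self.p_raw
        if raw == 0.0:
            return f"p < {1.0 / self.n_permutations:g}"
        return f"p = {raw:g}"


def permutation_pvalue(
    samples: BetaSampleSet,
    n_perm: int = 1000,
    seed: int = 0,
    observed: float | None = None,
) -> PermutationNull:
    """Permutation null of LOSO decoding accuracy.

    Labels are shuffled within subject; the full LOSO decoder is refit per
    permutation. The empirical p value is the proportion of null
    accuracies >= the observed accuracy, floored at 1/n_perm.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if observed is None:
        observed = loso_decode(samples).accuracy
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for i in range(n_perm):
        labels = shuffle_labels_within_subject(samples.labels, samples.groups,
                                               rng)
        shuffled = BetaSampleSet(X=samples.X, labels=labels,
                                 groups=samples.groups, runs=samples.runs,
                                 mask=samples.mask)
        null[i] = loso_decode(shuffled).accuracy
    p = max(float(np.mean(null >= observed)), 1.0 / n_perm)
    return PermutationNull(null_accuracies=null, n_permutations=n_perm,
                           seed=seed, observed_accuracy=float(observed),
                           p_value=p)


# --- Searchlight -----------------------------------------------------------------


def sphere_offsets(radius_mm: float, voxel_size_mm=1.0) -> np.ndarray:
    """All integer voxel offsets within a world-space radius.

    Radius 3 mm at 1 mm voxels gives 123 offsets; radius 0 gives only the
    centre.
    """
    if radius_mm < 0:
        raise ValueError("radius must be >= 0")
    vs = np.broadcast_to(np.asarray(voxel_size_mm, dtype=float), 3)
    r_vox = np.floor(radius_mm / vs).astype(int)
    axes = [np.arange(-r, r + 1) for r in r_vox]
    grid = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3)
    dist = np.linalg.norm(grid * vs, axis=1)
    return grid[dist <= radius_mm + 1e-9]


def _loso_accuracy(X, y, groups) -> float:
    correct = total = 0
    for test, pred in _loso_predictions(X, y, groups):
        correct += int(np.sum(pred == y[test]))
        total += len(test)
    return 100.0 * correct / total


def searchlight_map(
    beta_stack: np.ndarray,
    labels,
    groups,
    mask: np.ndarray,
    radius_mm: float = 3.0,
    voxel_size_mm=1.0,
) -> np.ndarray:
    """Per-voxel LOSO multiclass accuracy within a spherical neighbourhood.

    ``beta_stack`` is (n_samples, x, y, z). For each mask voxel, features
    are the sphere-and-mask voxels around it and the decoder matches
    :func:`loso_decode` (pooled accuracy over held-out samples). Voxels
    outside the mask are NaN.
    """
    if not mask.any():
        raise ValueError("mask is empty")
    labels = np.asarray(labels)
    groups = np.asarray(groups)
    offsets = sphere_offsets(radius_mm, voxel_size_mm)
    shape = mask.shape
    feat_index = -np.ones(shape, dtype=int)
    coords = np.argwhere(mask)
    feat_index[mask] = np.arange(len(coords))
    F = beta_stack[:, mask]  # (n_samples, n_mask_voxels)

    out = np.full(shape, np.nan)
    for c in coords:
        neigh = c[None, :] + offsets
        ok = np.all((neigh >= 0) & (neigh < np.array(shape)[None, :]), axis=1)
        neigh = neigh[ok]
        fidx = feat_index[neigh[:, 0], neigh[:, 1], neigh[:, 2]]
        fidx = fidx[fidx >= 0]
        if len(fidx) < 1:
            continue
        out[tuple(c)] = _loso_accuracy(F[:, fidx], labels, groups)
    return out


def searchlight_permutation_maps(
    beta_stack: np.ndarray,
    labels,
    groups,
    mask: np.ndarray,
    n_perm: int,
    seed: int = 0,
    radius_mm: float = 3.0,
    voxel_size_mm=1.0,
) -> list[np.ndarray]:
    """Searchlight maps under within-subject label shuffling.

    One label shuffle per permutation map, reused across all sphere
    centres of that map.
    """
    rng = np.random.default_rng(seed)
    labels = np.asarray(labels)
    groups = np.asarray(groups)
    maps = []
    for _ in range(n_perm):
        shuffled = shuffle_labels_within_subject(labels, groups, rng)
        maps.append(searchlight_map(beta_stack, shuffled, groups, mask,
                                    radius_mm, voxel_size_mm))
    return maps


@dataclass
class Cluster:
    voxels: np.ndarray  # (k, 3) indices
    size: int
    peak_accuracy: float
    centroid: tuple[float, float, float]


@dataclass
class SearchlightResult:
    accuracy_map: np.ndarray
    radius_mm: float
    accuracy_cutoff: float
    cluster_size_cutoff: int
    clusters: list[Cluster]
    null_max_cluster_sizes: np.ndarray

    def cluster_table(self) -> pd.DataFrame:
        rows = [{"cluster": i + 1, "size": c.size,
                 "peak_accuracy": c.peak_accuracy,
                 "centroid_x": c.centroid[0], "centroid_y": c.centroid[1],
                 "centroid_z": c.centroid[2]}
                for i, c in enumerate(self.clusters)]
        return pd.DataFrame(rows, columns=["cluster", "size", "peak_accuracy",
                                           "centroid_x", "centroid_y",
                                           "centroid_z"])


def _max_cluster_size(binary: np.ndarray, structure: np.ndarray) -> int:
    labels, n = ndimage.label(binary, structure=structure)
    if n == 0:
        return 0
    sizes = np.bincount(labels.reshape(-1))
    sizes[0] = 0
    return int(sizes.max())


def cluster_correct_searchlight(
    observed_map: np.ndarray,
    permutation_maps: list[np.ndarray],
    mask: np.ndarray | None = None,
    alpha_voxel: float = 0.05,
    alpha_cluster: float = 0.05,
    radius_mm: float = 3.0,
    connectivity: int = 26,
) -> SearchlightResult:
    """Permutation cluster-size correction of a searchlight accuracy map.

    The voxelwise accuracy cutoff is the (1 - alpha_voxel) quantile of the
    pooled distribution of all voxels' accuracies across all permutation
    maps. Observed and permutation maps are thresholded at that cutoff;
    the cluster-size cutoff is the smallest size whose exceedance
    probability under the max-cluster-size null is <= alpha_cluster.
    Surviving observed clusters have size >= that cutoff.
    """
    if len(permutation_maps) < 100:
        warnings.warn("fewer than 100 permutation maps: correction is coarse",
                      stacklevel=2)
    if mask is None:
        mask = np.isfinite(observed_map)
    structure = _structure(connectivity)

    pooled = np.concatenate([pm[mask][np.isfinite(pm[mask])]
                             for pm in permutation_maps])
    cutoff = float(np.quantile(pooled, 1.0 - alpha_voxel))

    null_max = np.array([
        _max_cluster_size(np.nan_to_num(pm, nan=-np.inf) > cutoff, structure)
        for pm in permutation_maps])

    # smallest integer size s with P(max cluster >= s) <= alpha_cluster
    candidates = np.arange(1, null_max.max(initial=0) + 2)
    exceed = (null_max[None, :] >= candidates[:, None]).mean(axis=1)
    size_cutoff = int(candidates[np.argmax(exceed <= alpha_cluster)])

    supra = np.nan_to_num(observed_map, nan=-np.inf) > cutoff
    labels_arr, n_comp = ndimage.label(supra, structure=structure)
    clusters: list[Cluster] = []
    for lab in range(1, n_comp + 1):
        vox = np.argwhere(labels_arr == lab)
        if len(vox) < size_cutoff:
            continue
        vals = observed_map[labels_arr == lab]
        clusters.append(Cluster(
            voxels=vox, size=len(vox), peak_accuracy=float(np.max(vals)),
            centroid=tuple(vox.mean(axis=0))))
    clusters.sort(key=lambda c: -c.size)
    return SearchlightResult(
        accuracy_map=observed_map, radius_mm=radius_mm,
        accuracy_cutoff=cutoff, cluster_size_cutoff=size_cutoff,
        clusters=clusters, null_max_cluster_sizes=null_max)
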