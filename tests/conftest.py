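"""Shared fixtures: phantom atlases and simulated cohorts.

Heavy simulations are session-scoped so that decoding-ordering,
searchlight and permutation-null checks reuse one cohort. Problem sizes
are scaled to keep the suite deep but quick: the acquisition-like grid is
22^3 voxels at 1.8 mm, cohorts are 10 subjects.
"""

from __future__ import annotations

import numpy as np
import pytest

from somatopipe import mvpa, pipeline
from somatopipe import synthetic_data as synth


@pytest.fixture(scope="session")
def atlas18():
    """Phantom atlas on the acquisition-like 1.8 mm grid."""
    grid = synth.VolumeGrid.centered((22, 22, 22), 1.8)
    return synth.build_phantom_atlas(grid)


@pytest.fixture(scope="session")
def atlas_default():
    """Phantom atlas on the default 40^3 analysis grid at 1 mm."""
    return synth.build_phantom_atlas()


@pytest.fixture(scope="session")
def default_effect():
    return synth.EffectSpec()


@pytest.fixture(scope="session")
def calibrated_cohort(atlas18, default_effect):
    """10-subject, 4-run cohort at default effect sizes, with first-level
    GLM results and the generating patterns."""
    cohort = synth.generate_cohort(n_subjects=10, atlas=atlas18,
                                   effect=default_effect, seed=1, n_runs=4)
    cohort_glm = pipeline.fit_cohort(cohort)
    patterns = synth.make_condition_patterns(atlas18, default_effect, seed=1,
                                             n_subjects=10)
    return {"atlas": atlas18, "cohort": cohort, "glm": cohort_glm,
            "patterns": patterns, "effect": default_effect}


@pytest.fixture(scope="session")
def region_accuracies(calibrated_cohort):
    """LOSO decoding accuracy per region mask on the calibrated cohort."""
    atlas = calibrated_cohort["atlas"]
    out = {}
    for name in ("s1", "thalamus", "brainstem"):
        samples = mvpa.assemble_beta_samples(calibrated_cohort["glm"].beta_maps,
                                             atlas.mask(name))
        out[name] = mvpa.loso_decode(samples).accuracy
    return out


@pytest.fixture(scope="session")
def brainstem_permutation_null(atlas18, default_effect):
    """Within-subject label-shuffled LOSO null on a small cohort
    (10 subjects, 2 runs, brainstem mask, 200 permutations)."""
    cohort = synth.generate_cohort(n_subjects=10, atlas=atlas18,
                                   effect=default_effect, seed=3, n_runs=2)
    cohort_glm = pipeline.fit_cohort(cohort)
    samples = mvpa.assemble_beta_samples(cohort_glm.beta_maps,
                                         atlas18.mask("brainstem"))
    observed = mvpa.loso_decode(samples).accuracy
    return mvpa.permutation_pvalue(samples, n_perm=200, seed=7,
                                   observed=observed)


@pytest.fixture(scope="session")
def searchlight_correction(calibrated_cohort):
    """Searchlight map, permutation maps and cluster correction over the
    brainstem of the calibrated cohort (3 mm radius, 20 permutation maps)."""
    import warnings

    atlas = calibrated_cohort["atlas"]
    grid = atlas.grid
    full = np.ones(grid.shape, dtype=bool)
    samples = mvpa.assemble_beta_samples(calibrated_cohort["glm"].beta_maps,
                                         full)
    stack = samples.X.reshape(samples.n_samples, *grid.shape)
    mask = atlas.mask("brainstem")
    observed = mvpa.searchlight_map(stack, samples.labels, samples.groups,
                                    mask, radius_mm=3.0,
                                    voxel_size_mm=grid.voxel_size_mm)
    perms = mvpa.searchlight_permutation_maps(
        stack, samples.labels, samples.groups, mask, n_perm=20, seed=9,
        radius_mm=3.0, voxel_size_mm=grid.voxel_size_mm)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        result = mvpa.cluster_correct_searchlight(observed, perms, mask)
    truth = np.zeros(grid.shape, dtype=bool)
    for cond_map in calibrated_cohort["patterns"].templates.values():
        truth |= cond_map != 0
    truth &= mask
    return {"observed": observed, "result": result, "truth": truth,
            "mask": mask}
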