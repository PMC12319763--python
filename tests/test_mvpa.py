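"""Across-subject decoding, permutation inference, searchlight correction."""

import warnings

import numpy as np
import pytest

from somatopipe import mvpa


def make_samples(n_subjects=6, n_runs=2, n_features=10, separation=0.0,
                 seed=0, classes=("left_hand", "right_hand", "face")):
    """Synthetic beta samples with class means `separation` apart."""
    rng = np.random.default_rng(seed)
    means = {c: rng.standard_normal(n_features) * separation
             for c in classes}
    X, labels, groups, runs = [], [], [], []
    for s in range(n_subjects):
        for r in range(n_runs):
            for c in classes:
                X.append(means[c] + rng.standard_normal(n_features))
                labels.append(c)
                groups.append(f"sub{s}")
                runs.append(r)
    return mvpa.BetaSampleSet(X=np.asarray(X), labels=np.asarray(labels),
                              groups=np.asarray(groups), runs=np.asarray(runs))


class TestAssembleBetaSamples:
    @staticmethod
    def _beta_maps(n_subjects, n_runs, shape=(4, 4, 4), seed=0):
        rng = np.random.default_rng(seed)
        return {
            f"sub{s}": [
                {c: rng.standard_normal(shape)
                 for c in ("left_hand", "right_hand", "face")}
                for _ in range(n_runs)]
            for s in range(n_subjects)}

    def test_default_cohort_bookkeeping(self):
        maps = self._beta_maps(20, 4)
        mask = np.ones((4, 4, 4), dtype=bool)
        samples = mvpa.assemble_beta_samples(maps, mask)
        assert samples.n_samples == 240

    def test_single_run_single_subject(self):
        samples = mvpa.assemble_beta_samples(self._beta_maps(1, 1),
                                             np.ones((4, 4, 4), bool))
        assert samples.n_samples == 3

    def test_feature_dimension_is_mask_size(self):
        mask = np.zeros((4, 4, 4), dtype=bool)
        mask.reshape(-1)[:50] = True
        samples = mvpa.assemble_beta_samples(self._beta_maps(2, 1), mask)
        assert samples.n_features == 50

    def test_unbalanced_labels_rejected(self):
        maps = self._beta_maps(2, 1)
        del maps["sub0"][0]["face"]
        with pytest.raises(ValueError, match="unbalanced"):
            mvpa.assemble_beta_samples(maps, np.ones((4, 4, 4), bool))


class TestLosoDecode:
    def test_separable_set_is_perfect(self):
        samples = make_samples(n_subjects=6, separation=8.0, seed=1)
        result = mvpa.loso_decode(samples)
        assert result.accuracy == 100.0
        assert result.confusion.to_numpy().trace() == samples.n_samples

    def test_fold_count_equals_subjects(self):
        samples = make_samples(n_subjects=20, separation=1.0, seed=2)
        result = mvpa.loso_decode(samples)
        assert len(result.fold_accuracies) == 20

    def test_shuffled_labels_at_chance(self):
        samples = make_samples(n_subjects=20, n_runs=4, separation=5.0, seed=3)
        rng = np.random.default_rng(4)
        shuffled = mvpa.shuffle_labels_within_subject(samples.labels,
                                                      samples.groups, rng)
        chance_set = mvpa.BetaSampleSet(X=samples.X, labels=shuffled,
                                        groups=samples.groups,
                                        runs=samples.runs)
        acc = mvpa.loso_decode(chance_set).accuracy
        assert acc == pytest.approx(100.0 / 3, abs=3.0)

    def test_confusion_consistency(self):
        samples = make_samples(n_subjects=8, separation=1.0, seed=5)
        result = mvpa.loso_decode(samples)
        assert result.accuracy == pytest.approx(
            result.accuracy_from_confusion(), abs=1e-9)
        row_sums = result.confusion.sum(axis=1)
        assert (row_sums == samples.n_samples // 3).all()

    def test_label_permutation_exchangeability(self):
        """Relabelling every sample through a fixed class permutation
        permutes the confusion matrix rows/columns identically."""
        samples = make_samples(n_subjects=5, separation=2.0, seed=6)
        base = mvpa.loso_decode(samples)
        perm = {"left_hand": "face", "face": "right_hand",
                "right_hand": "left_hand"}
        relabeled = mvpa.BetaSampleSet(
            X=samples.X,
            labels=np.array([perm[l] for l in samples.labels]),
            groups=samples.groups, runs=samples.runs)
        swapped = mvpa.loso_decode(relabeled)
        classes = list(base.confusion.index)
        for a in classes:
            for b in classes:
                assert (swapped.confusion.loc[perm[a], perm[b]]
                        == base.confusion.loc[a, b])
        assert swapped.accuracy == pytest.approx(base.accuracy)

    def test_single_subject_rejected(self):
        samples = make_samples(n_subjects=1)
        with pytest.raises(ValueError, match="2 subjects"):
            mvpa.loso_decode(samples)


class TestPermutationPvalue:
    def test_p_strictly_inside_unit_interval(self):
        samples = make_samples(n_subjects=6, separation=0.6, seed=7)
        null = mvpa.permutation_pvalue(samples, n_perm=50, seed=8)
        if (null.observed_accuracy < null.null_accuracies.max()
                and null.observed_accuracy > null.null_accuracies.min()):
            assert 0.0 < null.p_value < 1.0

    def test_floor_rule(self):
        samples = make_samples(n_subjects=8, separation=10.0, seed=9)
        null = mvpa.permutation_pvalue(samples, n_perm=10, seed=10)
        assert null.p_raw == 0.0
        assert null.p_value == pytest.approx(1.0 / 10)
        assert null.p_string().startswith("p <")

    def test_null_length_and_determinism(self):
        samples = make_samples(n_subjects=5, separation=1.0, seed=11)
        a = mvpa.permutation_pvalue(samples, n_perm=20, seed=12)
        b = mvpa.permutation_pvalue(samples, n_perm=20, seed=12)
        assert len(a.null_accuracies) == 20
        np.testing.assert_array_equal(a.null_accuracies, b.null_accuracies)


class TestSphereOffsets:
    def test_zero_radius_is_centre_only(self):
        offsets = mvpa.sphere_offsets(0.0, 1.0)
        assert offsets.shape == (1, 3)
        np.testing.assert_array_equal(offsets[0], 0)

    def test_three_mm_at_one_mm_voxels_by_lattice_enumeration(self):
        offsets = mvpa.sphere_offsets(3.0, 1.0)
        # exhaustive lattice oracle
        count = 0
        for i in range(-3, 4):
            for j in range(-3, 4):
                for k in range(-3, 4):
                    if i * i + j * j + k * k <= 9:
                        count += 1
        assert count == 123
        assert len(offsets) == 123

    def test_isotropic_acquisition_voxels(self):
        offsets = mvpa.sphere_offsets(1.8, 1.8)
        assert len(offsets) == 7  # centre + 6 face neighbours

    def test_anisotropic_voxels(self):
        offsets = mvpa.sphere_offsets(2.0, (1.0, 2.0, 2.0))
        dist = np.linalg.norm(offsets * np.array([1.0, 2.0, 2.0]), axis=1)
        assert np.all(dist <= 2.0 + 1e-9)
        assert len(offsets) == 5 + 2 + 2  # x +-1,+-2; y +-1; z +-1


class TestSearchlight:
    def _stack_with_signal(self, mask, signal_vox, n_subjects=8, n_runs=2,
                           seed=0):
        rng = np.random.default_rng(seed)
        shape = mask.shape
        classes = ("left_hand", "right_hand", "face")
        class_maps = {c: np.zeros(shape) for c in classes}
        for c in classes:
            class_maps[c][signal_vox] = rng.standard_normal(
                signal_vox.sum()) * 3.0
        stack, labels, groups = [], [], []
        for s in range(n_subjects):
            for r in range(n_runs):
                for c in classes:
                    stack.append(class_maps[c] + rng.standard_normal(shape))
                    labels.append(c)
                    groups.append(f"sub{s}")
        return (np.asarray(stack), np.asarray(labels), np.asarray(groups))

    def test_accuracy_bounded(self):
        mask = np.ones((6, 6, 6), dtype=bool)
        sig = np.zeros((6, 6, 6), dtype=bool)
        sig[2:4, 2:4, 2:4] = True
        stack, labels, groups = self._stack_with_signal(mask, sig)
        out = mvpa.searchlight_map(stack, labels, groups, mask,
                                   radius_mm=1.0, voxel_size_mm=1.0)
        vals = out[np.isfinite(out)]
        assert np.all((vals >= 0) & (vals <= 100))

    def test_signal_region_beats_noise_region(self):
        mask = np.ones((8, 8, 8), dtype=bool)
        sig = np.zeros((8, 8, 8), dtype=bool)
        sig[2:5, 2:5, 2:5] = True
        stack, labels, groups = self._stack_with_signal(mask, sig, seed=1)
        out = mvpa.searchlight_map(stack, labels, groups, mask,
                                   radius_mm=1.5, voxel_size_mm=1.0)
        assert np.nanmean(out[sig]) > np.nanmean(out[~sig]) + 10.0

    def test_pure_noise_near_chance(self):
        mask = np.ones((6, 6, 6), dtype=bool)
        sig = np.zeros((6, 6, 6), dtype=bool)  # no signal anywhere
        stack, labels, groups = self._stack_with_signal(mask, sig,
                                                        n_subjects=10, seed=2)
        out = mvpa.searchlight_map(stack, labels, groups, mask,
                                   radius_mm=1.0, voxel_size_mm=1.0)
        assert np.nanmean(out) == pytest.approx(100.0 / 3, abs=2.0)

    def test_whole_mask_radius_equals_roi_decode(self):
        mask = np.zeros((5, 5, 5), dtype=bool)
        mask[1:4, 1:4, 2] = True
        sig = mask.copy()
        stack, labels, groups = self._stack_with_signal(mask, sig,
                                                        n_subjects=5, seed=3)
        out = mvpa.searchlight_map(stack, labels, groups, mask,
                                   radius_mm=50.0, voxel_size_mm=1.0)
        samples = mvpa.BetaSampleSet(
            X=stack[:, mask], labels=labels, groups=groups,
            runs=np.zeros(len(labels), dtype=int))
        correct = 0
        total = 0
        for test, pred in mvpa._loso_predictions(samples.X, labels, groups):
            correct += int(np.sum(pred == labels[test]))
            total += len(test)
        roi_acc = 100.0 * correct / total
        np.testing.assert_allclose(out[mask], roi_acc)


class TestClusterCorrection:
    def test_observed_equal_to_null_yields_nothing(self):
        rng = np.random.default_rng(13)
        mask = np.ones((8, 8, 8), dtype=bool)
        m = rng.uniform(30, 40, (8, 8, 8))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = mvpa.cluster_correct_searchlight(m, [m.copy()
                                                       for _ in range(50)],
                                                   mask)
        assert res.clusters == []

    def test_false_positive_rate_under_exchangeable_null(self):
        """30 pure-noise replicates, 200 permutation maps each: the chance
        of any surviving cluster stays within Monte-Carlo range of the
        nominal 0.05."""
        rng = np.random.default_rng(14)
        mask = np.ones((14, 14, 14), dtype=bool)
        fp = 0
        for _ in range(30):
            observed = rng.normal(33.3, 5.0, (14, 14, 14))
            perms = [rng.normal(33.3, 5.0, (14, 14, 14)) for _ in range(200)]
            res = mvpa.cluster_correct_searchlight(observed, perms, mask)
            fp += bool(res.clusters)
        assert fp / 30 <= 0.10

    def test_surviving_clusters_respect_cutoffs(self):
        rng = np.random.default_rng(15)
        mask = np.ones((10, 10, 10), dtype=bool)
        observed = rng.normal(33.3, 5.0, (10, 10, 10))
        observed[2:6, 2:6, 2:6] += 30.0
        perms = [rng.normal(33.3, 5.0, (10, 10, 10)) for _ in range(150)]
        res = mvpa.cluster_correct_searchlight(observed, perms, mask)
        assert res.clusters, "injected block should survive"
        for c in res.clusters:
            assert c.size >= res.cluster_size_cutoff
            vals = observed[tuple(c.voxels.T)]
            assert np.all(vals > res.accuracy_cutoff)

    def test_cluster_table_columns(self):
        rng = np.random.default_rng(16)
        mask = np.ones((8, 8, 8), dtype=bool)
        observed = rng.normal(33.3, 5.0, (8, 8, 8))
        observed[2:6, 2:6, 2:6] += 40.0
        perms = [rng.normal(33.3, 5.0, (8, 8, 8)) for _ in range(120)]
        res = mvpa.cluster_correct_searchlight(observed, perms, mask)
        tab = res.cluster_table()
        assert list(tab.columns) == ["cluster", "size", "peak_accuracy",
                                     "centroid_x", "centroid_y", "centroid_z"]


class TestCohortDecoding:
    def test_accuracy_ordering_mirrors_snr_gradient(self, region_accuracies):
        """On the default synthetic cohort the across-subject decoding
        accuracies order S1 > thalamus > brainstem > chance."""
        acc = region_accuracies
        assert acc["s1"] > acc["thalamus"] > acc["brainstem"]
        assert acc["brainstem"] > 100.0 / 3 + 2.0

    def test_permutation_null_centred_on_chance(self,
                                                brainstem_permutation_null):
        null = brainstem_permutation_null
        assert null.null_accuracies.mean() == pytest.approx(100.0 / 3,
                                                            abs=1.5)

    def test_searchlight_recall_of_active_voxels(self, searchlight_correction):
        """Surviving searchlight clusters recover at least half of the
        ground-truth active voxels at the default effect sizes."""
        res = searchlight_correction["result"]
        truth = searchlight_correction["truth"]
        surviving = np.zeros(truth.shape, dtype=bool)
        for c in res.clusters:
            surviving[tuple(c.voxels.T)] = True
        recall = (surviving & truth).sum() / truth.sum()
        assert recall >= 0.5

    def test_snr_monotonicity(self, atlas18):
        """Brainstem decoding accuracy is non-decreasing in brainstem SNR
        over a 3-point sweep at matched seeds (2-point tolerance)."""
        from somatopipe import pipeline
        from somatopipe import synthetic_data as synth

        accs = []
        for snr in (0.02, 0.05, 0.125):
            eff = synth.EffectSpec(snr_brainstem=snr)
            cohort = synth.generate_cohort(n_subjects=10, atlas=atlas18,
                                           effect=eff, seed=5, n_runs=2)
            cg = pipeline.fit_cohort(cohort)
            samples = mvpa.assemble_beta_samples(cg.beta_maps,
                                                 atlas18.mask("brainstem"))
            accs.append(mvpa.loso_decode(samples).accuracy)
        assert accs[1] >= accs[0] - 2.0
        assert accs[2] >= accs[1] - 2.0
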