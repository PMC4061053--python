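"""Pattern construction, cross-validated decoding and permutation nulls."""

import numpy as np
import pandas as pd
import pytest

from dsfm_attention import bold, design, mvpa


@pytest.fixture(scope="module")
def preprocessed_v1(tiny_dataset):
    stat = mvpa.localizer_stats(tiny_dataset)
    voxels = mvpa.select_voxels(stat, tiny_dataset.roi_mask("V1", "left"), k=40)
    ts = mvpa.extract_timeseries(tiny_dataset, voxels)
    ts, _ = mvpa.preprocess(ts, tiny_dataset.volumes_per_scan)
    return ts


class TestSelectVoxels:
    def test_known_top_k_recovered_exactly(self):
        rng = np.random.default_rng(0)
        stat = rng.normal(size=(6, 6, 3))
        mask = np.ones_like(stat, dtype=bool)
        top = np.argsort(-stat.ravel(), kind="stable")[:10]
        assert set(mvpa.select_voxels(stat, mask, k=10)) == set(top)

    def test_k_equals_mask_size_returns_whole_mask(self):
        stat = np.zeros((4, 4, 2))
        mask = np.zeros_like(stat, dtype=bool)
        mask[:2] = True
        out = mvpa.select_voxels(stat, mask, k=int(mask.sum()))
        assert set(out) == set(np.flatnonzero(mask.ravel()))

    def test_selection_restricted_to_mask(self, tiny_dataset):
        stat = mvpa.localizer_stats(tiny_dataset)
        mask = tiny_dataset.roi_mask("V1", "left")
        out = mvpa.select_voxels(stat, mask, k=40)
        assert np.all(mask.ravel()[out])

    def test_small_mask_rejected_with_size(self):
        stat = np.zeros((3, 3, 1))
        mask = np.zeros_like(stat, dtype=bool)
        mask[0, 0, 0] = True
        with pytest.raises(ValueError, match="1 voxel"):
            mvpa.select_voxels(stat, mask, k=5)


class TestPreprocess:
    def test_voxel_means_zero_and_roi_mean_projected_out(self, preprocessed_v1,
                                                         tiny_dataset):
        ts = preprocessed_v1
        vps = tiny_dataset.volumes_per_scan
        for s in range(ts.shape[1] // vps):
            blk = ts[:, s * vps:(s + 1) * vps]
            assert np.allclose(blk.mean(axis=1), 0.0, atol=1e-10)
            m = blk.mean(axis=0)
            assert np.abs(blk @ m).max() < 1e-8
            assert np.all(blk.std(axis=1) <= 1.0 + 1e-9)

    def test_zero_variance_voxel_excluded(self):
        ts = np.vstack([np.random.default_rng(0).normal(size=(3, 40)),
                        np.zeros((1, 40))])
        out, kept = mvpa.preprocess(ts)
        assert out.shape[0] == 3
        assert 3 not in kept

    def test_shared_mean_only_signal_is_abolished(self):
        # uniform additive gain with no voxel heterogeneity: after removing
        # the ROI-mean course no usable class information remains, so the
        # classifier never lands significantly above its permutation null
        # (estimation noise can push it below chance, never reliably above)
        d = design.build_design(seed=5, n_scans=2)
        p = bold.SimulationParams(gain_dispersion=0.0, w_dir_sd=0.0,
                                  g_att=3.0)
        ds = bold.simulate_dataset(d, bold.make_rois((10, 8, 4),
                                                     ("V1", "hMT+")), p,
                                   seed=6)
        res, perm = mvpa.decode(ds, "V1", "left", "attended_vs_unattended",
                                k=40, iterations=20, seed=0, n_perm=200)
        assert res.mean_accuracy <= 0.55
        assert res.mean_accuracy <= perm.null_ci[1]


class TestBuildPatterns:
    def test_pairing_halves_the_trial_count(self, preprocessed_v1,
                                            tiny_dataset):
        rng = np.random.default_rng(0)
        ps = mvpa.build_patterns(preprocessed_v1, tiny_dataset.events,
                                 "same_vs_different", "right",
                                 tiny_dataset.volumes_per_scan, rng=rng)
        # 2 scans x 20 contralateral-unattended blocks x 4 trials -> /2
        assert ps.n_patterns == 80
        assert sorted(np.unique(ps.y)) == ["different", "same"]
        counts = pd.Series(ps.y).value_counts()
        assert (counts == 40).all()

    def test_spatial_set_twice_the_feature_set(self, preprocessed_v1,
                                               tiny_dataset):
        rng = np.random.default_rng(1)
        spatial = mvpa.build_patterns(preprocessed_v1, tiny_dataset.events,
                                      "attended_vs_unattended", "right",
                                      tiny_dataset.volumes_per_scan, rng=rng)
        feature = mvpa.build_patterns(preprocessed_v1, tiny_dataset.events,
                                      "same_vs_different", "right",
                                      tiny_dataset.volumes_per_scan, rng=rng)
        assert spatial.n_patterns == 2 * feature.n_patterns

    def test_provenance_has_two_distinct_trials_per_pattern(
            self, preprocessed_v1, tiny_dataset):
        rng = np.random.default_rng(2)
        ps = mvpa.build_patterns(preprocessed_v1, tiny_dataset.events,
                                 "cw_vs_ccw", "right",
                                 tiny_dataset.volumes_per_scan, rng=rng)
        for pair in ps.provenance:
            assert len(pair) == 2 and pair[0] != pair[1]

    def test_patterns_stay_within_their_block(self, preprocessed_v1,
                                              tiny_dataset):
        rng = np.random.default_rng(3)
        ps = mvpa.build_patterns(preprocessed_v1, tiny_dataset.events,
                                 "attended_vs_unattended", "right",
                                 tiny_dataset.volumes_per_scan, rng=rng)
        ev = tiny_dataset.events
        for pair, group in zip(ps.provenance, ps.groups):
            blocks = {int(ev.loc[t, "scan"]) * 10_000 + int(ev.loc[t, "block"])
                      for t in pair}
            assert blocks == {group}


class TestClassify:
    @staticmethod
    def _toy_patterns(separable, n=40, seed=0):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(n, 10))
        y = np.array(["a", "b"] * (n // 2))
        if separable:
            X[:, 0] = np.where(y == "a", 5.0, -5.0)
        return mvpa.PatternSet(X=X, y=y, comparison="toy",
                               provenance=[(i,) for i in range(n)],
                               groups=np.arange(n))

    def test_separable_patterns_reach_perfect_accuracy(self):
        res = mvpa.classify(self._toy_patterns(True), iterations=5, seed=0)
        assert res.mean_accuracy == 1.0

    def test_pure_noise_patterns_sit_at_chance(self):
        res = mvpa.classify(self._toy_patterns(False, n=80), iterations=50,
                            seed=1)
        assert res.mean_accuracy == pytest.approx(0.5, abs=0.07)

    def test_accuracy_monotone_in_attention_gain(self):
        # stronger spatial-attention gain -> better attended-vs-unattended
        # decoding (heterogeneous per-voxel gains survive mean projection)
        rois = bold.make_rois((10, 8, 4), ("V1", "hMT+"))
        accs = []
        for g_att in (0.0, 0.5, 2.0):
            means = []
            for seed in range(3):
                d = design.build_design(seed=10 + seed, n_scans=2)
                ds = bold.simulate_dataset(
                    d, rois, bold.SimulationParams(g_att=g_att), seed=20 + seed)
                r, _ = mvpa.decode(ds, "V1", "left", "attended_vs_unattended",
                                   k=40, iterations=10, seed=0)
                means.append(r.mean_accuracy)
            accs.append(np.mean(means))
        assert accs[0] == pytest.approx(0.5, abs=0.08)
        assert accs[2] > accs[1] - 0.02
        assert accs[2] > accs[0] + 0.1

    def test_direction_decoding_needs_direction_weights(self):
        rois = bold.make_rois((10, 8, 4), ("V1", "hMT+"))
        d = design.build_design(seed=8, n_scans=2)
        with_w = bold.simulate_dataset(
            d, rois, bold.SimulationParams(w_dir_sd=0.3), seed=30)
        without = bold.simulate_dataset(
            d, rois, bold.SimulationParams(w_dir_sd=0.0), seed=30)
        acc_w = mvpa.decode(with_w, "V1", "left", "cw_vs_ccw", k=40,
                            iterations=10, seed=0)[0].mean_accuracy
        acc_0 = mvpa.decode(without, "V1", "left", "cw_vs_ccw", k=40,
                            iterations=10, seed=0)[0].mean_accuracy
        assert acc_w > 0.7
        assert acc_0 == pytest.approx(0.5, abs=0.1)

    def test_fixed_seed_bit_reproducible(self, tiny_dataset):
        a, _ = mvpa.decode(tiny_dataset, "V1", "left",
                           "attended_vs_unattended", k=40, iterations=5,
                           seed=4)
        b, _ = mvpa.decode(tiny_dataset, "V1", "left",
                           "attended_vs_unattended", k=40, iterations=5,
                           seed=4)
        assert np.array_equal(a.accuracies, b.accuracies)

    def test_too_few_patterns_per_class_rejected(self):
        ps = self._toy_patterns(False, n=8)
        with pytest.raises(ValueError, match="too few"):
            mvpa.classify(ps, folds=5, iterations=1, seed=0)


class TestPermutationTest:
    def test_null_centered_at_chance(self):
        ps = TestClassify._toy_patterns(True, n=40, seed=2)
        res = mvpa.permutation_test(ps, n_perm=300, seed=0,
                                    observed_iterations=10)
        assert res.null_mean == pytest.approx(0.5, abs=0.03)
        assert res.null.size == 300

    def test_separable_signal_is_significant(self):
        ps = TestClassify._toy_patterns(True, n=40, seed=3)
        res = mvpa.permutation_test(ps, n_perm=300, seed=1,
                                    observed_iterations=10)
        assert res.observed_mean == 1.0
        assert res.significant

    def test_noise_is_not_significant(self):
        ps = TestClassify._toy_patterns(False, n=80, seed=4)
        res = mvpa.permutation_test(ps, n_perm=300, seed=2,
                                    observed_iterations=20)
        assert not res.significant

    def test_boundary_value_counts_as_non_significant(self):
        ps = TestClassify._toy_patterns(False, n=40, seed=5)
        res = mvpa.permutation_test(ps, n_perm=200, seed=3,
                                    observed_iterations=5)
        boundary = mvpa.PermutationResult(
            observed_mean=res.null_ci[1], null=res.null,
            null_mean=res.null_mean, null_ci=res.null_ci,
            significant=bool(res.null_ci[1] < res.null_ci[0]),
            n_perm=res.n_perm)
        assert not boundary.significant

    def test_small_n_perm_warns(self):
        ps = TestClassify._toy_patterns(False, n=40, seed=6)
        with pytest.warns(UserWarning, match="unstable"):
            mvpa.permutation_test(ps, n_perm=50, seed=4,
                                  observed_iterations=2)
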