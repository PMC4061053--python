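"""High-pass filter, GLM, %BOLD extraction and ROI statistics."""

import numpy as np
import pandas as pd
import pytest

from dsfm_attention import bold, design, univariate


class TestHighpass:
    def test_linear_drift_removed_mean_preserved(self):
        t = np.arange(240)
        ts = 5.0 + 0.01 * t
        for method in ("dct", "gaussian"):
            out = univariate.highpass(ts, cutoff=100.0, tr=4.0, method=method)
            assert out.mean() == pytest.approx(ts.mean(), abs=1e-6)
            assert np.abs(np.polyfit(t, out, 1)[0]) < 2e-4

    def test_block_frequency_signal_passes(self):
        # a 96-s period component must survive a 100-s cutoff (< 5% loss)
        t = np.arange(240) * 4.0
        sig = np.sin(2 * np.pi * t / 96.0)
        out = univariate.highpass(sig, cutoff=100.0, tr=4.0)
        assert np.linalg.norm(out) >= 0.95 * np.linalg.norm(sig)

    def test_white_noise_variance_reduced(self):
        rng = np.random.default_rng(0)
        ts = rng.normal(size=240)
        out = univariate.highpass(ts, cutoff=100.0, tr=4.0)
        assert out.var() < ts.var()
        assert out.mean() == pytest.approx(ts.mean(), abs=1e-9)

    def test_invalid_cutoff_rejected(self):
        with pytest.raises(ValueError):
            univariate.highpass(np.zeros(100), cutoff=6.0, tr=4.0)


class TestGlm:
    def test_noiseless_betas_recover_gains_to_machine_precision(
            self, noiseless_dataset):
        fit = univariate.fit_glm(noiseless_dataset, 0)
        p = noiseless_dataset.ground_truth["params"]
        for roi in noiseless_dataset.rois:
            pct = univariate.roi_percent_bold(noiseless_dataset, fit, roi)
            contra = bold.contralateral_side(roi.hemisphere)
            ipsi = "left" if contra == "right" else "right"
            assert pct[f"attend_{contra}_same"] == pytest.approx(
                p["g_stim"] + p["g_att"], abs=1e-10)
            assert pct[f"attend_{contra}_different"] == pytest.approx(
                p["g_stim"] + p["g_att"], abs=1e-10)
            assert pct[f"attend_{ipsi}_same"] == pytest.approx(
                p["g_stim"] + p["g_feat"], abs=1e-10)
            assert pct[f"attend_{ipsi}_different"] == pytest.approx(
                p["g_stim"], abs=1e-10)

    def test_derivatives_leave_condition_betas_unchanged(
            self, noiseless_dataset):
        with_d = univariate.fit_glm(noiseless_dataset, 0, derivatives=True)
        without = univariate.fit_glm(noiseless_dataset, 0, derivatives=False)
        for cond in design.ACTIVE_CONDITIONS:
            i = with_d.columns.index(cond)
            j = without.columns.index(cond)
            assert np.allclose(with_d.betas[:, i], without.betas[:, j],
                               atol=1e-8)

    def test_collinear_confound_named_in_error(self, noiseless_dataset):
        ones = np.ones(noiseless_dataset.volumes_per_scan)
        with pytest.raises(ValueError, match="confound_0|intercept"):
            univariate.fit_glm(noiseless_dataset, 0, confounds=ones)

    def test_residuals_orthogonal_to_design(self, tiny_dataset):
        fit = univariate.fit_glm(tiny_dataset, 0)
        X = fit.design.to_numpy()
        dots = fit.residuals @ X  # (n_vox, p)
        assert np.abs(dots).max() < 1e-6 * np.abs(tiny_dataset.data).max()

    def test_prewhitening_estimates_positive_autocorrelation(self, tiny_dataset):
        fit = univariate.fit_glm(tiny_dataset, 0, prewhiten=True)
        assert fit.ar1_rho is not None
        assert 0.0 < fit.ar1_rho < 0.6

    def test_percent_bold_scale_invariant(self, noiseless_dataset):
        scaled = bold.BoldDataset(
            data=noiseless_dataset.data * 3.7,
            tr=noiseless_dataset.tr,
            roi_labels=noiseless_dataset.roi_labels,
            rois=noiseless_dataset.rois,
            events=noiseless_dataset.events,
            n_scans=noiseless_dataset.n_scans,
            volumes_per_scan=noiseless_dataset.volumes_per_scan,
            ground_truth=noiseless_dataset.ground_truth)
        a = univariate.roi_percent_bold(
            noiseless_dataset, univariate.fit_glm(noiseless_dataset, 0),
            noiseless_dataset.rois[0])
        b = univariate.roi_percent_bold(
            scaled, univariate.fit_glm(scaled, 0), scaled.rois[0])
        for cond in a:
            assert a[cond] == pytest.approx(b[cond], abs=1e-9)


class TestConditionTable:
    def test_contrast_columns_match_generating_gains(self, noiseless_dataset):
        table = univariate.condition_table(noiseless_dataset)
        p = noiseless_dataset.ground_truth["params"]
        row = table.iloc[0]
        assert row["attended"] == pytest.approx(p["g_stim"] + p["g_att"],
                                                abs=1e-9)
        assert row["unattended"] == pytest.approx(
            p["g_stim"] + p["g_feat"] / 2, abs=1e-9)
        assert (row["unattended_same"] - row["unattended_different"]
                == pytest.approx(p["g_feat"], abs=1e-9))

    def test_attended_exceeds_unattended_across_noisy_seeds(self):
        rois = bold.make_rois((8, 7, 2),
                              ("V1", "V2", "V3", "hV4", "V3a/b", "V7", "hMT+"))
        wins = 0
        n_seeds = 12
        for seed in range(n_seeds):
            d = design.build_design(seed=seed, n_scans=1)
            ds = bold.simulate_dataset(
                d, rois, bold.SimulationParams(noise_sd=0.3), seed=200 + seed)
            t = univariate.condition_table(ds)
            wins += (t["attended"].mean() > t["unattended"].mean())
        assert wins == n_seeds

    def test_session_pooling_halves_replicates(self, tiny_dataset):
        by_scan = univariate.condition_table(tiny_dataset, pool="scan")
        by_sess = univariate.condition_table(tiny_dataset, pool="session")
        assert len(by_sess) == len(by_scan) / 2


class TestRoiStats:
    @staticmethod
    def _null_table(seed, n_rep=15, effect_att=0.0, effect_feat=0.0):
        rng = np.random.default_rng(seed)
        rows = []
        for roi in ("V1", "V2", "V3"):
            base = rng.normal(1.0, 0.1, n_rep)
            rows.append(pd.DataFrame({
                "roi": roi, "replicate": np.arange(n_rep),
                "attended": base + effect_att + rng.normal(0, 0.05, n_rep),
                "unattended": base + rng.normal(0, 0.05, n_rep),
                "unattended_same": base + effect_feat
                + rng.normal(0, 0.05, n_rep),
                "unattended_different": base + rng.normal(0, 0.05, n_rep),
            }))
        return pd.concat(rows, ignore_index=True)

    def test_identical_pairs_give_p_one(self):
        table = self._null_table(0)
        table["unattended"] = table["attended"]
        out = univariate.roi_stats(table)
        att = out[out["test"] == "attended_vs_unattended"]
        assert (att["p"] == 1.0).all()
        assert not att["significant"].any()

    def test_spatial_attention_power_on_simulated_datasets(self):
        # g_att = 0.5%, noise SD 0.2%, 15 replicates: the attended-vs-
        # unattended contrast should survive Bonferroni in nearly every run
        rois = bold.make_rois((8, 7, 2),
                              ("V1", "V2", "V3", "hV4", "V3a/b", "V7", "hMT+"))
        hits = 0
        n_runs = 8
        for seed in range(n_runs):
            d = design.build_design(seed=seed, n_scans=15)
            ds = bold.simulate_dataset(
                d, rois, bold.SimulationParams(noise_sd=0.2), seed=300 + seed)
            table = univariate.condition_table(ds)
            out = univariate.roi_stats(table)
            att = out[out["test"] == "attended_vs_unattended"]
            hits += att["significant"].all()
        assert hits >= int(0.9 * n_runs)

    def test_too_few_replicates_rejected(self):
        with pytest.raises(ValueError):
            univariate.roi_stats(self._null_table(1, n_rep=3))

    def test_ks_normality_reported(self):
        out = univariate.roi_stats(self._null_table(2))
        assert out["ks_normality_p"].between(0, 1).all()

    def test_bonferroni_scales_uncorrected_p(self):
        out = univariate.roi_stats(self._null_table(3), n_areas=7)
        assert np.allclose(out["p_corrected"],
                           np.minimum(1.0, out["p"] * 7))


class TestGainRecovery:
    def test_single_dataset_recovery_close(self):
        d = design.build_design(seed=1, n_scans=6)
        rois = bold.make_rois((8, 7, 2),
                              ("V1", "V2", "V3", "hV4", "V3a/b", "V7", "hMT+"))
        ds = bold.simulate_dataset(d, rois,
                                   bold.SimulationParams(noise_sd=0.2),
                                   seed=42)
        g = univariate.recover_gains(ds)
        assert g["g_stim"] == pytest.approx(1.0, rel=0.15)
        assert g["g_att"] == pytest.approx(0.5, rel=0.15)
        assert g["g_feat"] == pytest.approx(0.05, rel=0.5)
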