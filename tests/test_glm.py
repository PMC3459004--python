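"""First-level model: HRF, design, AR(1), fitting, contrasts, smoothing."""

import numpy as np
import pandas as pd
import pytest

from dyadscan import glm
from dyadscan import synthetic as syn
from dyadscan.core import DyadscanError
from dyadscan.interbrain import roi_mean_series


def events_df(rows):
    return pd.DataFrame(rows, columns=["onset", "duration", "trial_type"])


class TestHrf:
    def test_peak_near_five_seconds(self):
        over = 50
        h = glm.canonical_hrf(3.0, oversampling=over)
        assert np.argmax(h) * 3.0 / over == pytest.approx(5.0, abs=0.2)
        assert h.max() == pytest.approx(1.0)

    def test_first_gamma_integral_positive(self):
        h = glm.canonical_hrf(1.0, oversampling=10, undershoot_ratio=0.0)
        assert h.sum() > 0

    def test_matches_reference_double_gamma(self):
        # independent oracle: nilearn's SPM-convention kernel
        nilearn_hrf = pytest.importorskip("nilearn.glm.first_level").spm_hrf
        over = 16
        ours = glm.canonical_hrf(3.0, oversampling=over)
        ref = nilearn_hrf(3.0, oversampling=over)[: len(ours)]
        ref = ref / ref.max()
        # sampling-grid conventions differ by a fraction of a sample
        assert np.corrcoef(ours, ref)[0, 1] > 0.99
        assert abs(int(np.argmax(ours)) - int(np.argmax(ref))) <= 2

    def test_block_periodic_boxcar_dominant_frequency(self):
        """A 15 s-periodic stimulus convolved with the HRF keeps its
        fundamental at 1/15 ~ 0.067 Hz after TR sampling."""
        over, tr = 16, 3.0
        dt = tr / over
        t = np.arange(0, 480, dt)
        box = ((t % 15.0) < 7.5).astype(float)
        h = glm.canonical_hrf(tr, oversampling=over)
        y = np.convolve(box, h)[: len(box)][::over]
        f, p = glm.power_spectrum(y, tr)
        nz = f > 1e-9
        assert f[nz][np.argmax(p[nz])] == pytest.approx(1.0 / 15.0, abs=1e-9)


class TestDesign:
    def test_empty_events_gives_drift_and_intercept_only(self):
        dm = glm.build_design_matrix(events_df([]), 3.0, 80)
        assert all(c.startswith(("drift", "const")) for c in dm.columns)

    @pytest.mark.parametrize("n_vols,tr", [(80, 3.0), (128, 2.0), (40, 3.0)])
    def test_drift_column_count_matches_cutoff(self, n_vols, tr):
        # independent count: DCT frequencies k/(2*duration) below 1/128 Hz
        duration = n_vols * tr
        expected = sum(
            1
            for k in range(1, n_vols)
            if k / (2 * duration) <= 1.0 / 128.0 + 1e-12
        )
        dm = glm.build_design_matrix(events_df([]), tr, n_vols)
        n_drift = sum(c.startswith("drift") for c in dm.columns)
        assert n_drift == expected == int(np.floor(2 * duration / 128.0))

    def test_drift_columns_orthonormal(self):
        dm = glm.build_design_matrix(events_df([]), 3.0, 80)
        drift = dm.matrix[:, [c.startswith("drift") for c in dm.columns]]
        assert np.allclose(drift.T @ drift, np.eye(drift.shape[1]), atol=1e-10)

    def test_unknown_condition_rejected(self):
        ev = events_df([(0.0, 2.5, "XX")])
        with pytest.raises(DyadscanError, match="unknown condition"):
            glm.build_design_matrix(ev, 3.0, 80)

    def test_event_beyond_run_end_rejected(self):
        ev = events_df([(239.0, 5.0, "ES")])
        with pytest.raises(DyadscanError, match="inside the run"):
            glm.build_design_matrix(ev, 3.0, 80)

    def test_duplicate_condition_columns_are_rank_deficient(self):
        # two conditions with identical event trains -> identical columns
        ev = events_df([(10.0, 2.5, "ES"), (10.0, 2.5, "SBNc")])
        with pytest.raises(DyadscanError, match="rank deficient"):
            glm.build_design_matrix(ev, 3.0, 80)

    def test_highpass_transfer(self):
        """Drift basis removes >= 99% of 256 s-period power (quadrature
        average) and passes >= 95% of a 32 s-period sinusoid."""
        dm = glm.build_design_matrix(events_df([]), 3.0, 80)
        x = dm.matrix
        proj = x @ np.linalg.pinv(x)
        t = np.arange(80) * 3.0

        def residual_power(period):
            fr = []
            for s in (np.sin(2 * np.pi * t / period), np.cos(2 * np.pi * t / period)):
                r = s - proj @ s
                fr.append(np.sum(r**2) / np.sum(s**2))
            return np.mean(fr)

        assert residual_power(256.0) < 0.01
        assert residual_power(32.0) > 0.95


class TestAr1:
    def test_white_noise_rho_near_zero(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(100_000, 2))
        assert glm.estimate_ar1(x) == pytest.approx(0.0, abs=0.01)

    def test_ar_coefficient_recovery(self):
        rng = np.random.default_rng(1)
        x = syn.ar1_noise((100_000, 2), 0.3, rng)
        assert glm.estimate_ar1(x) == pytest.approx(0.30, abs=0.01)

    def test_prewhitening_removes_lag1_autocorrelation(self):
        rng = np.random.default_rng(2)
        x = syn.ar1_noise((50_000, 1), 0.4, rng)
        w = glm.whiten_ar1(x, 0.4)
        assert glm.estimate_ar1(w) == pytest.approx(0.0, abs=0.02)

    def test_constant_series_warns_and_returns_zero(self):
        with pytest.warns(UserWarning, match="constant"):
            assert glm.estimate_ar1(np.ones((50, 1))) == 0.0

    def test_too_short_series_rejected(self):
        with pytest.raises(DyadscanError):
            glm.estimate_ar1(np.zeros((2, 1)))


class TestFit:
    def test_noise_free_recovery_is_exact(self):
        ev = [
            events_df([(15.0 * b + 2.0, 2.5, c) for b, c in
                       enumerate(["ES", "BS", "SBNc", "ES", "BS", "SBNc"])])
            for _ in range(2)
        ]
        dm = glm.design_for_runs(ev, 3.0, 30)
        rng = np.random.default_rng(3)
        beta_true = rng.normal(size=(dm.matrix.shape[1], 5))
        y = dm.matrix @ beta_true
        res = glm.fit_glm(y, dm)
        assert np.allclose(res.beta, beta_true, atol=1e-8)

    def test_residuals_orthogonal_to_whitened_design(self, fitted_subject):
        res = fitted_subject["result"]
        design = fitted_subject["design"]
        wx = glm.whiten_ar1(design.matrix, res.rho, design.run_index)
        dots = np.abs(wx.T @ res.whitened_residuals)
        scale = np.linalg.norm(wx) * np.linalg.norm(res.whitened_residuals)
        assert dots.max() / scale < 1e-8

    def test_residual_series_length_after_drop2(self, fitted_subject):
        # 6 runs x (80 retained - 2 dropped) = 468
        assert fitted_subject["result"].residual_series.shape[0] == 468

    def test_length_mismatch_rejected(self):
        dm = glm.build_design_matrix(events_df([]), 3.0, 80)
        with pytest.raises(DyadscanError, match="volumes"):
            glm.fit_glm(np.zeros((79, 3)), dm)

    def test_rho_recovery_at_study_length(self):
        # direct estimator on an AR(1) series of the study's length
        rng = np.random.default_rng(6)
        x = syn.ar1_noise((468, 50), 0.3, rng)
        assert glm.estimate_ar1(x) == pytest.approx(0.3, abs=0.05)

    def test_fitted_rho_is_positive_but_attenuated(self, fitted_subject):
        # the design projection absorbs low-frequency autocorrelation, so
        # the pooled estimate sits below the generating 0.3
        assert 0.1 < fitted_subject["result"].rho <= 0.3


class TestContrasts:
    def test_zero_weights_give_zero_map(self, fitted_subject):
        res = fitted_subject["result"]
        c = glm.compute_contrast(res, np.zeros(res.beta.shape[0]))
        assert np.allclose(c.effect, 0.0)

    def test_primed_contrast_is_null_for_equal_betas(self):
        # ES and SBNc generated with the same amplitude -> ES' ~ 0
        cfg = syn.SimulationConfig(
            shape=(6, 6, 4),
            effect_sizes={"ES": {"OP": 1.0}, "SBNc": {"OP": 1.0}},
            noise_sd=0.05,
            block_transient_amp=0.0,
        )
        runs, evs = [], []
        for i in range(2):
            sched = syn.simulate_task_schedule(cfg, "concordant", seed=i)
            bold, _ = syn.simulate_dyad_bold(sched, sched, cfg, paired=False, seed=i)
            runs.append(bold.drop_leading(cfg.discard_leading))
            evs.append(sched.event_tables()[0])
        dm = glm.design_for_runs(evs, cfg.tr, runs[0].n_volumes)
        res = glm.fit_glm(np.concatenate([r.timeseries() for r in runs]), dm)
        roi = cfg.roi_masks()["OP"].reshape(-1)
        es_prime = glm.primed_contrast(res, "ES'")
        assert es_prime.effect[roi].mean() == pytest.approx(0.0, abs=0.1)

    def test_eye_cued_effect_sums_primed_contrasts(self):
        # beta_eye = 1, beta_ball = 0 in OP -> (ES'+EN')-(BS'+BN') ~ 2
        cfg = syn.SimulationConfig(
            shape=(6, 6, 4),
            effect_sizes={"ES": {"OP": 1.0}, "EN": {"OP": 1.0}},
            noise_sd=0.02,
            block_transient_amp=0.0,
        )
        runs, evs = [], []
        for i, rt in enumerate(["concordant", "discordant"] * 2):
            sched = syn.simulate_task_schedule(cfg, rt, seed=10 + i)
            bold, _ = syn.simulate_dyad_bold(sched, sched, cfg, paired=False, seed=30 + i)
            runs.append(bold.drop_leading(cfg.discard_leading))
            evs.append(sched.event_tables()[0])
        dm = glm.design_for_runs(evs, cfg.tr, runs[0].n_volumes)
        res = glm.fit_glm(np.concatenate([r.timeseries() for r in runs]), dm)
        roi = cfg.roi_masks()["OP"].reshape(-1)
        eff = glm.effect_contrast(res, "eye_cued")
        assert eff.effect[roi].mean() == pytest.approx(2.0, abs=0.1)

    def test_wrong_length_rejected(self, fitted_subject):
        with pytest.raises(DyadscanError, match="length"):
            glm.compute_contrast(fitted_subject["result"], np.zeros(3))


class TestLeakage:
    def test_unmodelled_block_transient_leaves_peak_at_block_rate(
        self, fitted_subject
    ):
        """The condition model does not capture the block-boundary
        response, so the residual spectrum peaks at 1/15 Hz; with a fully
        matched generative model the peak is absent."""
        res = fitted_subject["result"]
        design = fitted_subject["design"]
        cfg = fitted_subject["cfg"]
        roi = fitted_subject["rois"]["OP"]

        def peak_ratio(result):
            ps = []
            for r in np.unique(design.run_index):
                seg = result.whitened_residuals[design.run_index == r]
                s = roi_mean_series(seg, roi)
                f, p = glm.power_spectrum(s, cfg.tr)
                ps.append(p)
            p = np.mean(ps, axis=0)
            sel = f > 0.005
            at_block = p[np.argmin(np.abs(f - 1 / 15))]
            return f[sel][np.argmax(p[sel])], at_block / np.median(p[sel])

        f_peak, ratio = peak_ratio(res)
        assert f_peak == pytest.approx(1 / 15, abs=1e-9)
        assert ratio > 10

        # matched model: regenerate without the transient
        import dataclasses

        cfg0 = dataclasses.replace(cfg, block_transient_amp=0.0)
        runs0 = []
        for i, sched in enumerate(fitted_subject["schedules"]):
            bold, _ = syn.simulate_dyad_bold(sched, sched, cfg0, paired=False, seed=200 + i)
            runs0.append(bold.drop_leading(cfg0.discard_leading))
        res0 = glm.fit_glm(
            np.concatenate([r.timeseries() for r in runs0]), design
        )
        _, ratio0 = peak_ratio(res0)
        assert ratio0 < 5


class TestSmoothing:
    def test_zero_fwhm_is_identity(self):
        img = np.random.default_rng(0).normal(size=(6, 6, 4))
        assert np.array_equal(glm.gaussian_smooth(img, fwhm=0.0), img)

    def test_delta_spread_matches_sigma_relation(self):
        delta = np.zeros((15, 15, 15))
        delta[7, 7, 7] = 1.0
        sm = glm.gaussian_smooth(delta, fwhm=8.0, voxel_size=4.0)
        sigma_expected = 8.0 / (np.sqrt(8 * np.log(2)) * 4.0)
        prof = sm[:, 7, 7]
        x = np.arange(15) - 7
        sigma_emp = np.sqrt((prof * x**2).sum() / prof.sum())
        assert sigma_emp == pytest.approx(sigma_expected, rel=0.01)

    def test_sum_and_mean_preserved_variance_reduced(self):
        img = np.random.default_rng(1).normal(size=(16, 16, 12))
        sm = glm.gaussian_smooth(img, fwhm=8.0, voxel_size=4.0)
        assert abs(sm.sum() - img.sum()) / abs(img.sum()) < 1e-6
        assert sm.var() < img.var()

    def test_subvoxel_fwhm_warns(self):
        img = np.zeros((4, 4, 4))
        with pytest.warns(UserWarning, match="voxel"):
            glm.gaussian_smooth(img, fwhm=2.0, voxel_size=4.0)
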