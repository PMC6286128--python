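import numpy as np
import pytest
from scipy.optimize import minimize_scalar

import prfgain as pg
from prfgain.gauss import gaussian_divide, gaussian_product


class TestGaussianAlgebra:
    def test_product_closed_form_example(self):
        center, sigma, _ = gaussian_product(((2.0, 0.0), 1.0), ((0.0, 0.0), 2.0))
        np.testing.assert_allclose(center, [1.6, 0.0], atol=1e-12)
        assert sigma == pytest.approx(np.sqrt(4.0 / 5.0), abs=1e-12)

    def test_flat_gain_limit(self):
        center, sigma, _ = gaussian_product(((1.0, -0.5), 0.7), ((0.0, 0.0), 1e9))
        np.testing.assert_allclose(center, [1.0, -0.5], atol=1e-6)
        assert sigma == pytest.approx(0.7, rel=1e-6)

    def test_identical_centers_symmetry(self):
        center, sigma, scale = gaussian_product(((1.0, 1.0), 0.8), ((1.0, 1.0), 0.8))
        np.testing.assert_allclose(center, [1.0, 1.0])
        assert sigma == pytest.approx(0.8 / np.sqrt(2))
        assert scale == pytest.approx(1.0)

    def test_division_inverts_product(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            c = tuple(rng.uniform(-3, 3, 2))
            s = rng.uniform(0.2, 1.5)
            c_af, s_af = tuple(rng.uniform(-1, 1, 2)), rng.uniform(1.6, 3.0)
            pc, ps, _ = gaussian_product((c, s), (c_af, s_af))
            rc, rs = gaussian_divide((tuple(pc), ps), (c_af, s_af))
            np.testing.assert_allclose(rc, c, atol=1e-9)
            assert rs == pytest.approx(s, abs=1e-9)

    def test_division_requires_narrower_numerator(self):
        with pytest.raises(ValueError):
            gaussian_divide(((0.0, 0.0), 2.0), ((0.0, 0.0), 2.0))

    def test_smaller_gain_field_pulls_harder(self):
        """Static multiplication: shrinking the gain field strictly increases
        the shift of the product center toward the gain-field center."""
        pulls = []
        for s_af in (3.0, 2.0, 1.5, 1.0, 0.5):
            center, _, _ = gaussian_product(((2.0, 0.0), 1.0), ((0.0, 0.0), s_af))
            pulls.append(2.0 - center[0])
        assert all(b > a for a, b in zip(pulls, pulls[1:]))


class TestGroundTruthSampler:
    def test_zero_slope_zero_jitter_gives_constant_sigma(self):
        voxels = pg.sample_ground_truth_voxels(
            50, size_intercept=0.7, size_slope=0.0, size_jitter_sd=0.0, seed=0
        )
        assert all(v.sd_sigma == pytest.approx(0.7) for v in voxels)

    def test_size_slope_recovered_by_ols(self):
        voxels = pg.sample_ground_truth_voxels(
            1000, ecc_range=(0.0, 3.3), size_intercept=0.4, size_slope=0.25,
            size_jitter_sd=0.02, seed=1,
        )
        ecc = np.array([v.ecc for v in voxels])
        sig = np.array([v.sd_sigma for v in voxels])
        slope = np.polyfit(ecc, sig, 1)[0]
        assert slope == pytest.approx(0.25, rel=0.05)

    def test_centers_within_range_and_deterministic(self):
        a = pg.sample_ground_truth_voxels(30, ecc_range=(0.5, 2.5), seed=9)
        b = pg.sample_ground_truth_voxels(30, ecc_range=(0.5, 2.5), seed=9)
        assert all(0.5 <= v.ecc <= 2.5 for v in a)
        assert [v.sd_center for v in a] == [v.sd_center for v in b]

    def test_meridian_bias_overrepresents_horizontal(self):
        voxels = pg.sample_ground_truth_voxels(4000, meridian_bias=0.8, seed=3)
        theta = np.array([np.arctan2(v.sd_center[1], v.sd_center[0]) for v in voxels])
        assert np.mean(np.cos(2 * theta)) > 0.1

    def test_empty_range_rejected(self):
        with pytest.raises(ValueError):
            pg.sample_ground_truth_voxels(5, ecc_range=(2.0, 2.0))


class TestBoldGeneration:
    def test_noiseless_fixation_fit_recovers_product(self, dm101, hrf, prf_model):
        af = pg.GenerativeAFSpec()
        vox = pg.GroundTruthVoxel(sd_center=(1.2, -0.8), sd_sigma=0.7)
        ts = pg.generate_bold_timeseries(vox, dm101, "AttendFixation", af, hrf, 0.0, 0)
        truth_c, truth_s, _ = gaussian_product(
            (vox.sd_center, vox.sd_sigma), ((0.0, 0.0), af.sigma_fix)
        )
        fit = pg.fit_prf_joint(ts.values, prf_model, tuple(truth_c), init_sigma=truth_s)
        assert np.hypot(fit.params.x - truth_c[0], fit.params.y - truth_c[1]) < 0.01
        assert fit.params.sigma == pytest.approx(truth_s, rel=0.01)
        assert fit.r2 > 1 - 1e-6

    def test_amplitude_linearity(self, dm101, hrf):
        af = pg.GenerativeAFSpec()
        v1 = pg.GroundTruthVoxel(sd_center=(1.0, 0.5), sd_sigma=0.6, amplitude=1.0, baseline=0.0)
        v2 = pg.GroundTruthVoxel(sd_center=(1.0, 0.5), sd_sigma=0.6, amplitude=2.0, baseline=0.0)
        a = pg.generate_bold_timeseries(v1, dm101, "AttendFixation", af, hrf, 0.0, 0)
        b = pg.generate_bold_timeseries(v2, dm101, "AttendFixation", af, hrf, 0.0, 0)
        np.testing.assert_allclose(b.values, 2 * a.values, rtol=1e-12)

    def test_unknown_condition_rejected(self, dm101, hrf):
        v = pg.GroundTruthVoxel(sd_center=(0, 0), sd_sigma=0.5)
        with pytest.raises(ValueError, match="condition"):
            pg.generate_bold_timeseries(v, dm101, "AttendNothing", pg.GenerativeAFSpec(), hrf)

    def test_seeded_reproducibility(self, dm101, hrf):
        v = pg.GroundTruthVoxel(sd_center=(1, 1), sd_sigma=0.6)
        af = pg.GenerativeAFSpec()
        a = pg.generate_bold_timeseries(v, dm101, "AttendColor", af, hrf, 0.3, seed=5)
        b = pg.generate_bold_timeseries(v, dm101, "AttendColor", af, hrf, 0.3, seed=5)
        np.testing.assert_array_equal(a.values, b.values)

    def test_peripheral_attend_condition_pulled_toward_fovea(self, dm101, hrf, prf_model):
        """Fitting attend-stimulus data for a peripheral SD yields a pRF at
        lower eccentricity than the SD (gain-field pull toward the fovea)."""
        af = pg.GenerativeAFSpec()
        for center in ((2.4, 0.8), (0.0, -2.6)):
            v = pg.GroundTruthVoxel(sd_center=center, sd_sigma=0.8)
            ts = pg.generate_bold_timeseries(v, dm101, "AttendColor", af, hrf, 0.0, 0)
            fit = pg.fit_prf_joint(ts.values, prf_model, center, init_sigma=0.8)
            assert fit.params.ecc < v.ecc


class TestStaircase:
    def test_chance_observer(self):
        df = pg.simulate_staircase_observer(true_threshold=np.inf, n_trials=2000, seed=0)
        assert df["correct"].mean() == pytest.approx(0.5, abs=0.05)

    def test_asymptotic_accuracy_near_target(self):
        df = pg.simulate_staircase_observer(true_threshold=1.0, n_trials=1000, seed=0)
        acc = df["correct"].tail(500).mean()
        assert acc == pytest.approx(0.83, abs=0.03)

    def test_ml_threshold_recovery(self):
        """Independent maximum-likelihood Weibull fit to the trial table."""
        true_t = 1.3
        df = pg.simulate_staircase_observer(true_threshold=true_t, n_trials=1000, seed=3)
        x = df["intensity"].to_numpy()
        c = df["correct"].to_numpy()

        def nll(log_t):
            p = 1 - 0.5 * np.exp(-((x / 10**log_t) ** 3.5))
            p = np.clip(p, 1e-9, 1 - 1e-9)
            return -(np.log(p[c]).sum() + np.log1p(-p[~c]).sum())

        res = minimize_scalar(nll, bounds=(-2, 1), method="bounded")
        assert 10**res.x == pytest.approx(true_t, rel=0.10)

    def test_invalid_target_rejected(self):
        with pytest.raises(ValueError):
            pg.simulate_staircase_observer(target_p=0.4)


class TestGazeGenerator:
    def test_clean_trace_constant(self):
        tr = pg.generate_gaze_trace(2.0, rate_hz=100, seed=0)
        assert tr["x"].abs().max() == 0 and tr["valid"].all()

    def test_blink_gap_span(self):
        tr = pg.generate_gaze_trace(5.0, rate_hz=500, blink_spec=[(1.0, 0.2)], seed=0)
        assert (~tr["valid"]).sum() == int(0.2 * 500)
        assert tr.loc[~tr["valid"], "x"].isna().all()

    def test_overlapping_blinks_merged_with_warning(self):
        with pytest.warns(UserWarning, match="merged"):
            tr = pg.generate_gaze_trace(
                5.0, rate_hz=100, blink_spec=[(1.0, 0.5), (1.3, 0.5)], seed=0
            )
        assert (~tr["valid"]).sum() == int(0.8 * 100)

    def test_spike_exceeds_acceleration_threshold(self):
        """Finite-difference pupil acceleration at the constructed spike."""
        rate = 500.0
        tr = pg.generate_gaze_trace(4.0, rate_hz=rate, spike_spec=[(2.0, 5.0)], seed=0)
        p = tr["pupil"].to_numpy()
        accel = np.abs(np.diff(p, 2)) * rate**2
        assert accel.max() > 1e5


def test_model_condition_table_columns_and_average(dm101):
    voxels = pg.sample_ground_truth_voxels(5, ecc_range=(0.5, 2.5), seed=0)
    tab = pg.model_condition_table(voxels, pg.GenerativeAFSpec(), dm101, seed=0)
    np.testing.assert_allclose(
        tab["AttendStimulus_x"], (tab["AttendColor_x"] + tab["AttendTF_x"]) / 2
    )
    assert (tab["AttendFixation_ecc"] <= tab["sd_x"].pow(2).add(tab["sd_y"] ** 2).pow(0.5) + 1e-9).all()
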