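import numpy as np
import pandas as pd
import pytest

import prfgain as pg
from prfgain.metrics import make_shift_records


def wide_table(fix, stim, color=None, tf=None, r2=None, fix_sigma=None, sigmas=None):
    """Build a minimal wide per-voxel condition table from position arrays."""
    fix = np.asarray(fix, float)
    stim = np.asarray(stim, float)
    n = fix.shape[0]
    color = np.asarray(color, float) if color is not None else stim
    tf = np.asarray(tf, float) if tf is not None else stim
    d = {
        "voxel_id": np.arange(n),
        "AttendFixation_x": fix[:, 0], "AttendFixation_y": fix[:, 1],
        "AttendStimulus_x": stim[:, 0], "AttendStimulus_y": stim[:, 1],
        "AttendColor_x": color[:, 0], "AttendColor_y": color[:, 1],
        "AttendTF_x": tf[:, 0], "AttendTF_y": tf[:, 1],
        "r2": r2 if r2 is not None else np.ones(n),
    }
    sig_f = fix_sigma if fix_sigma is not None else np.full(n, 0.5)
    d["AttendFixation_sigma"] = sig_f
    for cond in ("AttendStimulus", "AttendColor", "AttendTF"):
        d[f"{cond}_sigma"] = sigmas[cond] if sigmas else sig_f
    for cond in ("AttendFixation", "AttendStimulus", "AttendColor", "AttendTF"):
        d[f"{cond}_ecc"] = np.hypot(d[f"{cond}_x"], d[f"{cond}_y"])
    return pd.DataFrame(d)


class TestMirroring:
    def test_sign_rule(self):
        fix = np.array([[-1.0, 2.0]])
        stim = np.array([[-1.5, 2.5]])
        mf, ms = pg.mirror_to_quadrant(fix, stim)
        np.testing.assert_allclose(mf, [[1.0, 2.0]])
        np.testing.assert_allclose(ms, [[1.5, 2.5]])

    def test_cross_meridian_shift_preserved(self):
        fix = np.array([[1.0, -1.0]])
        stim = np.array([[1.2, 0.1]])
        mf, ms = pg.mirror_to_quadrant(fix, stim)
        np.testing.assert_allclose(mf, [[1.0, 1.0]])
        np.testing.assert_allclose(ms, [[1.2, -0.1]])  # exits the quadrant

    def test_zero_coordinate_treated_positive(self):
        fix = np.array([[0.0, 2.0]])
        np.testing.assert_allclose(pg.mirror_to_quadrant(fix), [[0.0, 2.0]])


class TestShiftRecords:
    def test_component_identity(self):
        rng = np.random.default_rng(0)
        fix = rng.uniform(-3, 3, (50, 2))
        stim = fix + rng.normal(0, 0.3, (50, 2))
        rec = make_shift_records(wide_table(fix, stim))
        np.testing.assert_allclose(
            rec["abs_dx"] ** 2 + rec["abs_dy"] ** 2, rec["L"] ** 2, atol=1e-12
        )
        assert (rec["abs_d_ecc"] <= rec["L"] + 1e-12).all()
        assert (rec[["start_x", "start_y"]].to_numpy() >= 0).all()


class TestShiftDecomposition:
    def test_pure_radial_shift_ratios(self):
        rec = make_shift_records(wide_table([[1.5, 1.5]], [[1.0, 1.0]]))
        res = pg.decompose_shift_directions(
            pd.concat([rec] * 3, ignore_index=True), n_boot=100, seed=0
        )
        ratios = dict(zip(res.ratios["component"], res.ratios["estimate"]))
        assert ratios["radial"] == pytest.approx(1.0, abs=1e-9)
        assert ratios["horizontal"] == pytest.approx(np.sqrt(0.5), abs=1e-9)
        assert ratios["vertical"] == pytest.approx(np.sqrt(0.5), abs=1e-9)

    def test_horizontal_meridian_shift(self):
        rec = make_shift_records(wide_table([[2.0, 0.0]] * 3, [[1.5, 0.0]] * 3))
        res = pg.decompose_shift_directions(rec, n_boot=100, seed=0)
        ratios = dict(zip(res.ratios["component"], res.ratios["estimate"]))
        assert ratios["horizontal"] == pytest.approx(1.0)
        assert ratios["radial"] == pytest.approx(1.0)
        assert ratios["vertical"] == pytest.approx(0.0)

    def test_pure_vertical_off_meridian(self):
        rec = make_shift_records(wide_table([[2.0, 0.0]] * 3, [[2.0, 0.2]] * 3))
        res = pg.decompose_shift_directions(rec, n_boot=100, seed=0)
        ratios = dict(zip(res.ratios["component"], res.ratios["estimate"]))
        assert ratios["vertical"] == pytest.approx(1.0)
        assert ratios["radial"] == pytest.approx(abs(np.sqrt(4.04) - 2.0) / 0.2, abs=1e-4)

    def test_zero_length_shifts_excluded(self):
        fix = np.array([[1.0, 1.0], [2.0, 1.0], [1.5, 0.5]])
        stim = np.array([[1.0, 1.0], [1.5, 0.8], [1.2, 0.4]])
        rec = make_shift_records(wide_table(fix, stim))
        res = pg.decompose_shift_directions(rec, n_boot=100, seed=0)
        assert res.n_zero_length == 1 and res.n_used == 2


class TestPolarSlopes:
    def test_radial_shift_population_pattern(self):
        """Inward radial shifts: |dx| largest near the horizontal meridian,
        |dy| near the vertical, d_ecc flat."""
        rng = np.random.default_rng(1)
        theta = rng.uniform(0.01, np.pi / 2 - 0.01, 600)
        ecc = rng.uniform(1.0, 3.0, 600)
        fix = np.column_stack([ecc * np.cos(theta), ecc * np.sin(theta)])
        stim = fix * 0.8  # 20% radial pull
        rec = make_shift_records(wide_table(fix, stim))
        res = pg.polar_angle_slope_analysis(rec, n_boot=500, seed=0)
        # bins ordered vertical -> horizontal
        assert res.bins["mean_dx"].iloc[-1] < res.bins["mean_dx"].iloc[0]
        assert res.bins["mean_dy"].iloc[-1] > res.bins["mean_dy"].iloc[0]
        assert np.ptp(res.bins["mean_d_ecc"]) < 0.1 * abs(res.bins["mean_d_ecc"]).max() + 0.05
        assert res.contrast.estimate < 0 and res.contrast.p < 0.05

    def test_pure_horizontal_shifts_flat_dx(self):
        rng = np.random.default_rng(2)
        theta = rng.uniform(0.01, np.pi / 2 - 0.01, 500)
        fix = np.column_stack([2 * np.cos(theta), 2 * np.sin(theta)])
        stim = fix + np.array([-0.3, 0.0])
        rec = make_shift_records(wide_table(fix, stim))
        res = pg.polar_angle_slope_analysis(rec, n_boot=500, seed=0)
        assert np.ptp(res.bins["mean_dx"]) < 0.02

    def test_empty_bin_error(self):
        rec = make_shift_records(wide_table([[2.0, 0.0]] * 5, [[1.5, 0.0]] * 5))
        with pytest.raises(ValueError, match="empty"):
            pg.polar_angle_slope_analysis(rec, n_bins=3, n_boot=50)


class TestEccSizeChange:
    def _records(self, n=200, seed=0, dsize_fn=None):
        rng = np.random.default_rng(seed)
        ecc = rng.uniform(0.1, 3.2, n)
        theta = rng.uniform(0, np.pi / 2, n)
        fix = np.column_stack([ecc * np.cos(theta), ecc * np.sin(theta)])
        d_ecc = 0.1 - 0.08 * ecc
        stim = fix * ((ecc + d_ecc) / ecc)[:, None]
        sig_f = 0.4 + 0.2 * ecc
        dsz = dsize_fn(d_ecc) if dsize_fn else 2 * d_ecc
        sigmas = {
            "AttendStimulus": sig_f + dsz,
            "AttendColor": sig_f + dsz,
            "AttendTF": sig_f + dsz,
        }
        return make_shift_records(
            wide_table(fix, stim, fix_sigma=sig_f, sigmas=sigmas)
        )

    def test_linear_size_change_gives_unit_correlation(self):
        rec = self._records()
        res = pg.ecc_size_change_analysis(rec, n_boot=200, seed=0)
        assert res.pearson_r == pytest.approx(1.0, abs=1e-6)

    def test_identical_conditions_flagged_degenerate(self):
        rec = self._records()
        rec["d_ecc"] = 0.0
        rec["d_sigma"] = 0.0
        res = pg.ecc_size_change_analysis(rec, n_boot=100, seed=0)
        assert res.degenerate and np.isnan(res.pearson_r)
        np.testing.assert_allclose(res.profile["d_ecc_mean"], 0.0, atol=1e-12)

    def test_crossing_profile_detected(self):
        rec = self._records()
        prof = pg.ecc_size_change_analysis(rec, n_boot=100, seed=0).profile
        means = prof["d_ecc_mean"].to_numpy()
        assert means[0] > 0 and means[-1] < 0


class TestFeatureAMI:
    def _table(self, d_color, d_tf, n=40, seed=0):
        """Voxels whose color/tf changes are scaled copies of a base change."""
        rng = np.random.default_rng(seed)
        ecc = rng.uniform(0.5, 3.0, n)
        theta = rng.uniform(0, np.pi / 2, n)
        fix = np.column_stack([ecc * np.cos(theta), ecc * np.sin(theta)])
        base_e = rng.normal(0, 0.2, n)
        base_s = rng.normal(0, 0.1, n)
        sig_f = np.full(n, 0.6)

        def cond(scale_e, scale_s):
            ecc_new = ecc + scale_e * base_e
            pos = fix * (ecc_new / ecc)[:, None]
            return pos, sig_f + scale_s * base_s

        col_pos, col_sig = cond(*d_color)
        tf_pos, tf_sig = cond(*d_tf)
        stim_pos = (col_pos + tf_pos) / 2
        return wide_table(
            fix, stim_pos, color=col_pos, tf=tf_pos, fix_sigma=sig_f,
            sigmas={
                "AttendStimulus": (col_sig + tf_sig) / 2,
                "AttendColor": col_sig,
                "AttendTF": tf_sig,
            },
        )

    def test_double_change_gives_one_third(self):
        tab = self._table((2.0, 2.0), (1.0, 1.0))
        ami = pg.compute_feature_ami(tab)
        np.testing.assert_allclose(ami["feature_ami"], 1.0 / 3.0, atol=1e-9)

    def test_equal_changes_give_zero(self):
        tab = self._table((1.0, 1.0), (1.0, 1.0))
        ami = pg.compute_feature_ami(tab)
        np.testing.assert_allclose(ami["feature_ami"], 0.0, atol=1e-12)

    def test_zero_color_change_gives_minus_one(self):
        tab = self._table((0.0, 0.0), (1.0, 1.0))
        ami = pg.compute_feature_ami(tab)
        np.testing.assert_allclose(ami["feature_ami"], -1.0, atol=1e-12)

    def test_antisymmetric_under_condition_swap(self):
        tab = self._table((1.5, 0.8), (0.7, 1.2))
        ami = pg.compute_feature_ami(tab)
        swapped = tab.copy()
        for p in ("x", "y", "sigma", "ecc"):
            swapped[f"AttendColor_{p}"], swapped[f"AttendTF_{p}"] = (
                tab[f"AttendTF_{p}"].copy(), tab[f"AttendColor_{p}"].copy(),
            )
        ami_sw = pg.compute_feature_ami(swapped)
        np.testing.assert_allclose(ami_sw["feature_ami"], -ami["feature_ami"], atol=1e-12)

    def test_zero_dispersion_rejected(self):
        tab = self._table((1.0, 1.0), (1.0, 1.0))
        for p in ("x", "y", "sigma", "ecc"):
            tab[f"AttendStimulus_{p}"] = tab[f"AttendFixation_{p}"]
        with pytest.raises(ValueError, match="dispersion"):
            pg.compute_feature_ami(tab)


class TestFeaturePreference:
    def test_values(self):
        assert pg.feature_preference_index(1.0, 1.0) == 0.0
        assert pg.feature_preference_index(1.0, 0.0) == 1.0
        assert pg.feature_preference_index(0.2, 0.6) == pytest.approx(-0.5)

    def test_undefined_when_both_zero(self):
        assert np.isnan(pg.feature_preference_index(0.0, 0.0))

    def test_vectorized(self):
        out = pg.feature_preference_index(np.array([1.0, 0.0]), np.array([0.0, 1.0]))
        np.testing.assert_allclose(out, [1.0, -1.0])
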