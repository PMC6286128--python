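import numpy as np
import pytest
from scipy.ndimage import gaussian_filter

import prfgain as pg
from prfgain.gainfield import (
    AttentionFieldModel,
    NonInvertibleError,
    bin_shift_vectors_quadrant,
    condition_shift_profiles,
    estimate_stimulus_drive,
    fit_af_sizes,
    predict_attend_stimulus_position,
)
from prfgain.gauss import gaussian_product


class TestStimulusDrive:
    def test_round_trip_identity(self):
        rng = np.random.default_rng(0)
        for _ in range(30):
            c = tuple(rng.uniform(-3, 3, 2))
            s = rng.uniform(0.2, 1.4)
            sf = rng.uniform(1.6, 2.5)
            pc, ps, _ = gaussian_product((c, s), ((0.0, 0.0), sf))
            drive = estimate_stimulus_drive((tuple(pc), ps), sf)
            np.testing.assert_allclose(drive.center, c, atol=1e-9)
            assert drive.sigma == pytest.approx(s, abs=1e-9)

    def test_closed_form_example(self):
        drive = estimate_stimulus_drive(((1.6, 0.0), np.sqrt(4 / 5)), 2.0)
        np.testing.assert_allclose(drive.center, [2.0, 0.0], atol=1e-12)
        assert drive.sigma == pytest.approx(1.0, abs=1e-12)

    def test_non_invertible_flagged(self):
        with pytest.raises(NonInvertibleError):
            estimate_stimulus_drive(((1.0, 0.0), 2.0), 2.0)


class TestPrediction:
    def test_central_sd_stays_central(self, dm101):
        x, y = predict_attend_stimulus_position(((0.0, 0.0), 0.5), 1.0, dm101)
        assert np.hypot(x, y) <= 7.2 / 101

    def test_flat_kernel_limit_returns_sd_center(self, dm101):
        x, y = predict_attend_stimulus_position(((2.0, 0.0), 1.0), 20.0, dm101)
        assert np.hypot(x - 2.0, y) <= 7.2 / 101

    def test_peripheral_sd_pulled_inward_vs_dense_oracle(self, seq, dm101):
        """Brute-force re-evaluation of the same averaging equation on a
        201x201 grid."""
        sd_center, sd_sigma, kernel = (2.0, 0.0), 1.0, 1.0
        px, py = predict_attend_stimulus_position((sd_center, sd_sigma), kernel, dm101)
        assert np.hypot(px, py) < 2.0  # pulled toward the fovea

        dm201 = pg.render_design_matrix(seq, 201)
        masks, _ = dm201.unique_bar_masks()
        x, y = dm201.pixel_centers()
        prof = np.exp(-((x - sd_center[0]) ** 2 + (y - sd_center[1]) ** 2) / (2 * sd_sigma**2))
        sigma_px = kernel / dm201.pixel_size_dva
        acc = np.zeros_like(prof)
        n_used = 0
        for m in masks:
            prod = gaussian_filter(m.astype(float), sigma_px, mode="constant") * prof
            peak = prod.max()
            if peak > 0:
                acc += prod / peak
                n_used += 1
        acc /= n_used
        iy, ix = np.unravel_index(np.argmax(acc), acc.shape)
        ox, oy = x[iy, ix], y[iy, ix]
        assert np.hypot(px - ox, py - oy) <= 7.2 / 101  # within one coarse pixel

    def test_grid_resolution_convergence(self, seq, dm101):
        dm201 = pg.render_design_matrix(seq, 201)
        rng = np.random.default_rng(4)
        for _ in range(5):
            c = tuple(rng.uniform(-2.5, 2.5, 2))
            s = rng.uniform(0.4, 1.2)
            p1 = predict_attend_stimulus_position((c, s), 1.0, dm101)
            p2 = predict_attend_stimulus_position((c, s), 1.0, dm201)
            assert np.hypot(p1[0] - p2[0], p1[1] - p2[1]) <= 7.2 / 101


class TestQuadrantBinning:
    def test_dense_coverage_fills_64_bins(self):
        rng = np.random.default_rng(0)
        starts = rng.uniform(0, 3.3, (2000, 2))
        ends = starts + 0.1
        b = bin_shift_vectors_quadrant(starts, ends, np.full(2000, 0.5))
        assert b.starts.shape[0] == 64 and b.n_empty == 0

    def test_single_bin_collapse(self):
        starts = np.array([[0.1, 0.1], [0.2, 0.2]])
        ends = np.array([[0.0, 0.0], [0.1, 0.1]])
        b = bin_shift_vectors_quadrant(starts, ends, np.array([0.5, 0.5]))
        assert b.starts.shape[0] == 1
        np.testing.assert_allclose(b.starts[0], [0.15, 0.15])
        np.testing.assert_allclose(b.ends[0], [0.05, 0.05])

    def test_r2_weighting(self):
        starts = np.array([[1.0, 1.0], [1.2, 1.2]])
        ends = starts.copy()
        b = bin_shift_vectors_quadrant(starts, ends, np.array([0.5, 0.7]),
                                       weights=np.array([1.0, 3.0]))
        np.testing.assert_allclose(b.starts[0], [1.15, 1.15])
        assert b.sigma_meas[0] == pytest.approx(0.65)


class TestGridSpec:
    def test_printed_grid_spacing(self):
        grid = AttentionFieldModel()
        assert grid.sigma_stim_grid()[1] - grid.sigma_stim_grid()[0] == pytest.approx(0.02)
        assert grid.sigma_fix_grid()[1] - grid.sigma_fix_grid()[0] == pytest.approx(0.02)
        assert grid.sigma_stim_grid()[0] == 0.6 and grid.sigma_stim_grid().size == 50

    def test_effective_size_adds_bar_width(self):
        grid = AttentionFieldModel()
        res = _tiny_fit_result()
        assert res.effective_stim_size == pytest.approx(res.sigma_stim_kernel + 0.9)


def _tiny_fit_result():
    from prfgain.gainfield import GainFieldFitResult

    return GainFieldFitResult(
        sigma_fix=2.0, sigma_stim_kernel=1.0,
        objective_surface=np.zeros((2, 2)),
        sigma_fix_grid=np.array([1.9, 2.0]), sigma_stim_grid=np.array([0.9, 1.0]),
        predicted=np.zeros((1, 2)), observed=np.zeros((1, 2)), n_vectors=1,
    )


@pytest.fixture(scope="module")
def forward_binned(dm101):
    """Noise-free forward data: one measured voxel per quadrant bin."""
    gen_fix, gen_k = 2.0, 1.0
    edges = np.linspace(0, 3.3, 9)
    cent = (edges[:-1] + edges[1:]) / 2
    starts, sig, ends = [], [], []
    for by in range(8):
        for bx in range(8):
            c = (cent[bx], cent[by])
            s = 0.30 + 0.15 * np.hypot(*c)
            drive = estimate_stimulus_drive((c, s), gen_fix)
            starts.append(c)
            sig.append(s)
            ends.append(predict_attend_stimulus_position(drive, gen_k, dm101))
    return (
        bin_shift_vectors_quadrant(np.array(starts), np.array(ends), np.array(sig)),
        gen_fix,
        gen_k,
    )


class TestGridFit:
    def test_noise_free_recovery_small_grid(self, forward_binned, dm101):
        """Coarse (10x10) search brackets the generative sizes exactly."""
        binned, gen_fix, gen_k = forward_binned
        grid = AttentionFieldModel(grid_n_per_dim=10)
        res = fit_af_sizes(binned, dm101, grid)
        assert res.sigma_fix == pytest.approx(gen_fix, abs=grid.grid_step[0] + 1e-9)
        assert res.sigma_stim_kernel == pytest.approx(gen_k, abs=grid.grid_step[1] + 1e-9)
        i, j = np.unravel_index(np.argmin(res.objective_surface), res.objective_surface.shape)
        assert res.objective_surface[i, j] <= res.objective_surface.min() + 1e-15

    def test_all_non_invertible_cells_are_inf(self, dm101):
        starts = np.array([[1.0, 1.0]])
        ends = starts.copy()
        binned = bin_shift_vectors_quadrant(starts, ends, np.array([2.0]))
        grid = AttentionFieldModel(sigma_fix_range=(1.5, 1.9), grid_n_per_dim=4)
        res = fit_af_sizes(binned, dm101, grid)
        assert np.isinf(res.objective_surface).all()

    def test_empty_input_rejected(self, dm101):
        from prfgain.gainfield import BinnedVectors

        empty = BinnedVectors(
            starts=np.empty((0, 2)), ends=np.empty((0, 2)), sigma_meas=np.empty(0),
            weights=np.empty(0), n_per_bin=np.empty(0, int), n_bins_total=64, n_empty=64,
        )
        with pytest.raises(ValueError):
            fit_af_sizes(empty, dm101)


class TestConditionShiftProfiles:
    def test_both_sources_pull_toward_fovea(self, dm101):
        rng = np.random.default_rng(2)
        pop = []
        for _ in range(40):
            e = rng.uniform(1.0, 3.2)
            th = rng.uniform(0, 2 * np.pi)
            pop.append(((e * np.cos(th), e * np.sin(th)), 0.5 + 0.2 * e))
        prof = condition_shift_profiles(pop, 2.0, 1.0, dm101, n_ecc_bins=3)
        assert (prof["d_ecc_fix"] <= 0).all()
        assert (prof["d_ecc_stim"] <= 0).all()

    def test_difference_curve_internal_consistency(self, dm101):
        pop = [((1.5, 0.5), 0.7), ((2.5, -1.0), 0.9), ((0.5, 0.2), 0.5)]
        prof = condition_shift_profiles(pop, 2.0, 1.0, dm101, n_ecc_bins=2)
        np.testing.assert_allclose(
            prof["d_ecc_diff"], prof["d_ecc_stim"] - prof["d_ecc_fix"], atol=1e-12
        )

    def test_identical_gain_fields_zero_difference(self, dm101):
        """When the stimulus AF is flat and the fixation AF is flat, neither
        condition moves the SD, so the difference curve vanishes."""
        pop = [((1.0, 1.0), 0.6), ((2.0, 0.5), 0.8)]
        prof = condition_shift_profiles(pop, 1e6, 50.0, dm101, n_ecc_bins=1)
        np.testing.assert_allclose(prof["d_ecc_diff"], 0.0, atol=0.08)
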