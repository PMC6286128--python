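"""Multiplicative attentional gain-field model and its grid-search inversion.

The measured pRF is modelled as the pointwise product of a stimulus-driven
Gaussian (SD) and a Gaussian attentional gain field (AF). Two AFs are
estimated jointly: one at fixation (AFfix) that multiplies the SD when the
task is at fixation, and one that travels with the bar (AFstim, expressed
as the Gaussian kernel the bar mask is convolved with). Estimation:

1. The SD is recovered from the measured Attend Fixation pRF by closed-form
   Gaussian division by AFfix.
2. The predicted attend-stimulus pRF position is the peak of the average,
   over all unique bar frames, of (bar mask * AFstim kernel) x SD, each
   frame's product rescaled to a maximum of 1 ("smearing" the pRF along the
   attended bar trajectory).
3. The two AF sizes are fitted by exhaustive search on a 50 x 50 grid
   (AFfix sigma 1.5-2.5 dva, AFstim kernel sigma 0.6-1.6 dva, 0.02 dva
   steps), minimizing the L2 distance between predicted and measured
   attend-stimulus positions of 64 vectors obtained by 8 x 8 binning of the
   quadrant-mirrored visual field.

Reported AFstim sizes add the 0.9 dva bar width to the kernel sigma (the
bar convolution makes the effective gain field that much larger); the raw
kernel sigma is always stored alongside.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .gauss import gaussian_divide, gaussian_product
from .stimulus import DesignMatrix
from .synth import blurred_unique_masks

__all__ = [
    "NonInvertibleError",
    "AttentionFieldModel",
    "StimulusDrive",
    "BinnedVectors",
    "GainFieldFitResult",
    "estimate_stimulus_drive",
    "predict_attend_stimulus_position",
    "bin_shift_vectors_quadrant",
    "fit_af_sizes",
    "condition_shift_profiles",
]

BAR_WIDTH_DVA = 0.9


class NonInvertibleError(ValueError):
    """Measured pRF is not narrower than the fixation gain field."""


@dataclass
class AttentionFieldModel:
    """Grid-search specification for the two attentional gain-field sizes."""

    sigma_fix_range: tuple[float, float] = (1.5, 2.5)
    sigma_stim_range: tuple[float, float] = (0.6, 1.6)
    grid_n_per_dim: int = 50
    endpoint: bool = False  # start-anchored spacing range/n by default
    bar_width_dva: float = BAR_WIDTH_DVA

    def sigma_fix_grid(self) -> np.ndarray:
        return self._grid(self.sigma_fix_range)

    def sigma_stim_grid(self) -> np.ndarray:
        return self._grid(self.sigma_stim_range)

    def _grid(self, rng: tuple[float, float]) -> np.ndarray:
        lo, hi = rng
        n = self.grid_n_per_dim
        if self.endpoint:
            return np.linspace(lo, hi, n)
        step = (hi - lo) / n
        return lo + step * np.arange(n)

    @property
    def grid_step(self) -> tuple[float, float]:
        f, s = self.sigma_fix_range, self.sigma_stim_range
        d = self.grid_n_per_dim - 1 if self.endpoint else self.grid_n_per_dim
        return ((f[1] - f[0]) / d, (s[1] - s[0]) / d)


@dataclass
class StimulusDrive:
    """Estimated stimulus-driven pRF (the pRF outside attentional influence)."""

    center: tuple[float, float]
    sigma: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.sigma) and self.sigma > 0):
            raise ValueError("stimulus-drive sigma must be positive and finite")


@dataclass
class BinnedVectors:
    """r2-weighted bin means of quadrant-format start/end pRF positions.

    ``sigma_meas`` is the bin-mean measured Attend Fixation size, needed to
    derive the stimulus drive by Gaussian division during the model fit.
    """

    starts: np.ndarray  # (V, 2)
    ends: np.ndarray  # (V, 2)
    sigma_meas: np.ndarray  # (V,)
    weights: np.ndarray  # (V,) summed r2 per bin
    n_per_bin: np.ndarray  # (V,)
    n_bins_total: int
    n_empty: int


@dataclass
class GainFieldFitResult:
    sigma_fix: float
    sigma_stim_kernel: float
    objective_surface: np.ndarray  # (n_fix, n_stim) mean squared L2 distance
    sigma_fix_grid: np.ndarray
    sigma_stim_grid: np.ndarray
    predicted: np.ndarray  # (V, 2) at the best cell
    observed: np.ndarray  # (V, 2)
    n_vectors: int
    bar_width_dva: float = BAR_WIDTH_DVA
    excluded_vectors: dict = field(default_factory=dict)

    @property
    def effective_stim_size(self) -> float:
        """Reporting convention: kernel sigma plus the bar width."""
        return self.sigma_stim_kernel + self.bar_width_dva

    def surface_frame(self) -> pd.DataFrame:
        f, s = np.meshgrid(self.sigma_fix_grid, self.sigma_stim_grid, indexing="ij")
        return pd.DataFrame(
            {
                "sigma_fix": f.ravel(),
                "sigma_stim_kernel": s.ravel(),
                "objective": self.objective_surface.ravel(),
            }
        )

    def summary(self) -> dict:
        return {
            "sigma_fix": self.sigma_fix,
            "sigma_stim_kernel": self.sigma_stim_kernel,
            "effective_stim_size": self.effective_stim_size,
            "n_vectors": self.n_vectors,
            "objective_min": float(np.nanmin(self.objective_surface)),
            "excluded_vectors": self.excluded_vectors,
        }


# ---------------------------------------------------------------------------
# SD estimation (closed form)
# ---------------------------------------------------------------------------

def _center_sigma(prf) -> tuple[tuple[float, float], float]:
    if hasattr(prf, "center") and hasattr(prf, "sigma"):
        c = prf.center
        return (float(c[0]), float(c[1])), float(prf.sigma)
    (cx, cy), s = prf
    return (float(cx), float(cy)), float(s)


def estimate_stimulus_drive(prf_fix, sigma_fix: float) -> StimulusDrive:
    """Recover the SD by dividing the measured Attend Fixation pRF by AFfix.

    Closed form: ``1/sigma_SD^2 = 1/sigma_meas^2 - 1/sigma_fix^2``; the SD
    center solves the precision-weighted-mean relation with the AF centered
    at fixation. Raises :class:`NonInvertibleError` when the measured pRF is
    not narrower than the gain field (such voxels are excluded from the
    model fit).
    """
    center, sigma_meas = _center_sigma(prf_fix)
    if sigma_meas >= sigma_fix:
        raise NonInvertibleError(
            f"measured sigma {sigma_meas:.4f} >= fixation AF sigma {sigma_fix:.4f}"
        )
    c, s = gaussian_divide((center, sigma_meas), ((0.0, 0.0), sigma_fix))
    return StimulusDrive(center=(float(c[0]), float(c[1])), sigma=s)


# ---------------------------------------------------------------------------
# forward position prediction
# ---------------------------------------------------------------------------

def _parabolic_offset(fm, f0, fp) -> float:
    denom = fm - 2.0 * f0 + fp
    if denom >= 0 or f0 < max(fm, fp):
        return 0.0
    return float(np.clip(0.5 * (fm - fp) / denom, -0.5, 0.5))


def predict_attend_stimulus_position(
    sd, sigma_stim_kernel: float, dm101: DesignMatrix, refine: bool = True
) -> tuple[float, float]:
    """Predicted attend-stimulus pRF position for one stimulus drive.

    Every unique bar mask is convolved with the AFstim Gaussian kernel,
    multiplied pointwise with the SD profile, rescaled to a maximum of 1,
    and averaged; the peak of the average profile is returned (with 3-point
    parabolic sub-pixel refinement by default). Frames whose product
    underflows to zero everywhere are skipped; if all do, the SD lies
    outside the stimulated region and an error is raised.
    """
    (cx, cy), s_sd = _center_sigma(sd)
    n = dm101.grid_n
    x, y = dm101.pixel_centers()
    prof = np.exp(-((x - cx) ** 2 + (y - cy) ** 2) / (2.0 * s_sd**2))
    blurred = blurred_unique_masks(dm101, sigma_stim_kernel)
    prods = blurred * prof[None, :, :]
    peaks = prods.reshape(prods.shape[0], -1).max(axis=1)
    ok = peaks > 0
    if not ok.any():
        raise ValueError("SD profile does not overlap the stimulated region")
    avg = (prods[ok] / peaks[ok, None, None]).mean(axis=0)
    iy, ix = np.unravel_index(int(np.argmax(avg)), avg.shape)
    px, py = x[iy, ix], y[iy, ix]
    if refine:
        pix = dm101.pixel_size_dva
        if 0 < ix < n - 1:
            px += pix * _parabolic_offset(avg[iy, ix - 1], avg[iy, ix], avg[iy, ix + 1])
        if 0 < iy < n - 1:
            py += pix * _parabolic_offset(avg[iy - 1, ix], avg[iy, ix], avg[iy + 1, ix])
    return float(px), float(py)


# ---------------------------------------------------------------------------
# quadrant binning
# ---------------------------------------------------------------------------

def bin_shift_vectors_quadrant(
    starts: np.ndarray,
    ends: np.ndarray,
    sigma_meas: np.ndarray,
    weights: np.ndarray | None = None,
    ecc_max: float = 3.3,
    n_bins_per_dim: int = 8,
) -> BinnedVectors:
    """8x8 equal-width binning of quadrant-format positions.

    ``starts`` are quadrant-mirrored Attend Fixation positions (used for bin
    assignment), ``ends`` the corresponding attend-stimulus positions.
    Bin means are r2-weighted; empty bins are omitted and counted.
    """
    starts = np.asarray(starts, dtype=float)
    ends = np.asarray(ends, dtype=float)
    sigma_meas = np.asarray(sigma_meas, dtype=float)
    n = starts.shape[0]
    if weights is None:
        weights = np.ones(n)
    weights = np.asarray(weights, dtype=float)
    edges = np.linspace(0.0, ecc_max, n_bins_per_dim + 1)
    bx = np.clip(np.searchsorted(edges, starts[:, 0], side="right") - 1, 0, n_bins_per_dim - 1)
    by = np.clip(np.searchsorted(edges, starts[:, 1], side="right") - 1, 0, n_bins_per_dim - 1)
    bin_id = by * n_bins_per_dim + bx
    out_s, out_e, out_sig, out_w, out_n = [], [], [], [], []
    for b in range(n_bins_per_dim**2):
        sel = bin_id == b
        if not sel.any():
            continue
        w = weights[sel]
        wsum = w.sum()
        out_s.append((starts[sel] * w[:, None]).sum(axis=0) / wsum)
        out_e.append((ends[sel] * w[:, None]).sum(axis=0) / wsum)
        out_sig.append((sigma_meas[sel] * w).sum() / wsum)
        out_w.append(wsum)
        out_n.append(int(sel.sum()))
    total = n_bins_per_dim**2
    return BinnedVectors(
        starts=np.asarray(out_s),
        ends=np.asarray(out_e),
        sigma_meas=np.asarray(out_sig),
        weights=np.asarray(out_w),
        n_per_bin=np.asarray(out_n),
        n_bins_total=total,
        n_empty=total - len(out_n),
    )


# ---------------------------------------------------------------------------
# grid-search fit of the two AF sizes
# ---------------------------------------------------------------------------

def _coarse_and_windows(grid_n: int, stride: int = 5, half: int = 5):
    """Stride subgrid flat indices plus, per coarse point, a (2*half+1)^2
    window of full-grid flat indices (edge-clamped)."""
    coarse_1d = np.arange(0, grid_n, stride)
    cy, cx = np.meshgrid(coarse_1d, coarse_1d, indexing="ij")
    coarse_flat = (cy * grid_n + cx).ravel()
    offs = np.arange(-half, half + 1)
    wy = np.clip(cy.ravel()[:, None, None] + offs[None, :, None], 0, grid_n - 1)
    wx = np.clip(cx.ravel()[:, None, None] + offs[None, None, :], 0, grid_n - 1)
    windows = (wy * grid_n + wx).reshape(coarse_flat.size, -1)
    return coarse_flat, windows.astype(np.int64), 2 * half + 1


def fit_af_sizes(
    binned: BinnedVectors,
    dm101: DesignMatrix,
    grid: AttentionFieldModel | None = None,
    weighted: bool = False,
) -> GainFieldFitResult:
    """Exhaustive grid search over (AFfix sigma, AFstim kernel sigma).

    For every grid cell, each binned start position is divided by the
    candidate AFfix to obtain its SD, the attend-stimulus position is
    predicted with the candidate AFstim kernel, and the objective is the
    mean squared Euclidean distance to the observed end positions
    (optionally r2-weighted). Vectors non-invertible at a given AFfix are
    dropped from that cell (all-invertible failure sets the cell to +inf).
    Ties resolve toward smaller (sigma_fix, then kernel sigma).

    The search evaluates frame maxima and profile peaks on a stride-3
    subgrid refined in a local exact window; the returned predictions at the
    best cell are recomputed with the exact single-voxel predictor.
    """
    grid = grid or AttentionFieldModel()
    if binned.starts.shape[0] < 1:
        raise ValueError("need at least one binned vector")
    fix_grid = grid.sigma_fix_grid()
    stim_grid = grid.sigma_stim_grid()
    n = dm101.grid_n
    x, y = dm101.pixel_centers()
    xf, yf = x.ravel(), y.ravel()
    coarse, windows, wside = _coarse_and_windows(n)
    starts, ends = binned.starts, binned.ends
    sig_meas = binned.sigma_meas
    V = starts.shape[0]
    wvec = binned.weights / binned.weights.sum() if weighted else np.full(V, 1.0 / V)
    pix = dm101.pixel_size_dva

    # blurred bar stacks per kernel value (cached on the design across fits)
    stacks = [blurred_unique_masks(dm101, sk).reshape(-1, n * n) for sk in stim_grid]
    U = stacks[0].shape[0]
    arange_u = np.arange(U)
    coarse_stacks = [B[:, coarse] for B in stacks]

    surface = np.full((fix_grid.size, stim_grid.size), np.inf)
    for i, sf in enumerate(fix_grid):
        # SD per vector at this fixation-AF size (independent of the kernel)
        valid = sig_meas < sf
        idx = np.flatnonzero(valid)
        if idx.size == 0:
            continue
        centers = np.zeros((idx.size, 2))
        sigmas = np.zeros(idx.size)
        for vi, v in enumerate(idx):
            drive = estimate_stimulus_drive((tuple(starts[v]), sig_meas[v]), sf)
            centers[vi] = drive.center
            sigmas[vi] = drive.sigma
        G = np.exp(
            -(
                (xf[None, :] - centers[:, 0][:, None]) ** 2
                + (yf[None, :] - centers[:, 1][:, None]) ** 2
            )
            / (2.0 * sigmas[:, None] ** 2)
        )
        Gc = G[:, coarse]
        arange_v = np.arange(idx.size)
        wv = wvec[idx]
        for j in range(stim_grid.size):
            B, Bc = stacks[j], coarse_stacks[j]
            # per-frame maxima: coarse argmax then exact within local window
            prod_c = Gc[:, None, :] * Bc[None, :, :]
            ca = prod_c.argmax(axis=2)
            win = windows[ca]  # (v, U, w^2)
            B_w = B[arange_u[None, :, None], win]
            G_w = G[arange_v[:, None, None], win]
            m = (B_w * G_w).max(axis=2)
            m[m <= 0] = np.inf  # skip underflowed frames
            W = (1.0 / m) / np.isfinite(m).sum(axis=1, keepdims=True)
            W[~np.isfinite(W)] = 0.0
            # averaged profile on the coarse grid, then exact peak in window
            acc_c = W @ Bc  # (v, coarse)
            prof_c = acc_c * Gc
            pca = prof_c.argmax(axis=1)
            pwin = windows[pca]  # (v, w^2)
            B_pw = B[:, pwin.ravel()].reshape(U, idx.size, -1)
            acc_w = np.einsum("uvk,vu->vk", B_pw, W)
            G_pw = G[arange_v[:, None], pwin]
            prof_w = acc_w * G_pw
            k = prof_w.argmax(axis=1)
            ky, kx = divmod(k, wside)
            pred = np.empty((idx.size, 2))
            for vi in range(idx.size):
                flat = pwin[vi, k[vi]]
                iy, ix = divmod(flat, n)
                px, py = xf[flat], yf[flat]
                Fw = prof_w[vi].reshape(wside, wside)
                if 0 < kx[vi] < wside - 1 and 0 < ix < n - 1:
                    px += pix * _parabolic_offset(
                        Fw[ky[vi], kx[vi] - 1], Fw[ky[vi], kx[vi]], Fw[ky[vi], kx[vi] + 1]
                    )
                if 0 < ky[vi] < wside - 1 and 0 < iy < n - 1:
                    py += pix * _parabolic_offset(
                        Fw[ky[vi] - 1, kx[vi]], Fw[ky[vi], kx[vi]], Fw[ky[vi] + 1, kx[vi]]
                    )
                pred[vi] = (px, py)
            d2 = np.sum((pred - ends[idx]) ** 2, axis=1)
            surface[i, j] = float(np.sum(d2 * wv) / np.sum(wv))

    best_flat = int(np.argmin(surface))  # row-major: smaller fix, then kernel
    bi, bj = divmod(best_flat, stim_grid.size)
    best_fix, best_stim = float(fix_grid[bi]), float(stim_grid[bj])

    predicted = np.full((V, 2), np.nan)
    excluded = []
    for v in range(V):
        try:
            drive = estimate_stimulus_drive((tuple(starts[v]), sig_meas[v]), best_fix)
            predicted[v] = predict_attend_stimulus_position(drive, best_stim, dm101)
        except (NonInvertibleError, ValueError):
            excluded.append(v)
    return GainFieldFitResult(
        sigma_fix=best_fix,
        sigma_stim_kernel=best_stim,
        objective_surface=surface,
        sigma_fix_grid=fix_grid,
        sigma_stim_grid=stim_grid,
        predicted=predicted,
        observed=ends.copy(),
        n_vectors=V,
        bar_width_dva=grid.bar_width_dva,
        excluded_vectors={"at_best_cell": excluded},
    )


# ---------------------------------------------------------------------------
# model-derived eccentricity-change decomposition
# ---------------------------------------------------------------------------

def condition_shift_profiles(
    sd_population,
    sigma_fix: float,
    sigma_stim_kernel: float,
    dm101: DesignMatrix,
    n_ecc_bins: int = 4,
    ecc_max: float = 3.3,
) -> pd.DataFrame:
    """Model-derived eccentricity changes relative to the bare SD.

    For each stimulus drive in ``sd_population`` (tuples ``((x, y), sigma)``
    or :class:`StimulusDrive`), compute the eccentricity change induced by
    attending fixation (closed-form product with AFfix) and by attending the
    stimulus (argmax-average prediction), bin by SD eccentricity, and return
    per-bin means plus their difference — the model's account of the
    attend-stimulus minus attend-fixation eccentricity-change profile.
    """
    rows = []
    for sd in sd_population:
        center, sigma = _center_sigma(sd)
        ecc_sd = float(np.hypot(*center))
        c_fix, _, _ = gaussian_product((center, sigma), ((0.0, 0.0), sigma_fix))
        px, py = predict_attend_stimulus_position((center, sigma), sigma_stim_kernel, dm101)
        rows.append(
            {
                "ecc_sd": ecc_sd,
                "d_ecc_fix": float(np.hypot(*c_fix)) - ecc_sd,
                "d_ecc_stim": float(np.hypot(px, py)) - ecc_sd,
            }
        )
    df = pd.DataFrame(rows)
    df["d_ecc_diff"] = df["d_ecc_stim"] - df["d_ecc_fix"]
    edges = np.linspace(0.0, ecc_max, n_ecc_bins + 1)
    df["bin"] = np.clip(
        np.searchsorted(edges, df["ecc_sd"], side="right") - 1, 0, n_ecc_bins - 1
    )
    prof = df.groupby("bin")[["d_ecc_fix", "d_ecc_stim", "d_ecc_diff"]].mean()
    prof["bin_center"] = (edges[:-1] + edges[1:])[prof.index] / 2
    prof["n"] = df.groupby("bin").size()
    return prof.reset_index()
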