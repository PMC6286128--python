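"""Synthetic ground truth: voxels, BOLD, staircase behavior, gaze.

Every downstream stage (preprocessing, pRF fitting, gain-field inversion,
population metrics) is exercised against data generated here, so the
generators implement the same multiplicative gain-field model the analysis
inverts: each voxel owns a stimulus-driven Gaussian pRF (SD); attending
fixation multiplies it with a Gaussian gain field at fixation; attending the
bar multiplies it, frame by frame, with the bar mask convolved with a
stimulus gain-field kernel, so the locus of attention travels with the bar.

The BOLD signal of a voxel is the spatial overlap of each stimulus frame
with its (condition- and possibly time-dependent) effective pRF, normalized
to unit peak, scaled by the voxel amplitude, offset by the baseline,
convolved with the HRF, plus Gaussian observation noise. All generators are
bit-reproducible under a fixed seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .gauss import gaussian_product
from .stimulus import DesignMatrix, HRFKernel, convolve_timeseries

__all__ = [
    "GroundTruthVoxel",
    "GenerativeAFSpec",
    "VoxelTimeseries",
    "CONDITIONS",
    "gaussian_product",
    "sample_ground_truth_voxels",
    "voxels_to_frame",
    "generate_bold_timeseries",
    "model_condition_table",
    "simulate_staircase_observer",
    "generate_gaze_trace",
]

CONDITIONS = ("AttendFixation", "AttendColor", "AttendTF")


@dataclass
class GroundTruthVoxel:
    """One simulated voxel's stimulus-driven pRF and response scaling."""

    sd_center: tuple[float, float]  # dva
    sd_sigma: float  # dva
    amplitude: float = 1.0
    baseline: float = 0.0
    feature_pref: float = 0.0  # in [-1, 1], positive = color-preferring

    def __post_init__(self) -> None:
        if self.sd_sigma <= 0:
            raise ValueError("sd_sigma must be positive")

    @property
    def ecc(self) -> float:
        return float(np.hypot(*self.sd_center))


@dataclass
class GenerativeAFSpec:
    """Gain-field sizes used to generate condition-specific responses.

    ``sigma_stim_color <= sigma_stim_tf`` emulates the empirical finding that
    the stimulus gain field is more precise when color is attended.
    """

    sigma_fix: float = 2.0
    sigma_stim_color: float = 0.95
    sigma_stim_tf: float = 1.05
    fix_center: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        for s in (self.sigma_fix, self.sigma_stim_color, self.sigma_stim_tf):
            if s <= 0:
                raise ValueError("gain-field sigmas must be positive")

    def stim_kernel(self, condition: str) -> float:
        if condition == "AttendColor":
            return self.sigma_stim_color
        if condition == "AttendTF":
            return self.sigma_stim_tf
        raise ValueError(f"no stimulus kernel for condition {condition!r}")


@dataclass
class VoxelTimeseries:
    condition: str
    values: np.ndarray
    noise_sd: float
    seed: int


# ---------------------------------------------------------------------------
# ground-truth voxel sampling
# ---------------------------------------------------------------------------

def sample_ground_truth_voxels(
    n: int,
    ecc_range: tuple[float, float] = (0.0, 3.3),
    size_intercept: float = 0.4,
    size_slope: float = 0.25,
    size_jitter_sd: float = 0.05,
    amplitude: float = 1.0,
    baseline: float = 0.0,
    feature_pref_intercept: float = 0.5,
    feature_pref_slope: float = -0.3,
    feature_pref_jitter_sd: float = 0.1,
    meridian_bias: float = 0.0,
    seed: int = 0,
) -> list[GroundTruthVoxel]:
    """Draw voxels with centers uniform over an eccentricity annulus.

    pRF size follows the linear size-eccentricity relation
    ``sigma = intercept + slope * ecc`` plus Gaussian jitter (floored at
    0.05 dva). Feature preference decreases linearly with eccentricity by
    default (color preference is greatest near the fovea).

    ``meridian_bias`` (kappa >= 0) optionally biases polar angles toward the
    horizontal meridian with density proportional to ``1 + kappa*cos(2*theta)``,
    emulating the well-known cortical overrepresentation of the horizontal
    meridian; 0 keeps the angular distribution uniform.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    e0, e1 = ecc_range
    if not (0 <= e0 < e1):
        raise ValueError("ecc_range must satisfy 0 <= low < high")
    if size_slope < 0:
        raise ValueError("size_slope must be >= 0")
    rng = np.random.default_rng(seed)
    ecc = np.sqrt(rng.uniform(e0**2, e1**2, size=n))
    if meridian_bias > 0:
        theta = np.empty(n)
        filled = 0
        while filled < n:
            cand = rng.uniform(0, 2 * np.pi, size=2 * (n - filled))
            keep = rng.uniform(0, 1 + meridian_bias, size=cand.size) <= (
                1 + meridian_bias * np.cos(2 * cand)
            )
            take = cand[keep][: n - filled]
            theta[filled : filled + take.size] = take
            filled += take.size
    else:
        theta = rng.uniform(0, 2 * np.pi, size=n)
    sigma = size_intercept + size_slope * ecc + rng.normal(0, size_jitter_sd, size=n)
    sigma = np.maximum(sigma, 0.05)
    fp = (
        feature_pref_intercept
        + feature_pref_slope * ecc
        + rng.normal(0, feature_pref_jitter_sd, size=n)
    )
    fp = np.clip(fp, -1.0, 1.0)
    return [
        GroundTruthVoxel(
            sd_center=(float(ecc[i] * np.cos(theta[i])), float(ecc[i] * np.sin(theta[i]))),
            sd_sigma=float(sigma[i]),
            amplitude=amplitude,
            baseline=baseline,
            feature_pref=float(fp[i]),
        )
        for i in range(n)
    ]


def voxels_to_frame(voxels: list[GroundTruthVoxel]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "voxel_id": np.arange(len(voxels)),
            "x": [v.sd_center[0] for v in voxels],
            "y": [v.sd_center[1] for v in voxels],
            "sigma": [v.sd_sigma for v in voxels],
            "ecc": [v.ecc for v in voxels],
            "amplitude": [v.amplitude for v in voxels],
            "baseline": [v.baseline for v in voxels],
            "feature_pref": [v.feature_pref for v in voxels],
        }
    )


# ---------------------------------------------------------------------------
# grid helpers (shared with the gain-field model)
# ---------------------------------------------------------------------------

def gaussian_profile(dm: DesignMatrix, center, sigma: float) -> np.ndarray:
    """Unit-peak isotropic Gaussian evaluated at the design's pixel centers."""
    x, y = _pixel_grids(dm)
    cx, cy = center
    return np.exp(-((x - cx) ** 2 + (y - cy) ** 2) / (2.0 * sigma**2))


def _pixel_grids(dm: DesignMatrix):
    cached = dm.__dict__.get("_pixel_grids")
    if cached is None:
        cached = dm.pixel_centers()
        dm.__dict__["_pixel_grids"] = cached
    return cached


def unique_masks_cached(dm: DesignMatrix):
    cached = dm.__dict__.get("_unique_masks")
    if cached is None:
        cached = dm.unique_bar_masks()
        dm.__dict__["_unique_masks"] = cached
    return cached


def blurred_unique_masks(dm: DesignMatrix, sigma_dva: float) -> np.ndarray:
    """Unique bar masks convolved with a Gaussian kernel (sigma in dva).

    Cached on the design instance keyed by sigma; the blur preserves mask
    mass (normalized Gaussian kernel).
    """
    cache = dm.__dict__.setdefault("_blur_cache", {})
    key = round(float(sigma_dva), 9)
    out = cache.get(key)
    if out is None:
        masks, _ = unique_masks_cached(dm)
        sigma_px = sigma_dva / dm.pixel_size_dva
        out = np.stack(
            [gaussian_filter(m.astype(np.float64), sigma_px, mode="constant") for m in masks]
        )
        cache[key] = out
    return out


# ---------------------------------------------------------------------------
# BOLD generation
# ---------------------------------------------------------------------------

def generate_bold_timeseries(
    voxel: GroundTruthVoxel,
    design: DesignMatrix,
    condition: str,
    af: GenerativeAFSpec,
    hrf: HRFKernel,
    noise_sd: float = 0.0,
    seed: int = 0,
    attend_stim_mode: str = "model",
    bar_width_dva: float = 0.9,
    ar1_rho: float = 0.0,
) -> VoxelTimeseries:
    """Simulate one voxel's BOLD run under one attention condition.

    Attend Fixation: the effective pRF is the closed-form product of the SD
    with the fixation gain field, constant over the run. Attend Color / TF
    (``attend_stim_mode``):

    - ``"model"`` (default): the measured pRF the gain-field model asserts —
      a Gaussian centered at the argmax-of-average predicted position, with
      the closed-form product sigma of the SD and the effective stimulus
      gain field (kernel sigma + bar width).
    - ``"moving"``: frame-wise effective pRF, the SD multiplied pointwise
      with the bar mask convolved with the stimulus kernel (unit peak), so
      attention travels with the bar. A Gaussian fitted to such data sits at
      the SD center rather than at the model-predicted position — kept as an
      ablation of the measurement assumption.
    - ``"profile"``: the run-averaged smeared profile as one static
      non-Gaussian effective pRF (ablation).

    The neural overlap series is normalized to unit peak over bar frames
    before amplitude scaling, making ``noise_sd`` directly comparable to
    ``voxel.amplitude``.
    """
    if abs(hrf.dt_s - design.dt_s) > 1e-9:
        raise ValueError("HRF and design sampling intervals differ")
    masks, mapping = unique_masks_cached(design)
    flat_masks = masks.reshape(masks.shape[0], -1).astype(np.float64)
    if condition == "AttendFixation":
        center, sigma, _ = gaussian_product(
            (voxel.sd_center, voxel.sd_sigma), (af.fix_center, af.sigma_fix)
        )
        eff = gaussian_profile(design, center, sigma).ravel()
        overlap_u = flat_masks @ eff
    elif condition in ("AttendColor", "AttendTF"):
        kernel = af.stim_kernel(condition)
        if attend_stim_mode == "model":
            from .gainfield import predict_attend_stimulus_position

            pos = predict_attend_stimulus_position(
                (voxel.sd_center, voxel.sd_sigma), kernel, design
            )
            _, sigma, _ = gaussian_product(
                (voxel.sd_center, voxel.sd_sigma),
                ((0.0, 0.0), kernel + bar_width_dva),
            )
            eff = gaussian_profile(design, pos, sigma).ravel()
            overlap_u = flat_masks @ eff
        elif attend_stim_mode in ("moving", "profile"):
            sd_prof = gaussian_profile(design, voxel.sd_center, voxel.sd_sigma).ravel()
            blurred = blurred_unique_masks(design, kernel)
            eff_u = blurred.reshape(blurred.shape[0], -1) * sd_prof
            peaks = eff_u.max(axis=1)
            peaks[peaks == 0] = 1.0
            eff_u = eff_u / peaks[:, None]
            if attend_stim_mode == "moving":
                overlap_u = np.einsum("up,up->u", flat_masks, eff_u)
            else:
                overlap_u = flat_masks @ eff_u.mean(axis=0)
        else:
            raise ValueError(f"unknown attend_stim_mode {attend_stim_mode!r}")
    else:
        raise ValueError(f"unknown condition {condition!r}")
    neural = np.zeros(design.n_frames)
    on = mapping >= 0
    neural[on] = overlap_u[mapping[on]]
    peak = neural.max()
    if peak > 0:
        neural = neural / peak
    signal = voxel.baseline + voxel.amplitude * convolve_timeseries(neural, hrf)
    rng = np.random.default_rng(seed)
    if noise_sd > 0:
        eps = rng.normal(0, noise_sd, size=signal.shape)
        if ar1_rho:
            innov_sd = noise_sd * np.sqrt(1 - ar1_rho**2)
            eps = np.empty_like(signal)
            eps[0] = rng.normal(0, noise_sd)
            eps[1:] = rng.normal(0, innov_sd, size=signal.size - 1)
            for t in range(1, signal.size):
                eps[t] += ar1_rho * eps[t - 1]
        signal = signal + eps
    return VoxelTimeseries(condition=condition, values=signal, noise_sd=noise_sd, seed=seed)


def model_condition_table(
    voxels: list[GroundTruthVoxel],
    af: GenerativeAFSpec,
    dm101: DesignMatrix,
    param_noise_sd: float = 0.0,
    bar_width_dva: float = 0.9,
    seed: int = 0,
) -> pd.DataFrame:
    """Condition-level pRF parameters straight from the generative model.

    For population analyses that do not require time-series fitting, derive
    each voxel's per-condition parameters analytically: the Attend Fixation
    pRF is the closed-form SD x fixation-AF product; attend-stimulus
    positions come from the argmax-of-average model prediction; condition
    sizes use the closed-form product of the SD with the effective stimulus
    gain field (kernel sigma + bar width). Optional Gaussian noise of sd
    ``param_noise_sd`` (scaled by each voxel's sigma for the size column) is
    added to positions and sizes. ``r2`` is drawn from a Beta(8, 4)
    distribution as a stand-in fit-quality weight.
    """
    from .gainfield import predict_attend_stimulus_position

    rng = np.random.default_rng(seed)
    rows = []
    for vid, v in enumerate(voxels):
        rec: dict[str, float] = {"voxel_id": vid, "sd_x": v.sd_center[0], "sd_y": v.sd_center[1], "sd_sigma": v.sd_sigma}
        c_fix, s_fix, _ = gaussian_product((v.sd_center, v.sd_sigma), (af.fix_center, af.sigma_fix))
        rec.update(AttendFixation_x=c_fix[0], AttendFixation_y=c_fix[1], AttendFixation_sigma=s_fix)
        for cond in ("AttendColor", "AttendTF"):
            kern = af.stim_kernel(cond)
            px, py = predict_attend_stimulus_position(
                (v.sd_center, v.sd_sigma), kern, dm101
            )
            _, s_cond, _ = gaussian_product(
                (v.sd_center, v.sd_sigma), ((0.0, 0.0), kern + bar_width_dva)
            )
            rec[f"{cond}_x"] = px
            rec[f"{cond}_y"] = py
            rec[f"{cond}_sigma"] = s_cond
        rec["r2"] = float(rng.beta(8, 4))
        rows.append(rec)
    df = pd.DataFrame(rows)
    if param_noise_sd > 0:
        for cond in CONDITIONS:
            df[f"{cond}_x"] += rng.normal(0, param_noise_sd, len(df))
            df[f"{cond}_y"] += rng.normal(0, param_noise_sd, len(df))
            df[f"{cond}_sigma"] = np.maximum(
                df[f"{cond}_sigma"] + rng.normal(0, param_noise_sd, len(df)), 0.05
            )
    for cond in CONDITIONS:
        df[f"{cond}_ecc"] = np.hypot(df[f"{cond}_x"], df[f"{cond}_y"])
    df["AttendStimulus_x"] = (df["AttendColor_x"] + df["AttendTF_x"]) / 2
    df["AttendStimulus_y"] = (df["AttendColor_y"] + df["AttendTF_y"]) / 2
    df["AttendStimulus_sigma"] = (df["AttendColor_sigma"] + df["AttendTF_sigma"]) / 2
    df["AttendStimulus_ecc"] = np.hypot(df["AttendStimulus_x"], df["AttendStimulus_y"])
    return df


# ---------------------------------------------------------------------------
# adaptive staircase observer
# ---------------------------------------------------------------------------

def _weibull_p(x, threshold, beta, guess):
    return 1.0 - (1.0 - guess) * np.exp(-((x / threshold) ** beta))


def simulate_staircase_observer(
    true_threshold: float = 1.0,
    psychometric_slope: float = 3.5,
    n_trials: int = 1000,
    target_p: float = 0.83,
    guess_rate: float = 0.5,
    prior_mode: float = 1.0,
    prior_sd_log10: float = 1.0,
    lattice: tuple[float, float, int] = (-3.0, 1.0, 400),
    seed: int = 0,
) -> pd.DataFrame:
    """2AFC observer driven by a Bayesian adaptive (QUEST-style) staircase.

    A one-parameter posterior over log10 threshold is maintained on a
    lattice; each trial is placed at the intensity that would yield
    ``target_p`` correct under the current posterior-mode threshold, and the
    observer responds per a Weibull psychometric function with the given
    slope and guess rate. ``true_threshold=inf`` models an observer who never
    sees the stimulus (chance performance).

    Returns a trial table with columns trial, intensity, correct,
    threshold_mode (the running posterior-mode threshold estimate).
    """
    if not (guess_rate < target_p < 1.0):
        raise ValueError("target_p must lie strictly between the guess rate and 1")
    lo, hi, n_lat = lattice
    log_t = np.linspace(lo, hi, int(n_lat))
    thresholds = 10.0**log_t
    log_post = -0.5 * ((log_t - np.log10(prior_mode)) / prior_sd_log10) ** 2
    beta = psychometric_slope
    # intensity multiplier mapping a threshold estimate to the target_p point
    k = (-np.log((1.0 - target_p) / (1.0 - guess_rate))) ** (1.0 / beta)
    rng = np.random.default_rng(seed)
    rows = np.empty((n_trials, 3))
    for i in range(n_trials):
        t_mode = thresholds[int(np.argmax(log_post))]
        x = t_mode * k
        if np.isinf(true_threshold):
            p_true = guess_rate
        else:
            p_true = _weibull_p(x, true_threshold, beta, guess_rate)
        correct = rng.uniform() < p_true
        p_lat = _weibull_p(x, thresholds, beta, guess_rate)
        p_lat = np.clip(p_lat, 1e-10, 1 - 1e-10)
        log_post += np.log(p_lat) if correct else np.log1p(-p_lat)
        rows[i] = (x, float(correct), t_mode)
    df = pd.DataFrame(rows, columns=["intensity", "correct", "threshold_mode"])
    df.insert(0, "trial", np.arange(n_trials))
    df["correct"] = df["correct"].astype(bool)
    return df


# ---------------------------------------------------------------------------
# gaze traces
# ---------------------------------------------------------------------------

def generate_gaze_trace(
    duration_s: float,
    rate_hz: float = 500.0,
    fixation_noise_sd: float = 0.0,
    blink_spec: list[tuple[float, float]] | None = None,
    spike_spec: list[tuple[float, float]] | None = None,
    drift: tuple[float, float] = (0.0, 0.0),
    fixation: tuple[float, float] = (0.0, 0.0),
    pupil_baseline: float = 5.0,
    pupil_noise_sd: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Raw 2D gaze plus pupil-size trace with blinks and tracker spikes.

    Blinks are flagged gaps (``valid`` = False, channels NaN); overlapping
    blink intervals are merged with a warning. Spikes are
    ``(time_s, amplitude)`` single-sample pupil excursions producing the
    high-acceleration artifacts the cleaning stage must reject.
    """
    if rate_hz <= 0:
        raise ValueError("rate_hz must be positive")
    n = int(round(duration_s * rate_hz))
    t = np.arange(n) / rate_hz
    rng = np.random.default_rng(seed)
    x = fixation[0] + drift[0] * t + rng.normal(0, fixation_noise_sd, n)
    y = fixation[1] + drift[1] * t + rng.normal(0, fixation_noise_sd, n)
    pupil = pupil_baseline + rng.normal(0, pupil_noise_sd, n)
    valid = np.ones(n, dtype=bool)
    if blink_spec:
        intervals = sorted((float(s), float(s + d)) for s, d in blink_spec)
        merged = [list(intervals[0])]
        for s, e in intervals[1:]:
            if s <= merged[-1][1]:
                warnings.warn("overlapping blink intervals merged", stacklevel=2)
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        for s, e in merged:
            sel = (t >= s) & (t < e)
            valid[sel] = False
            x[sel] = np.nan
            y[sel] = np.nan
            pupil[sel] = np.nan
    if spike_spec:
        for ts, amp in spike_spec:
            idx = int(round(ts * rate_hz))
            if 0 <= idx < n and valid[idx]:
                pupil[idx] += amp
    return pd.DataFrame({"time_s": t, "x": x, "y": y, "pupil": pupil, "valid": valid})
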