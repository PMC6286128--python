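"""Three-step pRF estimation and voxel selection.

Step 1 (coarse): L2-regularized (ridge, lambda = 1e6) regression of the
voxel time series on the HRF-convolved 31x31 pixel regressors; the peak
coefficient's position initializes the nonlinear fit. Step 2 (joint): a
single isotropic 2D Gaussian (x, y, sigma, amplitude, baseline) is fitted
to all attention conditions combined on the 101x101 grid with a
derivative-free direction-set (Powell) minimizer. Step 3 (per condition):
one Gaussian per condition is fitted simultaneously, all parameters free
except a single shared baseline (13 parameters), initialized at the joint
fit. Fit quality is R^2 = 1 - residual/observed variance, used both for
voxel selection and as a statistical weight downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.linalg import cho_factor, cho_solve
from scipy.optimize import minimize

from .stimulus import DesignMatrix, HRFKernel, convolve_timeseries
from .synth import CONDITIONS, unique_masks_cached

__all__ = [
    "PRFParams",
    "PRFFit",
    "ConditionFitSet",
    "PRFModel",
    "DEFAULT_BOUNDS",
    "ridge_factor",
    "ridge_init",
    "fit_prf_joint",
    "fit_prf_per_condition",
    "compute_r2",
    "select_voxels",
    "fits_to_frame",
]

# x, y in [-5, 5] dva; sigma in [0.05, 10] dva; amplitude/baseline unbounded
DEFAULT_BOUNDS = {"xy": (-5.0, 5.0), "sigma": (0.05, 10.0)}


@dataclass
class PRFParams:
    """Isotropic 2D Gaussian receptive field parameters."""

    x: float
    y: float
    sigma: float
    amplitude: float
    baseline: float

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")

    @property
    def ecc(self) -> float:
        return float(np.hypot(self.x, self.y))

    @property
    def polar_angle(self) -> float:
        return float(np.arctan2(self.y, self.x))

    @property
    def center(self) -> tuple[float, float]:
        return (self.x, self.y)


@dataclass
class PRFFit:
    params: PRFParams
    r2: float
    converged: bool = True


@dataclass
class ConditionFitSet:
    """Per-condition pRFs with one shared baseline and an overall R^2."""

    fits: dict[str, PRFParams]
    shared_baseline: float
    r2: float
    converged: bool = True
    flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        for p in self.fits.values():
            if abs(p.baseline - self.shared_baseline) > 1e-9:
                raise ValueError("all conditions must share one baseline")

    @property
    def attend_stimulus(self) -> PRFParams:
        """Element-wise mean of the Attend Color and Attend TF parameters."""
        c, t = self.fits["AttendColor"], self.fits["AttendTF"]
        return PRFParams(
            x=(c.x + t.x) / 2,
            y=(c.y + t.y) / 2,
            sigma=(c.sigma + t.sigma) / 2,
            amplitude=(c.amplitude + t.amplitude) / 2,
            baseline=self.shared_baseline,
        )

    def condition(self, name: str) -> PRFParams:
        if name == "AttendStimulus":
            return self.attend_stimulus
        return self.fits[name]


class PRFModel:
    """Forward model: Gaussian-overlap prediction of one voxel's BOLD run.

    The Gaussian (unit peak; the amplitude parameter carries scale) is
    evaluated on the design grid, dotted with each frame's mask, convolved
    with the HRF and affinely scaled. The unique bar masks are held as a
    sparse matrix so one prediction costs a single sparse matvec.
    """

    def __init__(self, design: DesignMatrix, hrf: HRFKernel):
        if abs(hrf.dt_s - design.dt_s) > 1e-9:
            raise ValueError("HRF and design sampling intervals differ")
        self.design = design
        self.hrf = hrf
        masks, mapping = unique_masks_cached(design)
        self.S = sparse.csr_matrix(masks.reshape(masks.shape[0], -1).astype(np.float64))
        self.mapping = mapping
        self.on = mapping >= 0
        x, y = design.pixel_centers()
        self.xf = x.ravel()
        self.yf = y.ravel()
        self.n_frames = design.n_frames
        self.extent = design.extent_dva

    def predict(self, x: float, y: float, sigma: float, amplitude: float, baseline: float) -> np.ndarray:
        g = np.exp(-((self.xf - x) ** 2 + (self.yf - y) ** 2) / (2.0 * sigma**2))
        ov = self.S @ g
        neural = np.zeros(self.n_frames)
        neural[self.on] = ov[self.mapping[self.on]]
        return baseline + amplitude * convolve_timeseries(neural, self.hrf)

    def predict_shape(self, x: float, y: float, sigma: float) -> np.ndarray:
        """Prediction with unit amplitude and zero baseline."""
        return self.predict(x, y, sigma, 1.0, 0.0)


# ---------------------------------------------------------------------------
# step 1: ridge back-projection
# ---------------------------------------------------------------------------

def ridge_factor(regressors: np.ndarray, lam: float = 1e6):
    """Precompute the Cholesky factor of (R'R + lam*I) for reuse over voxels."""
    R = np.asarray(regressors, dtype=np.float64)
    G = R.T @ R
    G[np.diag_indices_from(G)] += lam
    return cho_factor(G)


def ridge_init(
    ts_all: np.ndarray,
    regressors: np.ndarray,
    grid_n: int,
    extent_dva: float = 7.2,
    lam: float = 1e6,
    factor=None,
    zscore_runs: bool = True,
) -> tuple[float, float]:
    """Coarse pRF center from heavily regularized pixel-wise regression.

    ``ts_all`` is the concatenation of all condition runs (its length must
    be a multiple of the regressor stack's frame count; the regressors are
    implicitly tiled). Each run is z-scored before regression. Returns the
    position (dva) of the maximum coefficient; exact ties resolve to the
    lowest flattened pixel index.
    """
    y = np.asarray(ts_all, dtype=np.float64)
    R = np.asarray(regressors, dtype=np.float64)
    T = R.shape[0]
    if y.size % T != 0:
        raise ValueError("time series length is not a multiple of the design length")
    if np.allclose(y, y[0] if y.size else 0.0):
        raise ValueError("all-zero or constant time series")
    n_runs = y.size // T
    rty = np.zeros(R.shape[1])
    for r in range(n_runs):
        seg = y[r * T : (r + 1) * T]
        if zscore_runs:
            sd = seg.std()
            if sd == 0:
                raise ValueError("constant run segment")
            seg = (seg - seg.mean()) / sd
        rty += R.T @ seg
    if factor is None:
        factor = ridge_factor(R, lam)
    w = cho_solve(factor, rty)
    flat = int(np.argmax(w))  # ties -> lowest flat index
    iy, ix = divmod(flat, grid_n)
    c = extent_dva * (np.arange(grid_n) + 0.5) / grid_n - extent_dva / 2
    return float(c[ix]), float(c[iy])


# ---------------------------------------------------------------------------
# steps 2-3: nonlinear fits
# ---------------------------------------------------------------------------

def compute_r2(measured: np.ndarray, predicted: np.ndarray) -> float:
    """R^2 = 1 - sum((m-p)^2) / sum((m-mean(m))^2)."""
    m = np.asarray(measured, dtype=float)
    p = np.asarray(predicted, dtype=float)
    if m.shape != p.shape or m.size < 2:
        raise ValueError("measured and predicted must have equal length >= 2")
    ss_obs = np.sum((m - m.mean()) ** 2)
    if ss_obs == 0:
        raise ValueError("measured series is constant; R^2 undefined")
    return float(1.0 - np.sum((m - p) ** 2) / ss_obs)


def _stack_conditions(ts_by_condition) -> tuple[list[str], np.ndarray]:
    if isinstance(ts_by_condition, dict):
        conds = [c for c in CONDITIONS if c in ts_by_condition]
        if not conds:
            conds = sorted(ts_by_condition)
        runs = [np.asarray(ts_by_condition[c], dtype=float) for c in conds]
    else:
        conds = ["all"]
        runs = [np.asarray(ts_by_condition, dtype=float)]
    return conds, np.concatenate(runs)


def _penalized(theta, lo, hi, scale):
    clipped = np.clip(theta, lo, hi)
    pen = float(np.sum((theta - clipped) ** 2)) * scale
    return clipped, pen


def _init_amp_base(y: np.ndarray, shape: np.ndarray) -> tuple[float, float]:
    A = np.column_stack([shape, np.ones_like(shape)])
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    return float(coef[0]), float(coef[1])


def fit_prf_joint(
    ts_by_condition,
    model: PRFModel,
    init_xy: tuple[float, float],
    init_sigma: float = 1.0,
    bounds: dict | None = None,
    xtol: float = 1e-4,
    maxiter: int = 300,
) -> PRFFit:
    """Fit one Gaussian pRF to all conditions combined (Powell).

    Bounds (x, y in [-5, 5] dva, sigma in [0.05, 10] dva) are enforced by a
    clipping penalty. Non-convergence is flagged on the returned fit rather
    than raised.
    """
    b = bounds or DEFAULT_BOUNDS
    conds, y = _stack_conditions(ts_by_condition)
    n_runs = len(conds)
    lo = np.array([b["xy"][0], b["xy"][0], b["sigma"][0], -np.inf, -np.inf])
    hi = np.array([b["xy"][1], b["xy"][1], b["sigma"][1], np.inf, np.inf])
    pen_scale = 1e4 * max(float(np.var(y)), 1e-12) * y.size

    shape0 = np.tile(model.predict_shape(init_xy[0], init_xy[1], init_sigma), n_runs)
    amp0, base0 = _init_amp_base(y, shape0)
    theta0 = np.array([init_xy[0], init_xy[1], init_sigma, amp0, base0])

    def objective(theta):
        th, pen = _penalized(theta, lo, hi, pen_scale)
        pred = np.tile(model.predict(*th), n_runs)
        return float(np.sum((y - pred) ** 2)) + pen

    res = minimize(
        objective, theta0, method="Powell", options={"xtol": xtol, "maxiter": maxiter}
    )
    th = np.clip(res.x, lo, hi)
    pred = np.tile(model.predict(*th), n_runs)
    params = PRFParams(x=th[0], y=th[1], sigma=th[2], amplitude=th[3], baseline=th[4])
    return PRFFit(params=params, r2=compute_r2(y, pred), converged=bool(res.success))


def fit_prf_per_condition(
    ts_by_condition: dict[str, np.ndarray],
    model: PRFModel,
    joint: PRFFit,
    bounds: dict | None = None,
    xtol: float = 1e-4,
    maxiter: int = 300,
) -> ConditionFitSet:
    """Simultaneous per-condition Gaussian fits with one shared baseline.

    3 conditions x (x, y, sigma, amplitude) + 1 baseline = 13 free
    parameters, initialized at the joint fit; R^2 is computed on the
    concatenated prediction.
    """
    b = bounds or DEFAULT_BOUNDS
    conds = [c for c in CONDITIONS if c in ts_by_condition]
    if len(conds) != 3:
        raise ValueError("per-condition fit requires all three condition runs")
    y = np.concatenate([np.asarray(ts_by_condition[c], dtype=float) for c in conds])
    jp = joint.params
    theta0 = np.concatenate(
        [np.array([jp.x, jp.y, jp.sigma, jp.amplitude]) for _ in conds] + [[jp.baseline]]
    )
    lo1 = np.array([b["xy"][0], b["xy"][0], b["sigma"][0], -np.inf])
    hi1 = np.array([b["xy"][1], b["xy"][1], b["sigma"][1], np.inf])
    lo = np.concatenate([np.tile(lo1, 3), [-np.inf]])
    hi = np.concatenate([np.tile(hi1, 3), [np.inf]])
    pen_scale = 1e4 * max(float(np.var(y)), 1e-12) * y.size
    T = model.n_frames

    def predict_all(th):
        base = th[12]
        preds = [
            base + th[4 * i + 3] * model.predict_shape(th[4 * i], th[4 * i + 1], th[4 * i + 2])
            for i in range(3)
        ]
        return np.concatenate(preds)

    def objective(theta):
        th, pen = _penalized(theta, lo, hi, pen_scale)
        return float(np.sum((y - predict_all(th)) ** 2)) + pen

    res = minimize(
        objective, theta0, method="Powell", options={"xtol": xtol, "maxiter": maxiter}
    )
    th = np.clip(res.x, lo, hi)
    base = float(th[12])
    fits = {
        c: PRFParams(
            x=float(th[4 * i]),
            y=float(th[4 * i + 1]),
            sigma=float(th[4 * i + 2]),
            amplitude=float(th[4 * i + 3]),
            baseline=base,
        )
        for i, c in enumerate(conds)
    }
    r2 = compute_r2(y, predict_all(th))
    flags = [] if res.success else ["nonconvergent"]
    return ConditionFitSet(
        fits=fits, shared_baseline=base, r2=r2, converged=bool(res.success), flags=flags
    )


# ---------------------------------------------------------------------------
# selection
# ---------------------------------------------------------------------------

def select_voxels(
    fits: list[ConditionFitSet],
    ecc_max: float = 3.3,
    size_max: float = 7.2,
    r2_min: float = 0.1,
) -> tuple[np.ndarray, dict[str, int]]:
    """Inclusion mask over fitted voxels plus a per-criterion rejection log.

    Excludes voxels whose Attend Fixation eccentricity exceeds ``ecc_max``
    (edge-of-stimulus artifacts), whose size exceeds ``size_max`` in any
    condition, or whose R^2 falls below ``r2_min``.
    """
    mask = np.ones(len(fits), dtype=bool)
    log = {"ecc": 0, "size": 0, "r2": 0, "total": 0}
    for i, f in enumerate(fits):
        bad = False
        if f.fits["AttendFixation"].ecc > ecc_max:
            log["ecc"] += 1
            bad = True
        if any(p.sigma > size_max for p in f.fits.values()):
            log["size"] += 1
            bad = True
        if f.r2 < r2_min:
            log["r2"] += 1
            bad = True
        if bad:
            log["total"] += 1
            mask[i] = False
    return mask, log


def fits_to_frame(fits: list[ConditionFitSet]) -> pd.DataFrame:
    """Long-format table (voxel_id, condition, x, y, sigma, ...)."""
    rows = []
    for vid, f in enumerate(fits):
        for cond in (*f.fits, "AttendStimulus"):
            p = f.condition(cond)
            rows.append(
                {
                    "voxel_id": vid,
                    "condition": cond,
                    "x": p.x,
                    "y": p.y,
                    "sigma": p.sigma,
                    "ecc": p.ecc,
                    "polar_angle": p.polar_angle,
                    "amplitude": p.amplitude,
                    "baseline": p.baseline,
                    "r2": f.r2,
                    "flags": ";".join(f.flags),
                }
            )
    return pd.DataFrame(rows)
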