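"""Inferential machinery for voxel-population analyses.

Voxel-level statistics are weighted by fit quality (R^2) and tested with a
resampling bootstrap: two-tailed p-values are twice the smaller of the
fractions of bootstrap samples below/above the threshold, floored at
2/n_boot. Multiple comparisons use Benjamini-Hochberg FDR; extreme values
are rejected at five two-sided median absolute deviations; angular
non-uniformity uses the Rayleigh test; correlations are Fisher-transformed
with atanh before comparison to zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from statsmodels.stats.multitest import multipletests

__all__ = [
    "BootstrapResult",
    "weighted_bootstrap",
    "fdr_correct",
    "mad_outlier_mask",
    "rayleigh_test",
    "fisher_z",
]


@dataclass
class BootstrapResult:
    estimate: float
    ci_low: float
    ci_high: float
    p: float
    n_boot: int
    seed: int
    n_redrawn: int = 0


def _weighted_mean(values: np.ndarray, weights: np.ndarray) -> float:
    return float(np.sum(values * weights) / np.sum(weights))


def weighted_bootstrap(
    values: np.ndarray,
    weights: np.ndarray | None = None,
    statistic=None,
    n_boot: int = 100_000,
    threshold: float = 0.0,
    seed: int = 0,
    ci_percentiles: tuple[float, float] = (2.5, 97.5),
) -> BootstrapResult:
    """Resample rows with replacement; weights enter the statistic, not the
    resampling probabilities.

    ``statistic(values, weights) -> float`` defaults to the weighted mean
    (1D values). ``values`` may be 2D (rows are resampled jointly for
    statistics over several columns). Resamples on which the statistic is
    undefined (NaN) are redrawn, counted, and capped at ``n_boot`` extra
    draws. p = 2 * min(frac below, frac above threshold), clamped to
    [2/n_boot, 1].
    """
    values = np.asarray(values, dtype=float)
    n = values.shape[0]
    if n < 2:
        raise ValueError("need at least 2 observations")
    if weights is None:
        weights = np.ones(n)
    weights = np.asarray(weights, dtype=float)
    if weights.shape[0] != n:
        raise ValueError("weights length mismatch")
    if (weights < 0).any() or not (weights > 0).any():
        raise ValueError("weights must be >= 0 and not all zero")
    rng = np.random.default_rng(seed)
    stat = statistic
    if stat is None:
        if values.ndim != 1:
            raise ValueError("default statistic (weighted mean) requires 1D values")
        stat = _weighted_mean

    boot = np.empty(n_boot)
    if statistic is None:
        # vectorized weighted-mean fast path, chunked to bound memory
        chunk = max(1, int(2_000_000 // max(n, 1)))
        done = 0
        while done < n_boot:
            m = min(chunk, n_boot - done)
            idx = rng.integers(0, n, size=(m, n))
            v = values[idx]
            w = weights[idx]
            boot[done : done + m] = (v * w).sum(axis=1) / w.sum(axis=1)
            done += m
        n_redrawn = 0
    else:
        n_redrawn = 0
        max_redraw = n_boot
        i = 0
        while i < n_boot:
            idx = rng.integers(0, n, size=n)
            val = stat(values[idx], weights[idx])
            if np.isnan(val) and n_redrawn < max_redraw:
                n_redrawn += 1
                continue
            boot[i] = val
            i += 1
        boot = boot[np.isfinite(boot)]
        if boot.size == 0:
            raise ValueError("statistic undefined on all bootstrap resamples")

    est = stat(values, weights)
    lo, hi = np.percentile(boot, ci_percentiles)
    frac_below = np.mean(boot < threshold)
    frac_above = np.mean(boot > threshold)
    p = 2.0 * min(frac_below, frac_above)
    p = float(np.clip(p, 2.0 / n_boot, 1.0))
    return BootstrapResult(
        estimate=float(est),
        ci_low=float(lo),
        ci_high=float(hi),
        p=p,
        n_boot=n_boot,
        seed=seed,
        n_redrawn=n_redrawn,
    )


def fdr_correct(pvals: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values (monotone)."""
    pvals = np.asarray(pvals, dtype=float)
    if pvals.size == 0:
        return pvals
    if np.any((pvals < 0) | (pvals > 1)) or not np.all(np.isfinite(pvals)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(pvals.ravel(), method="fdr_bh")[1].reshape(pvals.shape)


def mad_outlier_mask(values: np.ndarray, k: float = 5.0, scaled: bool = False) -> np.ndarray:
    """Inclusion mask: keep values within k (unscaled) MADs of the median.

    MAD = median(|v - median|) with no consistency scaling by default;
    ``scaled=True`` applies the Gaussian-consistency factor 1.4826. A zero
    MAD (more than half the values identical) excludes nothing, with a
    warning.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 3:
        raise ValueError("need at least 3 values for MAD outlier rejection")
    med = np.median(values)
    mad = np.median(np.abs(values - med))
    if scaled:
        mad = 1.4826 * mad
    if mad == 0:
        warnings.warn("MAD is zero; no outliers excluded", stacklevel=2)
        return np.ones(values.shape, dtype=bool)
    return np.abs(values - med) <= k * mad


def rayleigh_test(angles: np.ndarray) -> tuple[float, float]:
    """Rayleigh test of circular non-uniformity.

    Returns (Rbar, p) with Rbar the mean resultant length and p from the
    standard small-sample-corrected approximation
    ``exp(-Z) * (1 + (2Z - Z^2)/(4n) - (24Z - 132Z^2 + 76Z^3 - 9Z^4)/(288 n^2))``
    where ``Z = n * Rbar^2``, clipped to [0, 1] (the expansion degenerates as
    Rbar -> 1).
    """
    angles = np.asarray(angles, dtype=float)
    n = angles.size
    if n < 5:
        raise ValueError("Rayleigh test requires n >= 5")
    rbar = float(np.abs(np.mean(np.exp(1j * angles))))
    z = n * rbar**2
    p = np.exp(-z) * (
        1.0
        + (2 * z - z**2) / (4 * n)
        - (24 * z - 132 * z**2 + 76 * z**3 - 9 * z**4) / (288 * n**2)
    )
    return rbar, float(np.clip(p, 0.0, 1.0))


def fisher_z(r):
    """Fisher transform (inverse hyperbolic tangent); requires |r| < 1."""
    r = np.asarray(r, dtype=float)
    if np.any(np.abs(r) >= 1):
        raise ValueError("Fisher transform requires |r| < 1")
    out = np.arctanh(r)
    return float(out) if out.ndim == 0 else out
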