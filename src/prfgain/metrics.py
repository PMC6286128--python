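"""Descriptive population analyses of attention-induced pRF changes.

All position analyses use the quadrant visual-field format: every
condition's pRF center is mirrored into the first quadrant using the sign
of the Attend Fixation coordinates (cross-meridian shifts keep their sign,
so a shift may exit the quadrant). Shift vectors run from the Attend
Fixation to an attend-stimulus-condition position and are decomposed into
horizontal, vertical and radial (eccentricity) components; eccentricity and
size changes are profiled across Attend Fixation eccentricity; the feature
attention modulation index (AMI) contrasts the pRF changes induced by
attending color versus temporal frequency.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .stats import BootstrapResult, mad_outlier_mask, weighted_bootstrap

__all__ = [
    "mirror_to_quadrant",
    "make_shift_records",
    "decompose_shift_directions",
    "polar_angle_slope_analysis",
    "ecc_size_change_analysis",
    "compute_feature_ami",
    "feature_preference_index",
]


def mirror_to_quadrant(fix_xy: np.ndarray, *others: np.ndarray):
    """Mirror positions into the first quadrant by Attend Fixation signs.

    Every passed position array is multiplied elementwise by
    ``(sign(x_fix), sign(y_fix))`` with zeros treated as +1, so the Attend
    Fixation positions land in the first quadrant while other conditions
    preserve cross-meridian excursions.
    """
    fix_xy = np.asarray(fix_xy, dtype=float)
    signs = np.where(fix_xy >= 0, 1.0, -1.0)
    mirrored = [fix_xy * signs]
    for arr in others:
        arr = np.asarray(arr, dtype=float)
        if arr.shape != fix_xy.shape:
            raise ValueError("position arrays must share the fixation shape")
        mirrored.append(arr * signs)
    return mirrored[0] if not others else tuple(mirrored)


def make_shift_records(
    table: pd.DataFrame, comparison: str = "AttendStimulus", reference: str = "AttendFixation"
) -> pd.DataFrame:
    """Quadrant-mirrored shift records for one condition comparison.

    ``table`` is a wide per-voxel frame with ``{condition}_x/_y`` (and
    optionally ``r2``) columns. Returns one row per voxel with mirrored
    start/end, signed component changes, shift length L, absolute
    components, and the start polar angle (radians in [0, pi/2], 0 at the
    horizontal meridian).
    """
    fix = table[[f"{reference}_x", f"{reference}_y"]].to_numpy()
    other = table[[f"{comparison}_x", f"{comparison}_y"]].to_numpy()
    start, end = mirror_to_quadrant(fix, other)
    d = end - start
    L = np.hypot(d[:, 0], d[:, 1])
    ecc_start = np.hypot(start[:, 0], start[:, 1])
    ecc_end = np.hypot(end[:, 0], end[:, 1])
    out = pd.DataFrame(
        {
            "voxel_id": table.get("voxel_id", pd.RangeIndex(len(table))),
            "start_x": start[:, 0],
            "start_y": start[:, 1],
            "end_x": end[:, 0],
            "end_y": end[:, 1],
            "dx": d[:, 0],
            "dy": d[:, 1],
            "d_ecc": ecc_end - ecc_start,
            "L": L,
            "abs_dx": np.abs(d[:, 0]),
            "abs_dy": np.abs(d[:, 1]),
            "abs_d_ecc": np.abs(ecc_end - ecc_start),
            "polar_angle": np.arctan2(start[:, 1], start[:, 0]),
            "r2": table["r2"].to_numpy() if "r2" in table else np.ones(len(table)),
        }
    )
    if "AttendFixation_sigma" in table and f"{comparison}_sigma" in table:
        out["d_sigma"] = (
            table[f"{comparison}_sigma"].to_numpy() - table["AttendFixation_sigma"].to_numpy()
        )
        out["fix_ecc"] = np.hypot(fix[:, 0], fix[:, 1])
        out["fix_sigma"] = table["AttendFixation_sigma"].to_numpy()
    return out


# ---------------------------------------------------------------------------
# shift direction decomposition
# ---------------------------------------------------------------------------

@dataclass
class ShiftDirectionResult:
    ratios: pd.DataFrame  # component, estimate, ci_low, ci_high
    comparisons: pd.DataFrame  # pair, estimate, p
    n_used: int
    n_zero_length: int


def decompose_shift_directions(
    records: pd.DataFrame, n_boot: int = 10_000, seed: int = 0
) -> ShiftDirectionResult:
    """Mean radial/horizontal/vertical shift ratios with bootstrap tests.

    Per voxel the ratios |d_ecc|/L, |dx|/L, |dy|/L measure how much of the
    shift is explained by each direction hypothesis; zero-length shifts are
    excluded (and counted). Means are r2-weighted; pairwise differences
    (radial-horizontal, horizontal-vertical, radial-vertical) get two-tailed
    bootstrap p-values against zero.
    """
    L = records["L"].to_numpy()
    keep = L > 0
    n_zero = int((~keep).sum())
    if not keep.any():
        raise ValueError("all shift vectors have zero length")
    rec = records.loc[keep]
    w = rec["r2"].to_numpy()
    ratios = {
        "radial": rec["abs_d_ecc"].to_numpy() / rec["L"].to_numpy(),
        "horizontal": rec["abs_dx"].to_numpy() / rec["L"].to_numpy(),
        "vertical": rec["abs_dy"].to_numpy() / rec["L"].to_numpy(),
    }
    rows = []
    for i, (name, vals) in enumerate(ratios.items()):
        res = weighted_bootstrap(vals, w, n_boot=n_boot, seed=seed + i)
        rows.append((name, res.estimate, res.ci_low, res.ci_high))
    ratio_df = pd.DataFrame(rows, columns=["component", "estimate", "ci_low", "ci_high"])
    pairs = [("radial", "horizontal"), ("horizontal", "vertical"), ("radial", "vertical")]
    comp_rows = []
    for i, (a, b) in enumerate(pairs):
        res = weighted_bootstrap(ratios[a] - ratios[b], w, n_boot=n_boot, seed=seed + 10 + i)
        comp_rows.append((f"{a}-{b}", res.estimate, res.p))
    comp_df = pd.DataFrame(comp_rows, columns=["pair", "estimate", "p"])
    return ShiftDirectionResult(
        ratios=ratio_df, comparisons=comp_df, n_used=int(keep.sum()), n_zero_length=n_zero
    )


# ---------------------------------------------------------------------------
# polar-angle slope analysis
# ---------------------------------------------------------------------------

@dataclass
class PolarSlopeResult:
    bins: pd.DataFrame  # bin, angle_center, mean_dx, mean_dy, mean_d_ecc, n
    slope_dx: float  # last minus first bin, vertical -> horizontal ordering
    slope_dy: float
    contrast: BootstrapResult  # slope_dx - slope_dy


def polar_angle_slope_analysis(
    records: pd.DataFrame, n_bins: int = 3, n_boot: int = 10_000, seed: int = 0
) -> PolarSlopeResult:
    """Signed x/y/eccentricity changes across polar-angle bins.

    The folded polar angle is binned equal-width from the vertical meridian
    (first bin) to the horizontal meridian (last bin). Radial shifts produce
    x changes that grow in magnitude toward the horizontal meridian and y
    changes that grow toward the vertical meridian, so the slope (last minus
    first bin) of the x change is more negative than that of the y change
    for foveopetal radial shifts. The contrast slope_dx - slope_dy is
    bootstrap-tested against zero.
    """
    # angle measured from the vertical meridian so bins run vertical -> horizontal
    phi = np.pi / 2 - records["polar_angle"].to_numpy()
    edges = np.linspace(0, np.pi / 2, n_bins + 1)
    bin_of = np.clip(np.searchsorted(edges, phi, side="right") - 1, 0, n_bins - 1)
    w = records["r2"].to_numpy()
    empty = [b for b in range(n_bins) if not (bin_of == b).any()]
    if empty:
        raise ValueError(f"empty polar-angle bins: {empty}")

    def bin_means(dx, dy, de, wt, bins):
        out = np.empty((n_bins, 3))
        for b in range(n_bins):
            sel = bins == b
            if not sel.any():
                return None
            ws = wt[sel].sum()
            out[b] = (
                np.sum(dx[sel] * wt[sel]) / ws,
                np.sum(dy[sel] * wt[sel]) / ws,
                np.sum(de[sel] * wt[sel]) / ws,
            )
        return out

    dx = records["dx"].to_numpy()
    dy = records["dy"].to_numpy()
    de = records["d_ecc"].to_numpy()
    means = bin_means(dx, dy, de, w, bin_of)
    bins_df = pd.DataFrame(
        {
            "bin": np.arange(n_bins),
            "angle_center": (edges[:-1] + edges[1:]) / 2,
            "mean_dx": means[:, 0],
            "mean_dy": means[:, 1],
            "mean_d_ecc": means[:, 2],
            "n": [int((bin_of == b).sum()) for b in range(n_bins)],
        }
    )
    slope_dx = float(means[-1, 0] - means[0, 0])
    slope_dy = float(means[-1, 1] - means[0, 1])

    data = np.column_stack([phi, dx, dy])

    def contrast_stat(vals, wt):
        bins = np.clip(np.searchsorted(edges, vals[:, 0], side="right") - 1, 0, n_bins - 1)
        m = bin_means(vals[:, 1], vals[:, 2], vals[:, 2], wt, bins)
        if m is None:
            return np.nan
        return (m[-1, 0] - m[0, 0]) - (m[-1, 1] - m[0, 1])

    contrast = weighted_bootstrap(
        data, w, statistic=contrast_stat, n_boot=n_boot, seed=seed
    )
    return PolarSlopeResult(
        bins=bins_df, slope_dx=slope_dx, slope_dy=slope_dy, contrast=contrast
    )


# ---------------------------------------------------------------------------
# eccentricity / size change profiles
# ---------------------------------------------------------------------------

@dataclass
class EccSizeChangeResult:
    profile: pd.DataFrame  # the n_ecc_bins-bin d_ecc / d_sigma profile
    percentile_bins: pd.DataFrame  # the n_pct_bins bin means
    pearson_r: float
    r_ci: tuple[float, float]
    degenerate: bool


def ecc_size_change_analysis(
    records: pd.DataFrame,
    n_ecc_bins: int = 4,
    n_pct_bins: int = 20,
    ecc_max: float = 3.3,
    mad_k: float = 5.0,
    n_boot: int = 2000,
    seed: int = 0,
    equal_count: bool = False,
) -> EccSizeChangeResult:
    """Binned eccentricity and size changes plus their correlation.

    ``records`` must come from :func:`make_shift_records` with sigma columns
    present. The coarse profile uses equal-width Attend Fixation
    eccentricity bins over [0, ecc_max] (``equal_count=True`` switches to
    quantile bins) with per-bin MAD outlier rejection
    and r2-weighted means (bootstrap CI and p per bin); the correlation uses
    equal-count (percentile) bins and Pearson r over the bin means with a
    Fisher-transformed CI. Identical conditions (all changes zero) make the
    correlation undefined; this is flagged rather than raised.
    """
    for col in ("d_sigma", "fix_ecc"):
        if col not in records:
            raise ValueError("records lack size information; build them from sigma columns")
    if len(records) < n_pct_bins:
        raise ValueError(f"need at least {n_pct_bins} voxels")
    ecc = records["fix_ecc"].to_numpy()
    de = records["d_ecc"].to_numpy()
    ds = records["d_sigma"].to_numpy()
    w = records["r2"].to_numpy()

    if equal_count:
        edges = np.quantile(ecc, np.linspace(0, 1, n_ecc_bins + 1))
        edges[0], edges[-1] = 0.0, max(ecc_max, edges[-1])
    else:
        edges = np.linspace(0, ecc_max, n_ecc_bins + 1)
    bins = np.clip(np.searchsorted(edges, ecc, side="right") - 1, 0, n_ecc_bins - 1)
    rows = []
    for b in range(n_ecc_bins):
        sel = bins == b
        if not sel.any():
            raise ValueError(f"degenerate eccentricity bin {b} (empty)")
        keep = sel.copy()
        if sel.sum() >= 3:
            sub = np.flatnonzero(sel)
            km = mad_outlier_mask(de[sub], mad_k) & mad_outlier_mask(ds[sub], mad_k)
            keep = np.zeros_like(sel)
            keep[sub[km]] = True
        row = {"bin": b, "bin_center": (edges[b] + edges[b + 1]) / 2, "n": int(keep.sum())}
        for name, vals in (("d_ecc", de), ("d_sigma", ds)):
            if keep.sum() >= 2:
                res = weighted_bootstrap(vals[keep], w[keep], n_boot=n_boot, seed=seed + b)
                row[f"{name}_mean"] = res.estimate
                row[f"{name}_ci_low"] = res.ci_low
                row[f"{name}_ci_high"] = res.ci_high
                row[f"{name}_p"] = res.p
            else:
                row[f"{name}_mean"] = float(np.sum(vals[keep] * w[keep]) / np.sum(w[keep]))
                row[f"{name}_ci_low"] = row[f"{name}_ci_high"] = np.nan
                row[f"{name}_p"] = np.nan
        rows.append(row)
    profile = pd.DataFrame(rows)

    # 5-percentile bins for the change-change correlation
    qedges = np.quantile(ecc, np.linspace(0, 1, n_pct_bins + 1))
    qbins = np.clip(np.searchsorted(qedges, ecc, side="right") - 1, 0, n_pct_bins - 1)
    qrows = []
    for b in range(n_pct_bins):
        sel = np.flatnonzero(qbins == b)
        if sel.size == 0:
            raise ValueError(f"degenerate percentile bin {b}")
        if sel.size >= 3:
            km = mad_outlier_mask(de[sel], mad_k) & mad_outlier_mask(ds[sel], mad_k)
            sel = sel[km]
        ws = w[sel].sum()
        qrows.append(
            {
                "bin": b,
                "ecc_mean": float(np.sum(ecc[sel] * w[sel]) / ws),
                "d_ecc_mean": float(np.sum(de[sel] * w[sel]) / ws),
                "d_sigma_mean": float(np.sum(ds[sel] * w[sel]) / ws),
                "n": int(sel.size),
            }
        )
    pct = pd.DataFrame(qrows)
    a = pct["d_ecc_mean"].to_numpy()
    bvals = pct["d_sigma_mean"].to_numpy()
    degenerate = bool(np.std(a) == 0 or np.std(bvals) == 0)
    if degenerate:
        r, ci = np.nan, (np.nan, np.nan)
    else:
        from scipy.stats import pearsonr

        r = float(pearsonr(a, bvals)[0])
        if abs(r) < 1:
            z = np.arctanh(r)
            se = 1.0 / np.sqrt(n_pct_bins - 3)
            ci = (float(np.tanh(z - 1.96 * se)), float(np.tanh(z + 1.96 * se)))
        else:
            ci = (r, r)
    return EccSizeChangeResult(
        profile=profile, percentile_bins=pct, pearson_r=r, r_ci=ci, degenerate=degenerate
    )


# ---------------------------------------------------------------------------
# feature attention modulation index
# ---------------------------------------------------------------------------

def compute_feature_ami(table: pd.DataFrame, norm: str = "sd") -> pd.DataFrame:
    """Per-voxel AMIs and the feature AMI.

    For each attend-bar condition c the change vector
    ``d_c = (d_ecc_c / s_ecc, d_sigma_c / s_sigma)`` holds that condition's
    eccentricity and size change relative to Attend Fixation, each
    normalized by the across-voxel dispersion (SD by default, variance with
    ``norm='variance'``) of the corresponding Attend Stimulus - Attend
    Fixation difference, making the two components commensurate.
    ``AMI_c = ||d_c||`` and
    ``feature AMI = (AMI_color - AMI_tf) / (AMI_color + AMI_tf)``; voxels
    with a zero denominator are flagged undefined (NaN).
    """
    if len(table) < 2:
        raise ValueError("need at least 2 voxels to estimate dispersion")
    ecc_fix = table["AttendFixation_ecc"].to_numpy()
    sig_fix = table["AttendFixation_sigma"].to_numpy()
    de_stim = table["AttendStimulus_ecc"].to_numpy() - ecc_fix
    ds_stim = table["AttendStimulus_sigma"].to_numpy() - sig_fix
    s_e, s_s = np.std(de_stim, ddof=1), np.std(ds_stim, ddof=1)
    if norm == "variance":
        s_e, s_s = s_e**2, s_s**2
    elif norm != "sd":
        raise ValueError("norm must be 'sd' or 'variance'")
    if s_e == 0 or s_s == 0:
        raise ValueError("zero dispersion of the Stimulus-Fixation differences")
    out = {"voxel_id": table.get("voxel_id", pd.RangeIndex(len(table)))}
    for cond, tag in (("AttendColor", "color"), ("AttendTF", "tf")):
        de = (table[f"{cond}_ecc"].to_numpy() - ecc_fix) / s_e
        ds = (table[f"{cond}_sigma"].to_numpy() - sig_fix) / s_s
        out[f"d_ecc_{tag}"] = de
        out[f"d_sigma_{tag}"] = ds
        out[f"ami_{tag}"] = np.hypot(de, ds)
    df = pd.DataFrame(out)
    denom = df["ami_color"] + df["ami_tf"]
    with np.errstate(invalid="ignore", divide="ignore"):
        df["feature_ami"] = np.where(
            denom > 0, (df["ami_color"] - df["ami_tf"]) / denom, np.nan
        )
    df["fami_defined"] = denom > 0
    if "r2" in table:
        df["r2"] = table["r2"].to_numpy()
    return df


def feature_preference_index(beta_color, beta_tf):
    """Contrast of response amplitudes to color vs temporal frequency.

    ``(beta_color - beta_tf) / (|beta_color| + |beta_tf|)`` in [-1, 1];
    positive values mean color-preferring. Undefined (NaN) when both
    amplitudes are zero.
    """
    bc = np.asarray(beta_color, dtype=float)
    bt = np.asarray(beta_tf, dtype=float)
    denom = np.abs(bc) + np.abs(bt)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(denom > 0, (bc - bt) / denom, np.nan)
    return float(out) if out.ndim == 0 else out
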