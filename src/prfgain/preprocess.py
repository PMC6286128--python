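"""BOLD detrending/normalization and gaze cleaning.

BOLD runs are detrended with a third-order Savitzky-Golay filter (120 s
window) and converted to percent signal change per run. Gaze traces are
cleaned by linearly interpolating blink gaps, rejecting pupil-tracking
spikes whose pupil-size acceleration exceeds a threshold (plus neighbors
within a padding window), and removing slow drift by per-bar-pass median
subtraction; the cleaned gaze is summarized as the median and SD of the
along-traversal component per bar position.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.ndimage import binary_dilation
from scipy.signal import butter, savgol_filter, sosfiltfilt

from .stimulus import BarSequence

__all__ = [
    "savgol_detrend",
    "percent_signal_change",
    "clean_gaze",
    "gaze_summary_by_bar_position",
]


def savgol_detrend(
    ts: np.ndarray, tr_s: float, window_s: float = 120.0, order: int = 3
) -> np.ndarray:
    """Subtract a Savitzky-Golay polynomial trend, re-adding the series mean.

    The window is ``window_s`` seconds rounded up to an odd sample count;
    edges are handled by polynomial fits on the truncated window. Trends up
    to the filter order (cubic by default) are removed exactly.
    """
    ts = np.asarray(ts, dtype=float)
    win = int(round(window_s / tr_s))
    if win % 2 == 0:
        win += 1
    if win < order + 2:
        raise ValueError("window too short for the polynomial order")
    if win > ts.size:
        raise ValueError(f"window of {win} samples longer than series of {ts.size}")
    trend = savgol_filter(ts, win, order, mode="interp")
    return ts - trend + ts.mean()


def percent_signal_change(ts: np.ndarray) -> np.ndarray:
    """Per-run percent signal change: ``100 * (ts - mean) / mean``."""
    ts = np.asarray(ts, dtype=float)
    m = ts.mean()
    if abs(m) < 1e-12:
        raise ValueError("cannot compute percent signal change: run mean is zero")
    return 100.0 * (ts - m) / m


def _interp_invalid(values: np.ndarray, invalid: np.ndarray) -> np.ndarray:
    """Linear interpolation over invalid samples (edge gaps held constant)."""
    out = values.astype(float).copy()
    good = ~invalid
    if not good.any():
        raise ValueError("trace entirely invalid")
    idx = np.arange(values.size)
    out[invalid] = np.interp(idx[invalid], idx[good], out[good])
    return out


def clean_gaze(
    trace: pd.DataFrame,
    hp_cutoff_hz: float = 10.0,
    accel_thresh: float = 1e5,
    pad_s: float = 5.0,
    pass_intervals: list[tuple[float, float]] | None = None,
) -> pd.DataFrame:
    """Clean a raw gaze trace (columns time_s, x, y, pupil, valid).

    Steps: (1) blink gaps (invalid or NaN samples) are linearly
    interpolated; (2) the pupil channel is high-pass filtered at
    ``hp_cutoff_hz`` purely for spike detection, and samples whose pupil
    acceleration exceeds ``accel_thresh`` (units/s^2), together with their
    neighbors within ``pad_s`` seconds, are invalidated and interpolated;
    (3) if bar-pass intervals are supplied, gaze drift is removed by
    subtracting the within-pass median position. The returned trace has no
    missing samples; ``interpolated`` flags every repaired sample.
    """
    t = trace["time_s"].to_numpy(dtype=float)
    if t.size < 16:
        raise ValueError("trace too short to clean")
    dt = float(np.median(np.diff(t)))
    rate = 1.0 / dt
    invalid = ~trace["valid"].to_numpy(dtype=bool)
    for col in ("x", "y", "pupil"):
        invalid |= ~np.isfinite(trace[col].to_numpy(dtype=float))
    x = _interp_invalid(trace["x"].to_numpy(dtype=float), invalid)
    y = _interp_invalid(trace["y"].to_numpy(dtype=float), invalid)
    pupil = _interp_invalid(trace["pupil"].to_numpy(dtype=float), invalid)

    # spike rejection on the high-passed pupil channel
    if rate > 2.0 * hp_cutoff_hz:
        sos = butter(3, hp_cutoff_hz, btype="highpass", fs=rate, output="sos")
        hp = sosfiltfilt(sos, pupil)
    else:
        hp = pupil - pupil.mean()
    accel = np.zeros_like(hp)
    accel[1:-1] = (hp[2:] - 2 * hp[1:-1] + hp[:-2]) / dt**2
    spikes = np.abs(accel) > accel_thresh
    if spikes.any():
        pad = int(round(pad_s * rate))
        spikes = binary_dilation(spikes, structure=np.ones(2 * pad + 1, dtype=bool))
        x = _interp_invalid(x, spikes)
        y = _interp_invalid(y, spikes)
        pupil = _interp_invalid(pupil, spikes)
    repaired = invalid | spikes

    if pass_intervals:
        for start, end in pass_intervals:
            sel = (t >= start) & (t < end)
            if sel.any():
                x[sel] -= np.median(x[sel])
                y[sel] -= np.median(y[sel])
    return pd.DataFrame(
        {
            "time_s": t,
            "x": x,
            "y": y,
            "pupil": pupil,
            "valid": np.ones(t.size, dtype=bool),
            "interpolated": repaired,
        }
    )


def gaze_summary_by_bar_position(trace: pd.DataFrame, seq: BarSequence) -> pd.DataFrame:
    """Median/SD of the along-traversal gaze component per bar position.

    For every pass, gaze is rotated into the traversal frame (the component
    along the bar's direction of motion — the component that matters for pRF
    estimation); samples are pooled across passes within each of the
    ``n_positions_per_pass`` bar positions.
    """
    t = trace["time_s"].to_numpy(dtype=float)
    gx = trace["x"].to_numpy(dtype=float)
    gy = trace["y"].to_numpy(dtype=float)
    table = seq.frame_table()
    bars = table[table["kind"] == "bar"]
    pooled: dict[int, list[np.ndarray]] = {p: [] for p in range(seq.n_positions_per_pass)}
    for _, row in bars.iterrows():
        theta = np.deg2rad(row["direction_deg"])
        ux, uy = np.cos(theta), np.sin(theta)
        sel = (t >= row["time_s"]) & (t < row["time_s"] + seq.dwell_s)
        if sel.any():
            pooled[int(row["position_index"])].append(gx[sel] * ux + gy[sel] * uy)
    rows = []
    for pos in range(seq.n_positions_per_pass):
        if pooled[pos]:
            vals = np.concatenate(pooled[pos])
            rows.append((pos, np.median(vals), vals.std(ddof=0), vals.size))
        else:
            rows.append((pos, np.nan, np.nan, 0))
    return pd.DataFrame(rows, columns=["position_index", "median_along", "sd_along", "n_samples"])
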