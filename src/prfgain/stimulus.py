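"""Bar-stimulus traversal design and hemodynamic forward model.

A retinotopic mapping run consists of a bar of width 0.9 dva sweeping a
circular aperture of radius 3.6 dva in 8 directions (cardinals and
diagonals), stepping 0.34 dva per 1.6 s TR through 24 positions (one pass =
38.4 s), with a 4.8 s pause after every pass and four 38.4 s blank periods.
The rasterized per-frame binary masks form the design matrix that both the
simulator and the pRF fitter consume after convolution with a double-gamma
hemodynamic response function (HRF).

Coordinate convention: the square grid spans ``extent_dva`` centred on
fixation, pixel centers at ``extent*(i+0.5)/n - extent/2``; x increases
rightward, y upward. Arrays are indexed ``[iy, ix]``.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import fftconvolve

__all__ = [
    "BarSequence",
    "DesignMatrix",
    "HRFKernel",
    "DEFAULT_DIRECTIONS",
    "build_bar_sequence",
    "render_design_matrix",
    "hrf_double_gamma",
    "convolve_design",
]

DEFAULT_DIRECTIONS = (0.0, 45.0, 90.0, 135.0, 180.0, 225.0, 270.0, 315.0)


# ---------------------------------------------------------------------------
# bar sequence
# ---------------------------------------------------------------------------

@dataclass
class BarSequence:
    """Timed order of bar passes, pauses and blanks for one run.

    ``passes`` lists the traversal direction (degrees, bar moves along this
    direction) of each pass in presentation order. ``blanks`` holds
    ``(insert_after_pass, duration_s)`` pairs; a blank with insertion point
    ``k`` is shown after the k-th pass (1-based) and its trailing pause.
    """

    passes: list[float]
    n_positions_per_pass: int
    step_dva: float
    dwell_s: float
    pause_s: float
    blanks: list[tuple[int, float]] = field(default_factory=list)
    aperture_radius_dva: float = 3.6
    bar_width_dva: float = 0.9

    def __post_init__(self) -> None:
        if self.n_positions_per_pass < 1:
            raise ValueError("n_positions_per_pass must be >= 1")
        if self.step_dva <= 0 or self.dwell_s <= 0:
            raise ValueError("step_dva and dwell_s must be positive")
        counts = pd.Series(self.passes).value_counts()
        if len(counts) > 1 and counts.nunique() > 1:
            raise ValueError("each direction must occur equally often per run")

    @property
    def n_passes(self) -> int:
        return len(self.passes)

    @property
    def pass_duration_s(self) -> float:
        return self.n_positions_per_pass * self.dwell_s

    @property
    def total_duration_s(self) -> float:
        return (
            self.n_passes * (self.pass_duration_s + self.pause_s)
            + sum(d for _, d in self.blanks)
        )

    def position_offsets_dva(self) -> np.ndarray:
        """Signed offsets of the bar center along the traversal direction.

        The traversal is symmetric about fixation and spans
        ``n_positions * step`` dva (aperture diameter plus bar width for the
        default geometry), so the first and last bars sit partly outside the
        aperture and are clipped at render time.
        """
        n = self.n_positions_per_pass
        return (np.arange(n) - (n - 1) / 2.0) * self.step_dva

    def frame_table(self) -> pd.DataFrame:
        """Expand the sequence to one row per TR-length frame.

        Columns: frame, time_s, kind (bar/pause/blank), direction_deg,
        position_index, is_blank. Pause and blank frames carry NaN direction
        and position index -1.
        """
        n_pause = int(round(self.pause_s / self.dwell_s))
        blanks_after = {}
        for k, dur in self.blanks:
            blanks_after.setdefault(int(k), 0.0)
            blanks_after[int(k)] += dur
        rows = []

        def add(kind, direction, pos):
            rows.append((kind, direction, pos))

        for ipass, direction in enumerate(self.passes, start=1):
            for pos in range(self.n_positions_per_pass):
                add("bar", direction, pos)
            for _ in range(n_pause):
                add("pause", np.nan, -1)
            if ipass in blanks_after:
                nb = int(round(blanks_after[ipass] / self.dwell_s))
                for _ in range(nb):
                    add("blank", np.nan, -1)
        df = pd.DataFrame(rows, columns=["kind", "direction_deg", "position_index"])
        df.insert(0, "frame", np.arange(len(df)))
        df.insert(1, "time_s", df["frame"] * self.dwell_s)
        df["is_blank"] = df["kind"] == "blank"
        return df

    def to_tsv(self, path) -> None:
        self.frame_table().to_csv(path, sep="\t", index=False)


def build_bar_sequence(
    n_passes_per_direction: int = 3,
    directions: tuple[float, ...] = DEFAULT_DIRECTIONS,
    n_positions_per_pass: int = 24,
    step_dva: float = 0.34,
    dwell_s: float = 1.6,
    pause_s: float = 4.8,
    n_blanks: int = 4,
    blank_duration_s: float = 38.4,
    blank_insertion_points: tuple[int, ...] | None = None,
    aperture_radius_dva: float = 3.6,
    bar_width_dva: float = 0.9,
    seed: int = 0,
) -> BarSequence:
    """Build one run: every direction repeated equally in seeded random order.

    By default 3 passes per each of 8 directions (24 passes), a pause after
    every pass, and 4 blank periods inserted after every 6th pass.
    """
    if n_passes_per_direction < 1:
        raise ValueError("n_passes_per_direction must be >= 1")
    n_passes = n_passes_per_direction * len(directions)
    if blank_insertion_points is None:
        if n_blanks > 0:
            if n_passes % n_blanks != 0:
                raise ValueError(
                    f"{n_blanks} blanks do not divide evenly into {n_passes} passes; "
                    "pass blank_insertion_points explicitly"
                )
            spacing = n_passes // n_blanks
            blank_insertion_points = tuple(spacing * (i + 1) for i in range(n_blanks))
        else:
            blank_insertion_points = ()
    rng = np.random.default_rng(seed)
    order = np.repeat(np.asarray(directions, dtype=float), n_passes_per_direction)
    order = order[rng.permutation(order.size)]
    return BarSequence(
        passes=list(order),
        n_positions_per_pass=n_positions_per_pass,
        step_dva=step_dva,
        dwell_s=dwell_s,
        pause_s=pause_s,
        blanks=[(k, blank_duration_s) for k in blank_insertion_points],
        aperture_radius_dva=aperture_radius_dva,
        bar_width_dva=bar_width_dva,
    )


# ---------------------------------------------------------------------------
# design matrix
# ---------------------------------------------------------------------------

@dataclass
class DesignMatrix:
    """Per-frame binary stimulus masks on an ``n x n`` grid."""

    frames: np.ndarray  # (T, n, n) uint8
    grid_n: int
    extent_dva: float
    frame_times: np.ndarray  # (T,) seconds
    table: pd.DataFrame  # frame metadata from BarSequence.frame_table()

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def dt_s(self) -> float:
        return float(self.frame_times[1] - self.frame_times[0])

    @property
    def pixel_size_dva(self) -> float:
        return self.extent_dva / self.grid_n

    def pixel_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Return (x, y) coordinate images, shape (n, n), y increasing with row."""
        c = self.extent_dva * (np.arange(self.grid_n) + 0.5) / self.grid_n - self.extent_dva / 2
        x, y = np.meshgrid(c, c)
        return x, y

    def bar_frame_mask(self) -> np.ndarray:
        return (self.table["kind"] == "bar").to_numpy()

    def unique_bar_masks(self) -> tuple[np.ndarray, np.ndarray]:
        """Deduplicate the bar-on frames.

        Opposite traversal directions render identical strips, so the default
        run's 576 bar frames reduce to 96 distinct masks. Returns
        ``(masks, frame_to_unique)`` where ``frame_to_unique`` maps every
        frame to its mask index, -1 for blank/pause frames.
        """
        lookup: dict[bytes, int] = {}
        masks: list[np.ndarray] = []
        mapping = np.full(self.n_frames, -1, dtype=np.int64)
        is_bar = self.bar_frame_mask()
        for t in np.flatnonzero(is_bar):
            key = self.frames[t].tobytes()
            idx = lookup.get(key)
            if idx is None:
                idx = len(masks)
                lookup[key] = idx
                masks.append(self.frames[t])
            mapping[t] = idx
        return np.asarray(masks), mapping

    def save_npz(self, path) -> None:
        np.savez_compressed(
            path,
            frames=self.frames,
            grid_n=self.grid_n,
            extent_dva=self.extent_dva,
            frame_times=self.frame_times,
        )


def render_design_matrix(
    seq: BarSequence,
    grid_n: int,
    extent_dva: float = 7.2,
    apply_aperture: bool = True,
) -> DesignMatrix:
    """Rasterize a bar sequence into per-frame binary masks.

    A pixel is on when its center lies within half a bar width of the bar
    center line (the line perpendicular to the traversal direction through
    the bar center), and — if ``apply_aperture`` — within the circular
    aperture. Blank and pause frames are all-zero.
    """
    if grid_n < 3:
        raise ValueError("grid_n must be >= 3")
    table = seq.frame_table()
    c = extent_dva * (np.arange(grid_n) + 0.5) / grid_n - extent_dva / 2
    x, y = np.meshgrid(c, c)
    if apply_aperture:
        aperture = (x**2 + y**2) <= seq.aperture_radius_dva**2
    else:
        aperture = np.ones_like(x, dtype=bool)
    offsets = seq.position_offsets_dva()
    frames = np.zeros((len(table), grid_n, grid_n), dtype=np.uint8)
    bar_rows = table[table["kind"] == "bar"]
    # cache per (direction, position) since passes repeat
    cache: dict[tuple[float, int], np.ndarray] = {}
    for t, direction, pos in zip(
        bar_rows["frame"], bar_rows["direction_deg"], bar_rows["position_index"]
    ):
        key = (float(direction), int(pos))
        mask = cache.get(key)
        if mask is None:
            theta = np.deg2rad(direction)
            ux, uy = np.cos(theta), np.sin(theta)
            proj = x * ux + y * uy - offsets[int(pos)]
            mask = ((np.abs(proj) <= seq.bar_width_dva / 2) & aperture).astype(np.uint8)
            cache[key] = mask
        frames[t] = mask
    return DesignMatrix(
        frames=frames,
        grid_n=grid_n,
        extent_dva=extent_dva,
        frame_times=table["time_s"].to_numpy(dtype=float),
        table=table,
    )


# ---------------------------------------------------------------------------
# hemodynamic response
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HRFParams:
    peak_delay_s: float = 6.0
    undershoot_delay_s: float = 16.0
    peak_dispersion: float = 1.0
    undershoot_dispersion: float = 1.0
    peak_undershoot_ratio: float = 6.0
    length_s: float = 32.0


@dataclass
class HRFKernel:
    """Sampled double-gamma impulse response, normalized to unit sum."""

    dt_s: float
    weights: np.ndarray
    params: HRFParams

    @property
    def duration_s(self) -> float:
        return self.weights.size * self.dt_s


def hrf_double_gamma(params: HRFParams | None = None, dt_s: float = 1.6) -> HRFKernel:
    """Canonical two-gamma HRF sampled at ``dt_s``.

    Each lobe is a gamma density with mode at the stated delay
    (shape = delay/dispersion + 1, scale = dispersion); the undershoot is
    subtracted at 1/ratio amplitude. Weights are normalized to sum to 1 so
    convolution preserves the scale of sustained responses.
    """
    from scipy.stats import gamma as gamma_dist

    p = params or HRFParams()
    if dt_s <= 0:
        raise ValueError("dt_s must be positive")
    if p.peak_delay_s <= 0 or p.undershoot_delay_s <= 0:
        raise ValueError("HRF delays must be positive")
    if p.peak_dispersion <= 0 or p.undershoot_dispersion <= 0:
        raise ValueError("HRF dispersions must be positive")
    if p.length_s < 20.0:
        raise ValueError("HRF kernel length must be >= 20 s")
    t = np.arange(0.0, p.length_s, dt_s)
    peak = gamma_dist.pdf(t, p.peak_delay_s / p.peak_dispersion + 1, scale=p.peak_dispersion)
    under = gamma_dist.pdf(
        t, p.undershoot_delay_s / p.undershoot_dispersion + 1, scale=p.undershoot_dispersion
    )
    w = peak - under / p.peak_undershoot_ratio
    w = w / w.sum()
    return HRFKernel(dt_s=dt_s, weights=w, params=p)


def convolve_design(dm: DesignMatrix, hrf: HRFKernel) -> np.ndarray:
    """Causal HRF convolution of every pixel's stimulation time course.

    Returns the regressor stack, shape ``(T, grid_n**2)`` float32, truncated
    to the design's frame count. The HRF must be sampled at the frame
    interval.
    """
    if abs(hrf.dt_s - dm.dt_s) > 1e-9:
        raise ValueError(
            f"HRF sampled at {hrf.dt_s} s but design frames are {dm.dt_s} s apart"
        )
    T = dm.n_frames
    flat = dm.frames.reshape(T, -1).astype(np.float32)
    out = fftconvolve(flat, hrf.weights[:, None].astype(np.float32), axes=0)[:T]
    return out.astype(np.float32)


def convolve_timeseries(neural: np.ndarray, hrf: HRFKernel) -> np.ndarray:
    """Causal HRF convolution of a 1D neural time course, truncated to length."""
    return fftconvolve(neural, hrf.weights)[: neural.shape[0]]
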