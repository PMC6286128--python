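"""Stage orchestration: simulate -> preprocess -> fit -> gainfield -> metrics -> report.

Each stage reads only upstream artifacts from the output directory, writes
versioned TSV/JSON (arrays as compressed .npz) plus a manifest recording
the configuration, seeds and counts, and never mutates another stage's
outputs — any stage can be reproduced in isolation from the manifests.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import fitting, gainfield, metrics, preprocess
from .config import PipelineConfig
from .stimulus import build_bar_sequence, convolve_design, hrf_double_gamma, render_design_matrix
from .synth import (
    CONDITIONS,
    GenerativeAFSpec,
    generate_bold_timeseries,
    sample_ground_truth_voxels,
    voxels_to_frame,
)

__all__ = ["STAGES", "run_pipeline", "read_external_volume"]

STAGES = ("simulate", "preprocess", "fit", "gainfield", "metrics", "report")

log = logging.getLogger("prfgain")


def _write_json(path: Path, payload: dict) -> None:
    path.write_text(json.dumps(payload, indent=2, sort_keys=True, default=float) + "\n")


def _require(path: Path, stage: str, needed_by: str) -> Path:
    if not path.exists():
        raise FileNotFoundError(
            f"stage '{needed_by}' requires output of stage '{stage}' ({path.name}); run it first"
        )
    return path


def _build_designs(cfg: PipelineConfig):
    sc = cfg.stimulus
    seq = build_bar_sequence(
        n_passes_per_direction=sc.n_passes_per_direction,
        n_positions_per_pass=sc.n_positions_per_pass,
        step_dva=sc.step_dva,
        dwell_s=sc.dwell_s,
        pause_s=sc.pause_s,
        n_blanks=sc.n_blanks,
        blank_duration_s=sc.blank_duration_s,
        aperture_radius_dva=sc.aperture_radius_dva,
        bar_width_dva=sc.bar_width_dva,
        seed=sc.order_seed,
    )
    dm31 = render_design_matrix(seq, sc.grid_coarse, sc.extent_dva)
    dm101 = render_design_matrix(seq, sc.grid_fine, sc.extent_dva)
    hrf = hrf_double_gamma(dt_s=sc.dwell_s)
    return seq, dm31, dm101, hrf


def run_pipeline(
    config: PipelineConfig | None = None,
    stages=("simulate", "preprocess", "fit", "gainfield", "metrics", "report"),
    out_dir="prfgain_out",
    seed: int | None = None,
) -> Path:
    """Run the requested stages, returning the artifact directory."""
    cfg = config or PipelineConfig()
    if seed is not None:
        cfg.simulation.seed = int(seed)
        cfg.stats.seed = int(seed)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    seq, dm31, dm101, hrf = _build_designs(cfg)

    if "simulate" in stages:
        _stage_simulate(cfg, out, seq, dm101, hrf)
    if "preprocess" in stages:
        _stage_preprocess(cfg, out)
    if "fit" in stages:
        _stage_fit(cfg, out, dm31, dm101, hrf)
    if "gainfield" in stages:
        _stage_gainfield(cfg, out, dm101)
    if "metrics" in stages:
        _stage_metrics(cfg, out)
    if "report" in stages:
        _stage_report(cfg, out, dm101)
    return out


def _stage_simulate(cfg, out, seq, dm101, hrf):
    sim = cfg.simulation
    voxels = sample_ground_truth_voxels(
        sim.n_voxels,
        ecc_range=(sim.ecc_lo, sim.ecc_hi),
        size_intercept=sim.size_intercept,
        size_slope=sim.size_slope,
        size_jitter_sd=sim.size_jitter_sd,
        amplitude=sim.amplitude,
        baseline=sim.baseline,
        meridian_bias=sim.meridian_bias,
        seed=sim.seed,
    )
    af = GenerativeAFSpec(
        sigma_fix=sim.sigma_fix,
        sigma_stim_color=sim.sigma_stim_color,
        sigma_stim_tf=sim.sigma_stim_tf,
    )
    bold = np.empty((len(CONDITIONS), sim.n_voxels, dm101.n_frames))
    for ci, cond in enumerate(CONDITIONS):
        for vi, vox in enumerate(voxels):
            ts = generate_bold_timeseries(
                vox, dm101, cond, af, hrf, noise_sd=sim.noise_sd,
                seed=sim.seed * 1_000_003 % (2**31) + ci * sim.n_voxels + vi,
            )
            bold[ci, vi] = ts.values
    voxels_to_frame(voxels).to_csv(out / "ground_truth_voxels.tsv", sep="\t", index=False)
    np.savez_compressed(out / "bold.npz", bold=bold, conditions=np.array(CONDITIONS))
    seq.to_tsv(out / "design_frames.tsv")
    _write_json(
        out / "simulate_manifest.json",
        {
            "config": cfg.to_dict(),
            "n_voxels": sim.n_voxels,
            "n_frames": dm101.n_frames,
            "conditions": list(CONDITIONS),
        },
    )
    log.info("simulated %d voxels x %d conditions", sim.n_voxels, len(CONDITIONS))


def _stage_preprocess(cfg, out):
    path = _require(out / "bold.npz", "simulate", "preprocess")
    bold = np.load(path)["bold"]
    tr = cfg.stimulus.dwell_s
    proc = np.empty_like(bold)
    for ci in range(bold.shape[0]):
        for vi in range(bold.shape[1]):
            ts = preprocess.savgol_detrend(bold[ci, vi], tr_s=tr)
            proc[ci, vi] = preprocess.percent_signal_change(ts)
    np.savez_compressed(out / "bold_preprocessed.npz", bold=proc)
    _write_json(
        out / "preprocess_manifest.json",
        {"savgol_window_s": 120.0, "savgol_order": 3, "units": "percent signal change"},
    )


def _stage_fit(cfg, out, dm31, dm101, hrf):
    path = _require(out / "bold_preprocessed.npz", "preprocess", "fit")
    bold = np.load(path)["bold"]
    fc = cfg.fitting
    regress31 = convolve_design(dm31, hrf)
    factor = fitting.ridge_factor(regress31, fc.ridge_lambda)
    model = fitting.PRFModel(dm101, hrf)
    bounds = {"xy": (-fc.xy_bound, fc.xy_bound), "sigma": (fc.sigma_lo, fc.sigma_hi)}
    fits = []
    for vi in range(bold.shape[1]):
        ts = {cond: bold[ci, vi] for ci, cond in enumerate(CONDITIONS)}
        concat = np.concatenate([ts[c] for c in CONDITIONS])
        init = fitting.ridge_init(
            concat, regress31, dm31.grid_n, dm31.extent_dva, fc.ridge_lambda, factor=factor
        )
        joint = fitting.fit_prf_joint(ts, model, init, bounds=bounds, xtol=fc.xtol, maxiter=fc.maxiter)
        fits.append(
            fitting.fit_prf_per_condition(ts, model, joint, bounds=bounds, xtol=fc.xtol, maxiter=fc.maxiter)
        )
    mask, sel_log = fitting.select_voxels(fits, fc.ecc_max, fc.size_max, fc.r2_min)
    table = fitting.fits_to_frame(fits)
    table["selected"] = np.repeat(mask, 4)
    table.to_csv(out / "prf_fits.tsv", sep="\t", index=False)
    _write_json(
        out / "fit_manifest.json",
        {"n_voxels": int(bold.shape[1]), "n_selected": int(mask.sum()), "rejections": sel_log},
    )
    log.info("fitted %d voxels, selected %d", bold.shape[1], int(mask.sum()))


def _load_wide_fits(out: Path, needed_by: str) -> pd.DataFrame:
    path = _require(out / "prf_fits.tsv", "fit", needed_by)
    table = pd.read_csv(path, sep="\t")
    wide = table.pivot(index="voxel_id", columns="condition")
    flat = pd.DataFrame({"voxel_id": wide.index})
    for cond in (*CONDITIONS, "AttendStimulus"):
        for p in ("x", "y", "sigma", "ecc"):
            flat[f"{cond}_{p}"] = wide[(p, cond)].to_numpy()
    flat["r2"] = wide[("r2", "AttendFixation")].to_numpy()
    flat["selected"] = wide[("selected", "AttendFixation")].to_numpy()
    return flat[flat["selected"]].reset_index(drop=True)


def _stage_gainfield(cfg, out, dm101):
    flat = _load_wide_fits(out, "gainfield")
    mc = cfg.model
    start, end = metrics.mirror_to_quadrant(
        flat[["AttendFixation_x", "AttendFixation_y"]].to_numpy(),
        flat[["AttendStimulus_x", "AttendStimulus_y"]].to_numpy(),
    )
    binned = gainfield.bin_shift_vectors_quadrant(
        start,
        end,
        flat["AttendFixation_sigma"].to_numpy(),
        flat["r2"].to_numpy(),
        ecc_max=cfg.fitting.ecc_max,
        n_bins_per_dim=mc.n_bins_per_dim,
    )
    grid = gainfield.AttentionFieldModel(
        sigma_fix_range=(mc.sigma_fix_lo, mc.sigma_fix_hi),
        sigma_stim_range=(mc.sigma_stim_lo, mc.sigma_stim_hi),
        grid_n_per_dim=mc.grid_n_per_dim,
        bar_width_dva=cfg.stimulus.bar_width_dva,
    )
    result = gainfield.fit_af_sizes(binned, dm101, grid)
    result.surface_frame().to_csv(out / "af_surface.tsv", sep="\t", index=False)
    _write_json(
        out / "af_summary.json",
        {**result.summary(), "n_empty_bins": binned.n_empty},
    )
    log.info(
        "gain-field fit: sigma_fix=%.3f kernel=%.3f (effective %.3f)",
        result.sigma_fix, result.sigma_stim_kernel, result.effective_stim_size,
    )


def _stage_metrics(cfg, out):
    flat = _load_wide_fits(out, "metrics")
    st = cfg.stats
    records = metrics.make_shift_records(flat)
    from .stats import rayleigh_test

    # non-uniformity of folded polar angles (meridian overrepresentation);
    # the fold is unwrapped onto the full circle before testing
    rbar, rayleigh_p = rayleigh_test(4 * records["polar_angle"].to_numpy())
    shift = metrics.decompose_shift_directions(records, n_boot=st.n_boot, seed=st.seed)
    polar = metrics.polar_angle_slope_analysis(records, n_boot=st.n_boot, seed=st.seed)
    try:
        eccsize = metrics.ecc_size_change_analysis(
            records, mad_k=st.mad_k, n_boot=min(st.n_boot, 2000), seed=st.seed
        )
        ecc_summary = {
            "pearson_r": eccsize.pearson_r,
            "r_ci": list(eccsize.r_ci),
            "degenerate": eccsize.degenerate,
        }
        eccsize.profile.to_csv(out / "ecc_size_profile.tsv", sep="\t", index=False)
        eccsize.percentile_bins.to_csv(out / "ecc_size_pct_bins.tsv", sep="\t", index=False)
    except ValueError as err:
        ecc_summary = {"error": str(err)}
    ami = metrics.compute_feature_ami(flat)
    ami.to_csv(out / "feature_ami.tsv", sep="\t", index=False)
    defined = ami.loc[ami["fami_defined"], "feature_ami"].to_numpy()
    keep = metrics.mad_outlier_mask(defined, st.mad_k) if defined.size >= 3 else np.ones(defined.size, bool)
    fami_boot = metrics.weighted_bootstrap(
        defined[keep],
        ami.loc[ami["fami_defined"], "r2"].to_numpy()[keep] if "r2" in ami else None,
        n_boot=st.n_boot,
        seed=st.seed,
    )
    shift.ratios.to_csv(out / "shift_ratios.tsv", sep="\t", index=False)
    polar.bins.to_csv(out / "polar_angle_bins.tsv", sep="\t", index=False)
    _write_json(
        out / "metrics_summary.json",
        {
            "shift_ratio_comparisons": shift.comparisons.to_dict(orient="records"),
            "polar_slope_dx": polar.slope_dx,
            "polar_slope_dy": polar.slope_dy,
            "polar_contrast_p": polar.contrast.p,
            "ecc_size": ecc_summary,
            "polar_angle_rayleigh": {"rbar": rbar, "p": rayleigh_p},
            "feature_ami_mean": fami_boot.estimate,
            "feature_ami_p": fami_boot.p,
            "feature_ami_ci": [fami_boot.ci_low, fami_boot.ci_high],
            "n_voxels": int(len(flat)),
        },
    )


def _stage_report(cfg, out, dm101):
    report: dict = {"n_frames": int(dm101.n_frames)}
    for name, fname in (
        ("simulate", "simulate_manifest.json"),
        ("fit", "fit_manifest.json"),
        ("gainfield", "af_summary.json"),
        ("metrics", "metrics_summary.json"),
    ):
        p = out / fname
        if p.exists():
            payload = json.loads(p.read_text())
            payload.pop("config", None)
            report[name] = payload
    _write_json(out / "report.json", report)
    print(json.dumps(report, indent=2, sort_keys=True))


def read_external_volume(path, mask_path=None) -> tuple[pd.DataFrame, np.ndarray]:
    """Load a 4-D NIfTI volume into a voxel x time table.

    ``mask_path`` optionally names a 3-D volume whose nonzero voxels are
    kept. Voxels containing NaN are dropped (logged). Returns the table and
    the (n_voxels, 3) array mapping rows to volume indices.
    """
    import nibabel as nib

    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 4:
        raise ValueError("expected a 4-D volume")
    if mask_path is not None:
        mask = np.asarray(nib.load(str(mask_path)).dataobj) != 0
        if mask.shape != data.shape[:3]:
            raise ValueError("mask shape does not match the volume")
    else:
        mask = np.ones(data.shape[:3], dtype=bool)
    idx = np.argwhere(mask)
    if idx.shape[0] == 0:
        raise ValueError("mask selects no voxels")
    series = data[mask]
    finite = np.isfinite(series).all(axis=1)
    n_nan = int((~finite).sum())
    if n_nan:
        log.info("dropped %d NaN voxels", n_nan)
    series = series[finite]
    idx = idx[finite]
    table = pd.DataFrame(series)
    table.insert(0, "voxel_id", np.arange(series.shape[0]))
    return table, idx
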