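# Methods

`prfgain` implements a complete, simulation-validated pipeline for studying
how spatial and feature-based attention change the sampling of visual space
in retinotopic cortex: population receptive field (pRF) mapping with a
traversing-bar stimulus, a multiplicative attentional gain-field model that
explains condition-dependent pRF changes, and the population statistics
used to characterize those changes.

## The measurement model

A voxel's pRF is an isotropic 2D Gaussian over visual space (center
`(x, y)` and size `sigma`, all in degrees of visual angle, dva). Its BOLD
prediction is the spatial overlap of the Gaussian (unit peak; the
amplitude parameter carries scale) with the binary bar mask of each frame,
convolved with a hemodynamic response function and scaled affinely:

```
y(t) = baseline + amplitude * (h * <dm(t), G_xy,sigma>)(t)
```

The stimulus is a 0.9-dva-wide bar traversing a 7.2-dva circular aperture
in 8 directions (3 passes each, seeded random order), stepping 0.34 dva
per 1.6 s TR through 24 positions (38.4 s per pass), with a 4.8 s pause
after every pass and four 38.4 s blanks after every 6th pass — 744 frames
per run. Opposite traversal directions render identical masks, so the
24 x 8 bar stimuli reduce to 96 distinct masks; this identity is exploited
throughout (averages over "all unique bar stimuli" run over the 96
distinct masks, which is arithmetically identical to running over 192 with
each mask counted twice).

The HRF is a fixed double-gamma kernel (peak 6 s, undershoot 16 s, unit
dispersions, peak:undershoot 6, 32 s support, unit sum). Each gamma lobe
is parameterized so its mode sits exactly at the stated delay
(shape = delay/dispersion + 1). Subject-specific HRF estimation is out of
scope; simulator and fitter share this kernel.

## pRF estimation (three steps)

1. **Coarse localization.** Ridge regression (lambda = 1e6) of the
   (per-run z-scored) voxel time course on the 961 HRF-convolved pixel
   regressors of a 31 x 31 design matrix; the argmax coefficient gives the
   initial center. Exact ties resolve to the lowest flattened pixel index.
2. **Joint fit.** A single Gaussian (x, y, sigma, amplitude, baseline) is
   fitted to all conditions combined on a 101 x 101 grid with Powell's
   derivative-free direction-set method, initialized at step 1's center
   (sigma at 1 dva; amplitude/baseline by least squares at the
   initialization). Bounds (x, y in [-5, 5] dva, sigma in [0.05, 10] dva)
   are enforced by a clipping penalty; parameter tolerance 1e-4.
   Non-convergent fits are flagged, not raised; they leave the analysis
   through the R^2 filter, mirroring the filter-based rejection the
   pipeline applies anyway.
3. **Per-condition fit.** One Gaussian per condition (Attend Fixation /
   Attend Color / Attend TF), all parameters free except a single shared
   baseline (13 parameters), initialized at step 2. "Attend Stimulus" is
   the element-wise parameter mean of the two attend-bar conditions.

Fit quality is `R^2 = 1 - SS_res / SS_obs` on the concatenated prediction;
voxels are excluded when the Attend Fixation eccentricity exceeds 3.3 dva,
any condition's sigma exceeds 7.2 dva, or R^2 < 0.1. R^2 also weights all
population statistics.

## The attentional gain-field model

The measured pRF is modelled as the pointwise product of a stimulus-driven
Gaussian (SD) with a Gaussian attentional gain field (AF). Products and
quotients of isotropic Gaussians are Gaussians, so:

- **Attend Fixation**: measured pRF = SD x AFfix (AFfix centered at
  fixation). Inverting by Gaussian division
  (`1/sigma_SD^2 = 1/sigma_meas^2 - 1/sigma_fix^2`, precision-weighted
  center relation) recovers the SD, provided the measured pRF is narrower
  than AFfix; non-invertible voxels are flagged and excluded.
- **Attend Stimulus**: attention travels with the bar, so the model
  predicts the measured position as the peak of the average, over the 96
  distinct bar masks, of (bar * AFstim kernel) x SD, each product rescaled
  to a maximum of 1 — the pRF "smeared" along the attended trajectory.

The two AF sizes are estimated by exhaustive search on a 50 x 50 grid
(AFfix sigma 1.5-2.5 dva; AFstim kernel sigma 0.6-1.6 dva; start-anchored
spacing of 0.02 dva, an endpoint-inclusive option exists), minimizing the
mean squared Euclidean distance between predicted and observed
attend-stimulus positions of at most 64 vectors formed by 8 x 8
equal-width binning of the quadrant-mirrored visual field
(r2-weighted bin means; empty bins are omitted and counted). Because the
SD division needs a size as well as a position, each binned vector also
carries the r2-weighted mean measured Attend Fixation sigma of its bin.
Vectors non-invertible at a particular AFfix value are dropped from that
cell only (hence the mean rather than the sum of squared distances, to
keep cells comparable); a cell with no invertible vectors scores +inf.
Ties resolve toward smaller sigma_fix, then smaller kernel. Reported
stimulus-AF sizes add the 0.9 dva bar width to the kernel sigma (the bar
convolution makes the effective field that much wider); the raw kernel
sigma is stored alongside.

### Numerical evaluation of the position prediction

The prediction needs, per frame, the maximum of (blurred bar x SD) over
the 101 x 101 grid, and then the peak of the frame average. The
single-voxel predictor evaluates both exactly, in float64 (SD tails below
float32 range still matter because every frame is rescaled to unit peak).
The 2500-cell grid search batches this: maxima and peaks are located on a
stride-5 subgrid and then evaluated exactly within an 11 x 11 window
around the coarse argmax — exact for fields whose feature scale exceeds a
few pixels, which holds here (kernel sigma >= 0.6 dva ~ 8 px). Peaks are
refined to sub-pixel precision with a 3-point parabolic fit per axis;
without refinement the 0.071-dva grid quantization plateaus the objective
across neighboring cells of the 0.02-dva parameter grid. Frames whose
product underflows to zero are skipped; a voxel whose SD misses the
stimulated region entirely raises an error.

### Properties worth knowing

- The grid-search inversion is exact on noise-free forward data (the
  generative cell attains an objective within numerical zero).
- The predicted pull is **not monotone in the kernel size**: for a
  peripheral SD it vanishes in the flat-gain limit, peaks at intermediate
  kernels (around 1.3-1.5 dva for an SD of 1 dva at 2 dva eccentricity),
  and becomes small again for very narrow kernels, whose per-frame
  products track the bar so tightly that the unit-peak average re-centers
  on the SD. Plain Gaussian multiplication with a static gain field *is*
  monotone (smaller field, larger shift); the averaging over bar positions
  breaks it.
- The objective surface has a shallow diagonal valley (larger AFfix traded
  against a smaller stimulus kernel), consistent with the deliberate
  construction of the two grid ranges around equal effective sizes. Under
  measurement noise the argmin wanders along this valley; see the
  synthetic-data section for what recovery accuracy the tests establish.

## Synthetic data: what it emulates, and what it does not

The generator owns the study conditions. Ground-truth voxels have centers
uniform on an eccentricity annulus (optionally biased toward the
horizontal meridian with density `1 + kappa*cos(2*theta)`, emulating its
well-documented cortical overrepresentation), sizes linear in
eccentricity with Gaussian jitter, and a feature preference that falls
linearly with eccentricity (color preference greatest near the fovea).

BOLD generation under Attend Fixation uses the closed-form SD x AFfix
product. For the attend-bar conditions the default is the
**model-consistent measurement reading**: the voxel's effective pRF is a
Gaussian centered at the model's predicted position with the closed-form
product sigma of the SD and the effective stimulus field (kernel + bar
width). Two ablation modes exist: `"moving"` builds the frame-wise
effective pRF (SD x unit-peak blurred bar, attention travelling with the
bar) and `"profile"` uses the run-averaged smeared profile as one static
effective pRF. The moving reading is *not* the default because a Gaussian
fitted to such data sits essentially at the SD center — slightly outside
it for peripheral voxels — rather than at the model's predicted position:
the smeared-profile peak is a claim about where attention relocates the
*measured* pRF, not a literal frame-by-frame response model, and only the
measurement reading makes simulated fits, model predictions and model
inversion mutually consistent. The model predicts position only; using
the closed-form product sigma for condition sizes is this package's
convention, chosen so size changes carry the Gaussian-multiplication
structure the feature-AMI analysis expects.

The neural overlap series is normalized to unit peak before amplitude
scaling, so a noise SD of 0.2 x amplitude is genuinely "20% noise".
Observation noise is i.i.d. Gaussian by default with an optional AR(1)
mode. Real BOLD has structured physiological noise, per-voxel HRF
variability and motion artifacts that none of this emulates — passing
recovery tests demonstrates correctness of the estimators under the
model's own assumptions, not robustness to real-scanner nuisance.

Condition-level parameter tables for population analyses can also be
produced directly from the model (`model_condition_table`), bypassing
time-series fitting: positions and sizes as above plus optional Gaussian
parameter noise (0.05 dva emulates the scatter that 20%-noise time-series
fits produce) and a Beta(8, 4) stand-in R^2 weight.

Behavioral simulation: a one-parameter Bayesian adaptive staircase
(posterior over log10 threshold on a 400-point lattice spanning 4 decades,
Weibull likelihood with slope 3.5 and guess rate 0.5, trials placed at the
posterior-mode threshold's 83%-correct intensity) driving a Weibull 2AFC
observer. Asymptotic accuracy converges on the 83% target; a single
500-trial accuracy estimate carries ~1.7 percentage points of binomial
noise. The prior mode defaults to 1.0 in intensity units with a 1
log10-unit SD.

Gaze traces are 2D position plus pupil size with optional fixation noise,
linear drift, flagged blink gaps (overlaps merged with a warning) and
single-sample pupil spikes calibrated to exceed the cleaning stage's
acceleration threshold.

## Preprocessing

BOLD: third-order Savitzky-Golay detrending with a 120 s window (rounded
up to an odd sample count; edge frames via polynomial fits on the
truncated window), then per-run percent signal change. The window removes
cubic-and-slower trends exactly but also takes a small bite out of
genuine pRF signal at the blank-period timescale: on noiseless default
simulations the detrended series correlates ~0.97-0.98 with the
pre-filter signal rather than perfectly — an intrinsic cost of the
detrending choice, shared by simulator and any real data run through it.

Gaze: blink gaps linearly interpolated; pupil high-pass filtered at 10 Hz
(for detection only), samples whose pupil acceleration exceeds 1e5
units/s^2 plus neighbors within 5 s invalidated and interpolated ("1e5
mm/s" is treated as an acceleration threshold as the surrounding text
implies; both the threshold and padding are configurable); per-bar-pass
drift removal by median subtraction. Cleaning is idempotent on clean
traces. The summary statistic rotates gaze into each pass's traversal
frame and pools the along-traversal component per bar position (median
and SD) — the component that matters for pRF estimation.

## Population statistics

Positions are mirrored into the first quadrant with the sign of the
Attend Fixation coordinates (zeros count as +1); other conditions keep
their sign pattern, so cross-meridian shifts survive. Shift vectors run
from Attend Fixation to an attend-bar condition (or their average).

- **Direction decomposition**: per-voxel ratios |d_ecc|/L, |dx|/L, |dy|/L
  (zero-length shifts excluded and counted), r2-weighted means, pairwise
  bootstrap comparisons.
- **Polar-angle slopes**: the folded start angle is binned equal-width in
  three bins ordered from the vertical to the horizontal meridian; the
  contrast (last-minus-first-bin slope of dx) minus (same for dy) is
  bootstrap-tested. For inward radial shifts the dx slope is more
  negative than the dy slope on this axis.
- **Eccentricity/size profiles**: equal-width 4-bin profiles of d_ecc and
  d_sigma over Attend Fixation eccentricity in [0, 3.3] (equal-count
  option available), per-bin 5-MAD outlier rejection, r2-weighted means
  with bootstrap CIs; the d_ecc/d_sigma correlation uses 20 equal-count
  (5-percentile) bins, Pearson r over bin means, Fisher-transformed CI.
- **Feature AMI**: per attend-bar condition, the change vector
  (d_ecc, d_sigma) relative to Attend Fixation, each component divided by
  the across-voxel SD of the corresponding Attend Stimulus - Attend
  Fixation difference. The normalizer is the SD, not the variance, so the
  components stay dimensionless and commensurate; a `norm="variance"`
  flag reproduces the literal variance reading. Feature AMI is the
  difference-over-sum contrast of the two AMI norms; 0/0 voxels are
  flagged undefined and counted.
- **Feature preference**: `(b_color - b_tf) / (|b_color| + |b_tf|)`.

Inference: resampling bootstrap (default 1e5 draws; weights enter the
statistic — the r2-weighted mean by default — not the resampling
probabilities), two-tailed p = twice the smaller tail fraction around the
threshold, floored at 2/n_boot; undefined resamples are redrawn, counted
and capped. Benjamini-Hochberg FDR; unscaled 5-MAD outlier rejection
(zero MAD excludes nothing, with a warning; a scaled option exists);
Rayleigh test with the standard two-term small-sample correction, clipped
to [0, 1] (the expansion degenerates as the resultant length approaches
1 — the Monte-Carlo null is the better reference there); Fisher transform
by atanh.

The bootstrap's two-tailed test is slightly anti-conservative at small
samples (rejection rate ~0.06-0.08 at n <= 100 under a Gaussian null,
within 0.05 +/- 0.02 by n ~ 150), consistent with the known O(1/n) error
of percentile bootstrap tests — one reason across-voxel inference should
use large samples.

## Study conditions used by the validation suite

- pRF recovery: 100 voxels, 20% noise, eccentricities 0.2-3.0 dva, sizes
  0.5 + 0.1 x ecc. Median center error is a few hundredths of a dva, far
  inside the coarse-pixel bound (0.232 dva).
- Gain-field inversion, noise-free: one measured voxel per quadrant bin
  (64 vectors), forward-generated at sigma_fix = 2.0, kernel = 1.0;
  recovery is exact to the 0.02 dva grid step.
- Gain-field inversion under noise: 600 voxels, 20% noise, three fitted
  conditions with the attend-stimulus endpoint averaged over the two
  attend-bar fits, and the objective weighted by each bin's summed R^2.
  Unweighted, sparsely populated edge bins carry the noisiest means and
  drag the argmin along the shallow valley (an errors-in-variables
  attenuation worth +0.1-0.3 dva on AFfix at a few hundred voxels);
  weighting by bin mass removes the bias, and recovery lands within a few
  hundredths of a dva of the generative sizes.
- Shift-direction ordering: 500 voxels, meridian bias kappa = 0.5, sizes
  0.5 + 0.05 x ecc, AFfix 2.2 dva, kernels 0.95/1.05 dva, parameter noise
  0.05 dva — an inward-dominated regime, where radial > horizontal >
  vertical ratios and the slope contrast match the published ordering.
- Eccentricity crossover: sizes 0.7 + 0.05 x ecc with AFfix 2.1 and
  kernel ~1.0. The crossover (parafoveal outward, peripheral inward) is a
  property of particular SD populations — the published data also lack it
  in the earliest areas — and these conditions are a mid-level-area-like
  regime that exhibits it.
- Feature AMI: kernels 0.95 (color) vs 1.05 (TF) — a 0.1 dva precision
  difference — yields a positive population mean feature AMI; equal
  kernels yield a CI covering zero.

## Known limitations

- The gain-field model predicts position only; condition sizes in the
  generator follow a package convention (closed-form product), not a
  model-derived size prediction.
- AFfix and AFstim sizes are weakly identified jointly (shallow diagonal
  objective valley); position-noise at realistic levels moves the argmin
  along the valley even with hundreds of voxels. Conclusions about either
  size alone should respect this.
- Suppressive surrounds (difference-of-Gaussians pRFs or gain fields) and
  nonlinear spatial summation are out of scope.
- The simulator's noise model is unstructured; real-data robustness is
  untested by design.
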