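# Methods

This note records the models, estimators, parameter choices and known
limitations behind `dprtrack`, at the level of detail a user needs to judge
what a passing test suite does and does not demonstrate.

## Motion models and the synthetic generator

Trajectories are simulated in 2D with frame interval `dt`:

* **Brownian** — i.i.d. Gaussian steps, per-axis variance `2 D dt`, so the
  2D MSD grows as `4 D Δt`.
* **Directed** — Brownian steps plus a constant drift `v dt`; MSD
  `4 D Δt + v² Δt²`.
* **Confined** — Brownian steps reflected specularly at a circular corral
  of radius `R` centred on the start point. The generative model of real
  constrained aggregate motion is unknown; specular reflection is the
  standard corral model and produces the expected MSD plateau (the
  stationary law is uniform on the disc, so the mean squared displacement
  between two well-separated times tends to `R²`, and from the central
  start point to `R²/2`).
* **Localization error** — additive i.i.d. Gaussian noise of s.d.
  `sigma_loc` per coordinate on the *observed* positions only; it adds a
  constant `4 sigma_loc²` to the MSD.

Rendering uses a pixel-integrated Gaussian PSF (erf differences over pixel
edges, correct photometry at sub-pixel widths), Poisson noise on signal
plus background, additive Gaussian read noise, and clipping to the camera
bit depth. Organelles in the two-channel simulation are rendered as
PSF-blurred uniform discs. Randomness is driven by one `SeedSequence` per
call, split per particle, so output is bit-reproducible and independent of
particle ordering.

Default acquisition parameters emulate the targeted experiments: 60 frames
at 1 Hz, 0.19 µm pixels, PSF sigma 0.2 µm, 1000 photons/particle over a
50-count background with 2-count read noise (peak SNR ≈ 9). Default
kinetic parameters: Brownian D = 0.05 µm²/s, directed v = 0.3 µm/s with
D = 0.01 µm²/s, confined R = 0.5 µm with D = 0.05 µm²/s, sigma_loc =
20 nm. The two-channel simulation places 30 organelles in a 256-px field
(0.013 objects/µm², inside the detector's stated working regime of
≤ 0.02/µm²) with a colocalized fraction of 0.4 (count = floor(0.4·n) for
determinism); CL objects move at half the NCL speed (D scaled by 1/4,
since Brownian speed scales with √D) and have 1.5× the NCL area (radius
× √1.5). Organelle/aggregate photon budgets (3000/5000) are chosen so the
global-Otsu pathway sees a clearly bimodal histogram, as in well-exposed
stained movies.

What the generator does **not** emulate: photobleaching and blinking, 3D
motion and defocus, motion blur within a frame, EM gain statistics, spatially
varying background, aggregate shape irregularity, and switching between
motion states within one trajectory. Passing tests therefore demonstrate
correctness of the estimators under the stated model, not robustness to
every property of real movies.

## Detection

The DoG response is `G(σ₁) − G(σ₂)` with `σ₁ = d/(2√2)` for nominal blob
diameter `d` (default 0.8 µm) and `σ₂ = 1.6 σ₁` (the standard
approximation to the Laplacian of Gaussian). Candidates are strict local
maxima of the response over the 8-neighbourhood. Quality is the response
divided by the response a noise-free Gaussian spot of width σ₁ and unit
peak amplitude would produce (`σ₁²/2σ₁² − σ₁²/(σ₁²+σ₂²)`), so the quality
unit is "peak counts above background of a matched spot". The default
threshold (30) was calibrated on the synthetic movies at default optics,
where noise maxima score below ~15 and true spots ~100; it is a config
value, since the quality unit of the original acquisition software is not
portable.

Sub-pixel refinement takes the intensity-weighted centroid of the positive
DoG response in a window of radius `max(2, round(σ₁ in px))`. The window is
deliberately matched to the DoG core: with a wide window (e.g., the full
blob diameter) neighbouring spots and background noise pull the centroid,
and the localization RMSE measured on ground truth degrades from ~0.2 px to
~0.44 px at a density of 0.017 particles/µm².

## Linking

Both linking passes solve linear assignment problems on squared distance
with the augmented-cost construction: the cost matrix is bordered with
diagonal "non-link" alternatives costing `r²` (r the relevant radius) and a
transposed slack block, and solved exactly with the Jonker–Volgenant solver
(`scipy.optimize.linear_sum_assignment`); tests verify agreement with
exhaustive enumeration. Pass 1 links consecutive frames (radius 1 µm by
default); pass 2 joins a segment that ends at frame `e` to one that starts
at frame `s` when `1 ≤ s − e − 1 ≤ max_frame_gap` missing frames (default
5) and the bridge is within 1 µm. Splitting and merging are not modelled.
Track duration is `(last − first frame)·dt`, and the motion analysis keeps
tracks with duration strictly greater than 30 s.

## MSD estimation and model fitting

`compute_msd` is the time-averaged overlapping-window estimator: for lag
`n`, the mean of `|r(i+n) − r(i)|²` over every ordered pair of observed
frames separated by `n` (gaps skipped). Lags backed by fewer than 3 pairs
are flagged unreliable.

The diffusive–ballistic fit regresses the MSD on `(Δt, Δt²)` over lags ≤
20 s with weights `n_pairs/Δt²` — the inverse of the leading-order variance
of a time-averaged Brownian MSD point — and clips negative coefficients to
zero, re-solving the reduced model. `D = b₁/4`, `v = √b₂`.

**Directedness test.** Overlapping-window MSD points are strongly
autocorrelated, and a nested-model F-test between the quadratic and
pure-diffusion fits is badly oversized on them (measured size ≈ 0.33 at
nominal α = 0.05 on Brownian tracks; lowering α does not repair it because
the miscalibration is structural). The package therefore tests directedness
on the single-frame step vectors, which are i.i.d. under free diffusion:
Hotelling's T² on the mean step has an exact F(2, n−2) null. Measured size
is 0.045 at α = 0.05 with power ≈ 1.0 at v = 0.3 µm/s, and confined tracks
are never flagged. The curve-only code path (when no trajectory is
available) falls back to the F-test and documents its anticonservatism.
When the directed term is not supported, D is reported from the reduced
pure-diffusion fit; this removes the downward bias that the clipped
quadratic term otherwise induces (median D̂ error −5% instead of −19% at
the default conditions).

The anomalous exponent α is the OLS slope of `log MSD` vs `log Δt` over the
first 25% of lags (≥ 3 points, zero-MSD lags excluded; an all-zero curve is
classified constrained with a warning). Class bins: α < 0.8 constrained,
0.8 ≤ α < 1.5 diffusive, α ≥ 1.5 transported. The anchors (1 for
diffusion, 2 for transport, < 1 for confinement) fix only three points;
0.8/1.5 are the package's boundary choices, recorded in config and report
metadata. At the default conditions they give ≈ 93% three-class accuracy;
most residual error is Brownian tracks whose short-lag slope fluctuates
above 1.5.

## Segmentation and morphometrics

Segmentation is median filter (radius 1 by default) → global Otsu →
8-connected labelling → removal of objects under 4 px (suppresses
single-pixel noise while preserving diffraction-limited puncta).
Circularity is `4πA/P²` clipped at 1. The perimeter `P` is the length of
the marching-squares sub-pixel iso-contour smoothed with a 5-point circular
moving average: the raw contour overestimates smooth boundaries by
stair-stepping, while the common Crofton (4-direction) and Freeman
estimators are biased in opposite directions such that no single one is
accurate for both discs and squares. The smoothed-contour estimator gives
circularity 0.99 for a radius-50 disc, 0.81 for a square (analytic π/4 ≈
0.785), and 0.15 for a thin bar, preserving the disc > square > bar
ordering. Degenerate objects with zero estimated perimeter report
circularity 1 by convention.

Cell masks are inputs (the package does not segment cells); a cell counts
as aggregate-positive when at least one aggregate centroid falls inside its
mask. Mean grey values are arithmetic means over the mask; log10 is applied
only to positive means, with non-positive means flagged as missing rather
than −∞.

## CL/NCL colocalization kinetics

The aggregate channel is binarised by the same median+Otsu pathway; a
channel-1 object is CL when ≥ 30% of its pixels (config:
`overlap_threshold`) fall inside the channel-2 mask, else NCL, and a
continuous membership score (mean min–max-normalized channel-2 intensity in
the object) is reported alongside. The original studies used an
unspecified fuzzy colour classifier on RGB movies; the overlap fraction is
a deterministic, testable surrogate and is recorded as such. If the Otsu
mask of channel 2 covers more than 25% of the field, the channel is treated
as signal-free (Otsu on a unimodal noise histogram splits the background);
this makes the zero-colocalization case behave correctly.

Object tracks carry per-frame centroid, area and label; a track's
population is its majority per-frame label (ties → CL, flagged), matching
the static CL/NCL dichotomy of the experimental analysis. Speed is the
mean frame-to-frame displacement over consecutive present frames divided by
`dt`; displacement is the first-to-last straight-line distance; size is the
mean segmented area. Population comparisons use Welch's t (closed form,
Welch–Satterthwaite df). Kinetic summaries use only tracks spanning at
least half the movie — short fragments carry unstable majority labels and
speed estimates — mirroring the duration filtering of the motion analysis.
Measured size contrasts are compressed relative to the generative truth
because the PSF halo adds a similar area to every object after
thresholding; effect *directions* are recovered reliably.

## Pipeline and determinism

`run_pipeline` chains simulate → detect → link → filter → MSD → classify →
coloc → report from a single `PipelineConfig` whose defaults are the
protocol values (0.8 µm diameter; 1 µm/1 µm/gap 5; 20 s fit range; > 30 s
tracks; 60 frames at 1 Hz; 0.19 µm pixels). All outputs are deterministic
functions of the config (including its seed); the report carries a SHA-256
config hash, the seed and the package version. Problem sizes in the bundled
analyses and checks (ensembles of 200–300 trajectories, movies of 30–60
frames at 128–256 px) are chosen so the full chain, including rendering and
per-frame segmentation, completes in seconds while leaving sampling error
well inside the tested tolerances.

## Known limitations

* Per-trajectory D estimates from 60-frame tracks have ~30–50% relative
  scatter; only ensemble medians are tested to tight tolerances.
* The drift test assumes a constant transport direction within a track;
  curvilinear transport reduces its power.
* Gap closing with a 1 µm radius cannot bridge 3-frame gaps of fast
  diffusers (D ≈ 0.05 µm²/s) for physical reasons — the expected bridge
  length exceeds the radius — so gap-recovery guarantees hold for slow
  particles.
* CL/NCL labelling degrades above ~0.02 objects/µm² because unrelated
  objects overlap the aggregate mask by proximity.
* No 3D, no photophysics, no cell segmentation.
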