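# Methods

This note documents the models behind `sptpalm`, the defaults and why they
were chosen, what the synthetic-data generator does and does not emulate,
and the numerical choices that affect results.

## Apparent diffusion coefficients

For a track with displacements d_1..d_n between consecutive frames
(interval Δt), the apparent diffusion coefficient is

    D* = (1 / 4 n Δt) Σ_j d_j²,

using **all** displacements of the track with a minimum of `min_steps = 4`
(`compute_dstar`). Displacements spanning a linking gap are excluded; if
fewer than `min_steps` remain the track is dropped and counted. D* is
*apparent*: localization error adds σ²/Δt, motion blur multiplies the true
contribution by roughly 2/3 at full-frame exposure, and confinement in the
~0.9-µm-wide cell caps it for fast molecules. Fitted components are
reported on the apparent scale; corrections live in the calibration module.

## Gamma-mixture model

For free 2D diffusion each squared displacement is exponential with mean
4DΔt, so the D* of an n-step track is Gamma(shape n, scale D/n), mean D.
A heterogeneous population with species amplitudes A_k and apparent
coefficients D_k, observed with track-length distribution w_n, has density

    f(x) = Σ_k A_k Σ_n w_n Γ(x; n, D_k/n).

`fit_mixture` maximizes the exact per-track likelihood — each record
contributes Γ(x_i; n_i, D_k/n_i) with its own step count — by EM with
closed-form updates (A_k = mean responsibility; D_k = responsibility- and
step-weighted mean of D*). Step counts are capped at `n_max = 30`, which
limits the number of distinct gamma shapes; under the geometric length
distribution (mean ~10.6 steps) fewer than 3% of tracks hit the cap. The
empirical w_n is kept on the model for density evaluation, band purities,
and the alternative `histogram_lsq` fitting path (least squares on
0.05-µm²/s bins over [0, 3], Nelder–Mead on softmax/log-transformed
parameters). Fixed components (the stepwise protocol below) keep their D
but their amplitude remains free. Step-to-step covariance induced by
shared localization error between consecutive displacements is neglected,
as is standard for this estimator.

Initialization is deterministic and scale-aware: D starts at the 20th /
50th / 90th percentiles of the data (k = 3; analogous quantiles for other
k) with equal amplitudes, so fits are reproducible and invariant to record
order. Convergence: relative log-likelihood change < 1e-8, max 2000
iterations; non-convergence warns and returns the best iterate.

### Model selection and the fixed-component ladder

`select_model` fits k = 1..max_k and ranks by BIC with
p = (k−1) + #free-D parameters. For k = 3 it applies the stepwise
protocol used when a minor fast species rides on two dominant slow ones:
the very-slow D is fixed at the slowest component of the k = 2 fit.
Residual structure is summarized by a Wald–Wolfowitz runs test on the
signs of binned residuals (normal approximation, two-sided); a
well-specified model gives p ≫ 0.05 while an underfit k leaves long
same-sign runs and p ≈ 0.

A property of the exact likelihood worth knowing: on data generated
*exactly* from a three-species gamma mixture with a minor fast component,
the global two-species MLE merges the two slow species and keeps the fast
one (rather than splitting the slow mass), so the ladder's fixed D_vslow
is then the merged value. The ladder is retained because it mirrors the
published protocol for experimental distributions; for parameter-recovery
studies on synthetic data the free three-species fit is the right tool and
is what the headline recovery checks use.

### Bootstrap errors

`bootstrap_amplitudes` resamples whole tracks with replacement (default
100 resamples), refits the same model specification initialized at the
point estimate, and reports per-species SDs of the amplitudes (percentage
points) and of the free D values. Failed resample fits are dropped with a
warning above 5%.

### Band purity

For D* bands defined by thresholds (default 0.31 and 0.7 µm²/s), the
composition of each band is computed from areas under the fitted curves:
P(species k | band) ∝ A_k Σ_n w_n [F_{n,D_k}(hi) − F_{n,D_k}(lo)]. Band
composition depends on the track-length mixture: longer tracks give
sharper gamma shapes and purer bands.

## Synthetic data generator

Molecules are photoactivated sparsely (Poisson per cell per frame,
default 0.03 — about 0.23 simultaneously active per cell), draw a
diffusive state by mixture fraction, an initial position uniform in the
state's zone, and perform 3D Brownian sub-steps inside a reflective
spherocylinder; the camera observes the mean (x, y) of the
`n_substeps = 10` intra-exposure positions (motion blur) plus Gaussian
localization noise (σ = 0.035 µm per axis, typical PAmCherry precision),
and each molecule survives a frame with probability 1 − `bleach_prob`.
Reflections mirror the offending point across the tangent plane at the
nearest surface point, iterated, with a clamp for pathologically long
steps; states never interconvert within a track, matching the
one-mobility-per-track mixture model.

Defaults encode the acquisition this analysis targets: frame interval
10.64 ms with zero dead time (exposure = frame interval), cells 2–3 µm
long with radius 0.45 µm, `bleach_prob = 0.13` so the mean observed track
conditional on the 4-step minimum is ~10.6 steps (~113 ms). Zones:
`nucleoid` is a centered ellipsoid spanning `nucleoid_fraction = 0.8` of
the length at full radius; `nucleoid_periphery` its outer 30% shell;
condensate-like states can add a reflective confinement sphere around the
start position. Rendering integrates a symmetric Gaussian PSF
(σ = 0.13 µm) over 0.1-µm pixels with Poisson noise on signal plus
background.

Two fast paths skip the spatial engine where only D* statistics matter:
`sample_dstar_records` draws per-track D* directly from the gamma sampling
distribution (used for mixture-recovery and bootstrap studies), and
`simulate_confined_dstar` batch-propagates all molecules of one cell
concurrently (used by the calibration).

What the generator does **not** emulate: fluorophore blinking, EM-gain and
readout noise, astigmatic/3D PSFs, state interconversion within tracks,
cell crowding/heterogeneity beyond length variation, and drift. Passing
tests therefore demonstrate correctness of the estimators under the
stated model, not robustness to every artifact of real movies.

## Detection and linking

Detection: difference-of-Gaussians band-pass (σ = 1 and 2 px), local
maxima above `threshold_snr = 8` times the robust noise SD (1.4826·MAD).
Sub-pixel positions from least-squares symmetric 2D Gaussian fits in 7-px
windows; clipped windows are skipped, degenerate or non-converged fits
dropped and counted. Coordinates are micrometers, origin at the field
top-left, pixel centers at (i + 0.5)·pixel; frames 0-based.

Linking: frame-to-frame greedy ascending-distance matching with
`max_disp_um = 0.8` (captures D up to ~5 µm²/s at 10.64 ms with <1%
missed steps) and `max_gap = 0`; distance ties break on the lower
candidate index, and a canonical within-frame sort makes the result
invariant to input row order. At sparse PALM densities greedy matching
agrees with globally optimal assignment; residual errors at the default
density are dominated by genuinely ambiguous events (two co-active
molecules in one cell, or a fresh activation right after a bleach), which
no distance-based assignment can resolve — per-link accuracy is ~99% and
the per-track majority state label remains recoverable for >99% of
tracks. Tracks are assigned to the cell containing the plurality of their
localizations (boundary points count as inside; overlapping outlines
resolve to the nearest cell center with a warning); tracks mostly outside
all cells are discarded and counted.

## Cell coordinates and heatmaps

The principal axis of each outline polygon comes from its area second
moments (shoelace decomposition). A localization maps to l ∈ [0, 1]
(projection onto the axis scaled by cell length) and r ∈ [−1, 1]
(perpendicular offset over the local half-chord of the outline).
Localizations outside the outline are clipped into range and counted.
Band membership is decided by the track's single D*; all its
localizations accumulate in that band's 50×20 (l, r) histogram over cells
filtered to the 2–3 µm length class (the ~2-nucleoid size range; other
ranges are a parameter). Because pole ordering of an outline is
arbitrary, maps are mirror-symmetrized in l (and r) by default; maps are
density-normalized to unit sum. Accumulation is per localization rather
than per track, weighting longer tracks more; this matches mapping every
location of the selected tracks.

## Calibration of D* to accurate D

`build_calibration` simulates tracks at each of 20 log-spaced true D
values in [0.05, 20] µm²/s (5,000 tracks per point, split over 4 seeds
for a Monte-Carlo SE) in a stated geometry/acquisition — default a
2.5 × 0.9 µm spherocylinder, 10.64-ms frames, 35-nm noise, 10-substep
blur — and records the single-species MLE of the apparent coefficient
(the step-weighted mean of D*). The map is strictly increasing; if
Monte-Carlo noise breaks monotonicity it is isotonically smoothed with a
warning. `invert_calibration` applies monotone (PCHIP) interpolation of
the inverse and refuses to extrapolate; the table SE propagates through
the local slope. Verified limits: identity when unconfined/noise-free/
blur-free; + σ²/Δt offset with noise only; and ~(2/3)·D + σ²/Δt for
full-frame blur unconfined (measured 2.454 vs 2.448 µm²/s at D = 3.5).
The inverse mapping of a given observed D* is strongly
geometry-sensitive: at D* = 1.4 µm²/s the default parameters give
D_acc ≈ 2.6 µm²/s, while, e.g., a 15.44-ms frame interval with a 0.40-µm
radius gives ≈ 3.3 µm²/s. Conversions are only comparable between
datasets if the calibration used the dataset's own geometry and timing.

## Binding-time fraction

`fns_estimate` implements the time-average model
D_intact = (1 − f_ns)·D_free: a protein spending a fraction f_ns of its
time bound to the effectively immobile chromosome shows proportionally
reduced long-time mobility, so f_ns = 1 − D_intact/D_free. It is
scale-invariant and refuses D_intact > D_free. Reported "~" fractions
round to the nearest ten percent (`round_to_nearest_ten_percent`); raw
values are always returned.

## Pipeline, determinism, and problem sizes

All randomness in a pipeline run flows from the single configuration
seed; configurations reject unknown keys; every artifact is hashed into a
provenance manifest, and CSV floats are written with 6 significant digits
so reruns are byte-identical. The test suite and the acceptance script
use the production scale for the headline statistics (75,264 tracks, 100
bootstrap resamples) and smaller sizes (2–20 k tracks, 5–15 cells,
≤3,000 frames) where a property is scale-free; each test states its size.

## Known limitations

- The likelihood ignores localization-error-induced correlation between
  consecutive displacements; at σ²/Δt ≈ 0.115 µm²/s this slightly blurs
  components below ~0.15 µm²/s.
- Gamma shapes assume free diffusion within a track; for strongly
  confined or blurred tracks the shape is only approximate, which is
  precisely why fitted D values are apparent and the calibration module
  exists.
- Greedy linking has no appearance/disappearance cost model; at densities
  well above ~0.3 active molecules per cell it will chain distinct
  molecules.
- The k = 2 → k = 3 fixed ladder inherits whatever the two-species MLE
  converges to; see the model-selection section.
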