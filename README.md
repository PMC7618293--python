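# sptpalm

Single-particle tracking PALM analysis for rod-shaped bacteria: simulate
multi-state diffusion in spherocylindrical cells, localize and link
single molecules into tracks, fit the distribution of apparent diffusion
coefficients as a gamma mixture with bootstrap errors, map mobility bands
onto normalized cell coordinates, and convert apparent to accurate
diffusion coefficients by simulation-based calibration.

## Who this is for

Tracking-PALM experiments on bacterial proteins (polymerase-associated
factors, ribosomal subunits, DNA-binding proteins…) produce tens of
thousands of short trajectories per condition. The standard analysis
summarizes each track by an apparent diffusion coefficient

    D* = (1 / 4 n Δt) Σ_j d_j²,

where d_1..d_n are the frame-to-frame displacements, and decomposes the
population by exploiting the sampling distribution of D*: for free 2D
diffusion, the D* of an n-step track is Gamma(shape n, scale D/n). A
mixture of K diffusive species observed with track-length distribution
w_n therefore has density

    f(x) = Σ_k A_k Σ_n w_n Γ(x; n, D_k / n),

and the amplitudes A_k are the population fractions (e.g. a very-slow
chromosome-associated species, a slow large-complex-bound species, and a
fast freely diffusing species). `sptpalm` implements this model end to
end — per-track exact-likelihood EM fitting with optional fixed
components, BIC + residual-runs-test model selection, track-level
bootstrap, D*-threshold band purities and spatial heatmaps — plus a
ground-truthed simulator of the whole measurement (reflective Brownian
motion in a spherocylinder, motion blur, localization noise, geometric
photobleaching) that doubles as the engine for calibrating apparent
against accurate diffusion coefficients.

## Worked example

`examples/fit_mobility_mixture.py` draws 75,264 synthetic tracks from a
three-species truth (41% / 47% / 12% at D* = 0.15 / 0.33 / 0.99 µm²/s),
selects the model order, refits, and bootstraps:

```
$ python examples/fit_mobility_mixture.py
75264 tracks, mean steps 10.5

model selection (BIC, lower is better; runs-test p on residuals):
  k=3: BIC=   -27968.9  runs_p=0.821
  k=2: BIC=   -13118.2  runs_p=0.000
  k=1: BIC=   169734.2  runs_p=0.000

three-species fit (amplitude +/- bootstrap SD, apparent D):
  very_slow:  41.2 +/- 0.27 %   D* = 0.150 um^2/s
       slow:  46.8 +/- 0.27 %   D* = 0.330 um^2/s
       fast:  12.0 +/- 0.14 %   D* = 0.986 um^2/s

band composition at thresholds 0.31 / 0.7 um^2/s
(how cleanly each mobility band isolates one species):
  [0, 0.31): 62.9% of tracks, dominant very_slow (65%)
  [0.31, 0.7): 27.1% of tracks, dominant slow (90%)
  [0.7, inf): 10.0% of tracks, dominant fast (96%)
```

Reading the output: BIC and the residual runs test agree that one or two
species underfit the distribution (structured residuals, p ≈ 0) while
three species leave random residuals; the fit recovers the generating
amplitudes to a fraction of a percentage point with bootstrap SDs well
under one point at this track count; and thresholding D* at 0.31 and
0.7 µm²/s yields bands dominated by one species each — the justification
for interpreting band-wise spatial maps as maps of individual species.

The other examples are one capability each:

- `examples/simulate_localize_track.py` — render a movie, detect + fit
  spots, link tracks, verify against ground truth.
- `examples/spatial_heatmaps.py` — nucleoid-zone vs whole-cell states and
  their band heatmaps in normalized cell coordinates.
- `examples/calibrate_diffusion.py` — the D* ↔ accurate-D calibration
  table and the non-specific DNA-binding time fraction
  f_ns = 1 − D_intact/D_free.
- `examples/run_full_pipeline.py` — the config-driven pipeline with its
  provenance manifest.

A thin CLI wraps the same functions
(`sptpalm run|simulate|localize|link|fit|heatmap|calibrate|dacc|fns|compare|validate`).

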