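# Methods

This note documents the models, numerical choices and known limitations of
`brixmap` — what each stage computes, why the defaults are what they are,
and what the synthetic-data tests do and do not demonstrate about real
hyperspectral data.

## The synthetic forward model

Real data for this workflow are reflectance spectra of punched markers on
produce slices paired with refractometer SSC readings. The generator
emulates that system as:

```
r(λ) = [ b(λ) − Σₖ dₖ(SSC) · exp(−(λ−cₖ)²/2wₖ²) ] · (1+m) + a + ε(λ)
```

* **Baseline** `b(λ)`: quadratic in normalized wavelength,
  coefficients (0.30, 0.45, −0.15) — a smooth convex curve rising from
  ~0.30 at 400 nm into the NIR, the qualitative shape of pale root tissue.
* **Absorption dips** at cₖ = 425, 650, 770, 980 nm (carotenoid,
  chlorophyll, and the O–H third/second water overtones), Gaussian widths
  18/22/28/35 nm, baseline depths 0.12/0.05/0.05/0.08 reflectance units.
* **SSC coupling**: dₖ(SSC) = dₖ⁰ + κₖ·(SSC − mean). Only the water
  overtones respond, κ = (0, 0, 0.010, 0.020) per °Brix. The magnitudes
  were set so that a band-limited calibration on these spectra reaches the
  predictive quality typical of real Vis-NIR SSC work (prediction R²
  around 0.85–0.95 with ~20 selected bands); with weaker coupling the
  per-band signal-to-noise ratio falls below what real fruit/root spectra
  exhibit, with stronger coupling the problem becomes trivially easy.
* **SSC draws**: Normal(11.8, 0.78²) °Brix by default (the calibration-set
  statistics of a yellow-flesh cultivar), redrawn when ≤ 0.
* **Scatter**: per-sample multiplicative gain (SD 0.05) and additive offset
  (SD 0.02) — exactly the effects SNV/MSC are designed to remove, so
  pretreatment efficacy is testable.
* **Noise**: i.i.d. Gaussian per band, SD 0.005 reflectance units.
* **Outliers**: reference-value contamination (+5·SD by default, spectra
  untouched), because a residual-based screen attributes abnormality to the
  y–spectrum mismatch. A spectral-contamination mode can be emulated by
  editing spectra directly; it is not the default.

Randomness is consumed from one seeded generator in a fixed order (SSC,
multiplicative scatter, additive scatter, band noise, outlier choice), so
a seed pins the dataset bit-for-bit.

What the generator does **not** emulate: within-slice spatial SSC gradients
(discs are independent draws), wavelength-dependent noise, detector
saturation/speculars, cultivar-specific pigment chemistry beyond dip
placement, or instrument drift. Passing tests therefore demonstrate
algorithmic correctness and statistical behavior under a plausible
scatter+noise model — not instrument-level robustness.

## Reflectance calibration and ROI extraction

`R = (R₀ − R_D)/(R_W − R_D)` element-wise; frames may be per-pixel images
or per-band vectors (broadcast explicitly). Calibration refuses cubes
already in reflectance units rather than silently re-normalizing. Values
outside [0, 1.5] are retained and logged, never clipped — specular pixels
exist, and silent clipping would bias pixel-wise prediction; the mapping
stage can mask them instead. A pixel belongs to a circular ROI when its
center lies within the radius (Euclidean, 0-based, boundary inclusive);
a 15 mm punch has no canonical pixel-scale definition, so this is the
package's convention. ROI means include all pixels (extremes logged).

## Pretreatments

All six transforms are row-separable and band-count preserving (mirror
padding for the windowed ones), so a fitted transformer replays on single
pixels. Defaults where the literature is silent: de-trending polynomial
order 2; baseline correction subtracts the row minimum (linear-endpoint
mode available); MA/SG window 9, SG order 2, derivative 0. Only MSC is
stateful — it stores the calibration-mean reference and always reuses it at
prediction time (transform refuses to run unfitted). SNV uses the n−1 SD
and raises on constant rows; MSC raises when a regression slope magnitude
falls below 10⁻¹².

## MCPLS outlier screening

Each of `n_iter` iterations draws a uniform random `cal_frac` split, fits a
rank-`n_components` PLS on the calibration part and records absolute
residuals |ŷ−y| for the prediction part. MPRE/STDPRE are each sample's
residual mean and SD (n−1). Defaults: 500 iterations (screening-grade;
the full published protocol of 5000 is available via the presets),
cal_frac 0.75, 10 components — near the ranks that full-spectrum PLSR
models select on such data while staying well conditioned on subsampled
calibration sets. Flagging is joint: MPRE **and** STDPRE must exceed their
cuts. Cuts are manual-first (set from an inspected scatter plot, as
practitioners do); `auto_threshold` provides mean + k·SD (k = 3) as a
scripted default. Note a pure reference shift elevates MPRE strongly but
STDPRE only mildly, so the automatic joint rule is conservative for that
contamination type — the recovery guarantee the tests assert is on the
MPRE ranking, and the presets carry explicit cuts.

## SPXY partitioning

Joint distance `d = d_x/max d_x + d_y/max d_y` (Euclidean on spectra,
absolute difference on SSC), Kennard–Stone selection: seed with the
max-distance pair, then repeatedly add the sample whose minimum distance to
the chosen set is maximal. Ties break toward the lowest index — fully
deterministic. r:1 sizing keeps `n − ⌊n/(r+1)⌋` for calibration
(410 → 308+102, 412 → 309+103). Distances are computed on whatever
representation the caller passes; the pipeline partitions raw spectra
before pretreatment (the published order of operations is ambiguous here —
this is the package's choice, configurable by pretreating first).

## Wavelength selection

**SPA.** For every start band and every chain length m ∈ [m_min, m_max]
(defaults 2–25), columns are iteratively deflated by their projection on
the last selected column and the maximal-residual-norm column is appended;
each candidate chain is scored by 10-fold MLR RMSECV with deterministic
contiguous folds, and the global minimizer wins. All bands serve as starts
by default; `max_starts` caps them by |correlation with y| for speed.
Degenerate (zero-norm) starts are skipped with a log entry.

**CARS.** N = 50 Monte Carlo runs by default, each fitting a PLS model on
an 80 % sample subset restricted to the currently retained bands. The
retained count follows the exponentially decreasing function with closed
form r_i = a·e^(−k·i), a = (p/2)^{1/(N−1)}, k = ln(p/2)/(N−1), giving
r₁ = 1 and r_N = 2/p exactly. Which bands fill that count is competitive:
the maximum-|coefficient| band is always kept (the enforced part of the
reduction) and the remainder is drawn by Efraimidis–Spirakis weighted
reservoir sampling **without replacement** with probability ∝ |coefficient|
(zero coefficients floored at 10⁻¹²). Each run's subset is scored by
10-fold PLS RMSECV on the full calibration set with the component count
capped at min(10, subset size) — a fixed cap rather than per-run inner CV,
which changes nothing about which subsets win on data of this kind and
keeps 100-seed experiments cheap. If the retained count would fall below 2
the run stops early with a warning and returns the best subset so far.

Neither method's published description fixes N, the subsampling ratio, PLS
ranks or the SPA start policy, so exact published wavelength lists are not
recoverable even in principle; the tests instead assert oracle equivalence
(SPA against an exhaustive projection oracle) and statistical behavior
(informative-band recovery, superiority over size-matched random subsets).

## Regression and metrics

PLSR wraps a NIPALS decomposition (mean-centered, unscaled) and exposes the
equivalent explicit linear form; at full rank it reproduces OLS to 10⁻⁶.
Rank selection is by 10-fold RMSECV. SVR standardizes inputs per band
(fitted on calibration) so the RBF width γ is comparable across bands;
the default grid is C ∈ {1,10,100,1000}, ε ∈ {0.01,0.1,0.5}, γ ∈ 20
log-spaced values in [10⁻³, 1], traversed row-major with first-minimizer
tie-breaking. MLR is OLS with intercept, t-test p-values, and optional
backward elimination of the worst coefficient with p > α (default 0.05).

Metric conventions (the ones under which published SD/RMSE/RPD triples are
mutually consistent): R² = 1 − SSE/SST about the evaluated set's own mean;
RPD = SD(that set's reference y)/RMSE with the n−1 divisor. Perfect
predictions report RPD as +inf with a warning. Report rounding: 4 decimals
for R²/RMSE, 2 for RPD.

## Mapping

Pixel-wise prediction applies the fitted bundle (pretreatment → band subset
→ model) to every masked pixel; unmasked pixels carry NaN and are never
pretreated (SNV/MSC are undefined on near-constant background spectra).
For linear bundles, predicting a uniform ROI's mean spectrum equals the
mean of its pixel predictions exactly; for SVR the difference is bounded by
the kernel's curvature and checked empirically on the generator. The
render range defaults to the 2nd–98th percentile of masked predictions
(robust to speculars), per cube; out-of-range values are clipped for
display only. Rendering is a pure view — stored values are never modified.

## Problem sizes in the test and acceptance runs

The statistical checks use the generator's study conditions at sizes that
keep the full suite fast while leaving comfortable statistical margin:
MCPLS recovery at n = 408 (400 clean + 8 contaminated), 500 splits,
20 seeds; CARS selection frequency at 40 × 50 over 100 seeds; the
end-to-end pipeline at n = 400 with a 3:1 SPXY split. These are the
package's chosen experiment sizes; all scale linearly if enlarged.

## Known limitations

* The ENVI reader/writer covers the fields this workflow needs (samples,
  lines, bands, interleave, data type, byte order, wavelength) — not map
  info, bad-band lists or vendor extensions.
* No leverage/Hotelling-T² spectral-space outlier diagnostics; MCPLS only.
* No UVE/GA/iPLS selectors; no OSC/EMSC pretreatments; no derivative
  spectra beyond SG's derivative option.
* SPXY assumes meaningful Euclidean distances on the chosen representation;
  heavily scattered spectra should be pretreated first if scatter dominates
  the spectral distance.
* The joint MPRE/STDPRE auto-threshold is conservative for pure
  reference-value contamination (see above); inspect the scatter plot.
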