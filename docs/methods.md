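# Methods

## Dispersion model and conventions

The package models complex relative permittivity with the multi-pole Debye
dispersion plus a static ionic conduction term (engineering e^{+jωt}
convention, so passive materials have Im ε̂ ≤ 0):

    ε̂(ω) = ε∞ + Σₚ Δεₚ / (1 + jωτₚ) + σₛ / (jωε₀).

Canonical storage is the real pair (εr, σ) — what a coaxial-probe
measurement suite reports and what tables in the field print — with the
complex form available as a view (`to_complex` / `from_complex`). The
conductivity returned by `evaluate_model` is the **total effective
conductivity**: the static term σₛ plus the dipolar-loss contribution
ε₀·Δεₚ·ω²τₚ/(1+(ωτₚ)²) per pole. The Cole–Cole pole (jωτ)^{1−α} is
implemented with its exact real/imaginary split; α = 0 reduces identically
to the Debye pole, and the Debye path uses the specialized closed form so the
two routes are independent checks of each other.

Pole ordering carries no physical meaning; the canonical order is τ strictly
descending (slowest relaxation first), which fixes the label symmetry.

## Frequency grids and single-frequency extraction

Instrument sweeps are 101 points uniform in log₁₀(f) with endpoints exact:
200 MHz–20 GHz (VNA1) and 200 MHz–8.5 GHz (VNA2). Because an open-ended
coaxial probe is only trusted from 500 MHz upward, grids are filtered at
≥ 500 MHz, leaving 81 points for VNA1 and 76 for VNA2. (Reports of this
instrument configuration sometimes quote 77 points for the shorter sweep;
the uniform-log construction used here yields 76, and the computed count is
what the package reports.)

Single-frequency values (e.g. the 2.4 GHz tables) are extracted by linear
interpolation in log₁₀(f) applied to εr and σ independently — the natural
interpolant on log-spaced grids, since 2.4 GHz need not be a grid point. On
dense model-generated grids the interpolation error is < 0.2% for
tissue-scale parameters, well inside measurement variability.

## Fit objective, multistart and determinism

"Least squares" underdetermines the fit; the package's concrete choices:

* **Objective**: joint relative residuals, Σ_f [((εr^mod−εr^meas)/εr^meas)² +
  ((σ^mod−σ^meas)/σ^meas)²], equal weights. Relative residuals put the O(50)
  permittivity and O(1) conductivity on one scale and weight a log-spaced
  sweep evenly.
* **Transformed space**: log₁₀τₚ and log₁₀(Δεₚ + 10⁻¹²) (the floor keeps
  Δε = 0 representable), linear ε∞ and σₛ; bounds ε∞ ∈ [1, 30],
  Δε ∈ [0, 10⁶], τ ∈ [10⁻¹³, 10⁻⁶] s, σₛ ∈ [0, 10] S/m. A
  bound-constrained trust-region reflective solver with an analytic Jacobian
  does the local minimization (ftol = xtol = 10⁻¹⁰).
* **Multistart**: the objective is multimodal in τ, so 32 seeded starts are
  drawn as a prefix-stable stream (enlarging `n_starts` can only improve the
  best objective). τ starts are log-spaced across the band's period range
  [1/(2πf_max), 1/(2πf_min)] and jittered by up to ±1 decade — deliberately
  generous because the slowest fitted pole of broadband tissue spectra
  (τ₁ ≈ 1–5 ns) lies above the visible period range, where only its
  high-frequency tail constrains the product Δε₁τ₁; the optimizer migrates τ
  beyond the start range when the data ask for it. Δε starts scatter around
  the observed permittivity span; ε∞ and σₛ start below the band-edge
  values. Best objective wins; ties go to the lowest start index.
* **Determinism**: a fixed (spectrum, config) pair, including the seed,
  yields a bit-identical result.

Individual pole parameters of a 3-pole fit need not be identifiable (two
poles can trade off, and the slow pole is tail-constrained); the reproducible
object is the fitted *spectrum*, and recovery tests assert on it, not on raw
parameters. Fitting is intended for per-(heart, part) **mean** spectra;
fitting individual repeats works but is not the default workflow.

## Error statistics

Both the fit error and the probe-validation error are the mean absolute
percentage difference across all frequency points, computed separately for
εr and σ. The denominator is always the designated *reference*: the measured
mean spectrum for fit errors (the model is judged against the data), the
reference-liquid model for validation errors (the probe is judged against
the literature model). Errors are aggregated across fits/validations as
arithmetic mean and maximum. Absolute values are used throughout; signed
averaging is never reported.

## Campaign design and statistics

The default plan is 4 hearts × 17 locations × 15 repeats = 1020 records.
The location catalogue fixes endocardium at 4 sites (LV, RV, LA, RA
interiors), myocardium at 1 (septum) and great vessels at 4 (aorta,
pulmonary artery, pulmonary vein, vena cava); the remaining 8 sites are
assigned 6 to the epicardium and one each to the appendage interior/exterior
surfaces. That split of the remaining sites is a package choice — study
descriptions fix only the first three groups — and the catalogue is
user-overridable; totals and the fixed groups hold regardless. Hearts A1/A3
are assigned to VNA1 and A2/A4 to VNA2. Reported SDs use the sample (n−1)
denominator.

The ANOVA battery is classical one-way ANOVA (F = MS_between/MS_within,
p from the F survival function; the computation is delegated to
`scipy.stats.f_oneway` and cross-checked in the tests against longhand sums
of squares). Two factorizations are exposed because "compare the mean values
for each heart sample" is ambiguous: the default compares **tissue parts
within each heart** (2 quantities × 4 hearts = 8 tests), where part means
differ by up to ~26% and rejection at p < 0.001 is robust; the alternative
compares hearts within each part, which for parts whose per-heart means
differ by only ~2% (the great vessels' conductivity) is *not* reliably
significant under realistic within-part variability — an informative
negative, not a defect.

The drift diagnostic is an OLS regression (slope per minute, Pearson r) of
2.4 GHz permittivity on time from excision, per heart; it should be run
within a tissue part (or on location-mean-corrected values) since part
baselines differ by several permittivity units.

## Synthetic campaign generator

The generator is the package's study-condition model, not a tuning knob:

* Ground truth: the 24 packaged three-pole Debye models (one per heart ×
  part), evaluated on the heart's instrument grid.
* Location variability: one lognormal multiplier per (heart, location) with
  unit mean and CV 0.05 applied to all Δεₚ and one to σₛ. Relaxation times
  are not perturbed — they are treated as tissue-type properties, which also
  keeps poles identifiable in recovery tests.
* Repeat noise: i.i.d. multiplicative Gaussian per frequency point on both
  quantities, CV 0.03. Together with the location CV this puts 2.4 GHz
  group SDs at roughly 1–3 permittivity units and 0.03–0.1 S/m — the order
  of magnitude repeated probe campaigns on excised tissue report (published
  group SDs span ~1–9 units and 0.04–0.35 S/m; the generator sits at the
  well-behaved end because it omits the occasional probe-contact outlier).
* Drift: off by default (measured campaigns of this design report no trend);
  a relative per-minute drift can be injected to exercise the diagnostic.
* Times: each heart's 255 measurements are spread evenly over a 240–510 min
  post-excision window, location by location. Temperatures are Gaussian,
  23.5 ± 0.9 °C. σ is clamped at 0 after noise.
* One integer seed drives everything; a fixed seed reproduces the campaign
  bit for bit.

What passing synthetic tests does **not** show: the generator has no probe
model (no contact-pressure or thin-fat-layer artifacts), no temperature
dependence, no instrument-specific frequency response, and Gaussian noise
with no outliers; real-data performance can differ accordingly.

## Numerical choices and degenerate inputs

* Grid invariants are strict (positive, strictly increasing); spectra reject
  negative conductivity but only *warn* for εr < 1, because noisy physical
  measurements may dip below the physical bound.
* Percentage differences require an identical grid and a nowhere-zero
  reference; violations raise alignment/zero-division errors rather than
  returning NaN.
* Sample SDs of constant data are forced to exactly 0 (no floating-point
  dust), so noiseless-limit identities hold exactly.
* ANOVA with zero pooled within-group variance, and drift regression with
  constant timestamps, raise degenerate-input errors.
* Spectrum CSVs round-trip losslessly (17 significant digits on write,
  round-trip float parsing on read); out-of-order rows are sorted with a
  warning, duplicates and non-numeric cells are parse errors naming the row.

## Problem sizes

The shipped tests fit all 24 parameter sets noiselessly and under 0.5% noise
(32 starts each), simulate full 1020-record campaigns (20 seeds for the SD
calibration check, one for the ANOVA battery), and run 99-validation and
100-seed Monte-Carlo bands; the whole suite completes in about a minute on a
single CPU.

## Known limitations

* No S11-to-permittivity inversion or probe admittance model: the pipeline
  starts from converted (εr, σ) spectra.
* No Cole–Cole *fitting* (forward evaluation and reference use only) and no
  parameter covariance/uncertainty on fits.
* No temperature correction; temperature is carried as metadata only.
* No baked-in literature saline model: validation references are pluggable,
  and the packaged example reference is synthetic and labelled as such.
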