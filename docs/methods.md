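# Methods

This note documents the models, conventions and design choices behind
`ctlensdose`, and what the synthetic-data tests do and do not demonstrate.

## The measurement problem

Medical staff who stay in the CT room to assist a patient during a
diagnostic scan (ventilating with a bag-valve-mask, holding the head,
observing) receive scattered radiation to the eye lens. Since the annual
equivalent-dose limit for the lens was lowered to 20 mSv (averaged over 5
years, no single year above 50 mSv), per-procedure monitoring matters.
The campaign this package models measures air kerma with six
radio-photoluminescent glass dosimeters per procedure — an L-shaped
vertical/horizontal pair behind each lens of the safety glasses plus one
dosimeter per side outside — and converts to the operational quantity
Hp(3) with a single beam-mean conversion coefficient K.

## Beam quality and the conversion coefficient

1. **Spectrum.** A semi-empirical tungsten-anode model: Kramers-type
   continuum N(E) ∝ (E₀ − E)/E on a 0.5 keV grid from 10 keV, hardened by
   an effective tungsten self-filtration path (5 µm at the 7° reference
   anode angle, scaling as 1/sin θ), with the four W K lines
   (Kα₁ 59.32, Kα₂ 57.98, Kβ₁ 67.24, Kβ₂ 69.07 keV) added above the
   69.525 keV K-edge. The 0.5 keV bin width changes the derived effective
   energy by <0.1 keV relative to finer grids. Fluence units are relative
   throughout; every downstream quantity is a ratio.
2. **Filtration.** Beer–Lambert per bin with log-log–interpolated mass
   attenuation coefficients (standard Hubbell–Seltzer-type compilations for
   Al and air, bundled as CSV). Log-log interpolation is exact for
   power-law segments; queries at tabulated nodes return node values
   bit-exactly.
3. **HVL and effective energy.** The Al half-value layer solves
   kerma(t)/kerma(0) = ½ by Brent bisection (tolerance 1e-5 mm), with air
   kerma as Σ fluence·E·(μ_en/ρ)_air. The effective energy inverts
   HVL = ln2/μ_Al(E) on the monotone 30–150 keV branch (tolerance
   1e-4 keV). Round trips are exact to 0.01 keV.
4. **Calibration.** Scanners do not publish total filtration, so the added
   Al-equivalent filtration per (scanner, FOV) is calibrated such that the
   120 kVp model reproduces the four measured effective energies
   (55.74, 57.97, 54.87, 57.30 keV); shipped values are 11.7–15.2 mm Al,
   plausible for a CT flat filter plus bowtie center. These are
   calibration constants, not measurements.
5. **Summary convention.** The four per-FOV effective energies summarise
   to 56.47 ± 1.23 keV only under the population-SD convention (divisor
   n); the sample SD would print 1.42. This module therefore uses divisor
   n for this one summary; everywhere else the package uses sample SD.
6. **K.** Hp(3)/Ka for photons at 0° on a cylinder head phantom,
   interpolated linearly at the mean effective energy. The bundled table
   is a synthetic reconstruction of a Behrens-type cylinder tabulation
   (no machine-readable original ships with the package); it is smooth,
   peaked near 50 keV, and anchored so K(56.47 keV) = 1.650 Sv/Gy. K is
   applied identically to inside and outside readings; the Sn-filter
   energy compensation of the dosimeter is taken as folded into the
   reported kerma.

## Aggregation conventions

Per procedure: inside dose = max over sides of (max of vertical/horizontal)
× K; outside dose = max over sides × K. The max (not mean) over
orientations follows from the observed V/H ratio being ≈1 (directional
dependence negligible), making the higher reading the conservative and
simplest choice. The result is invariant to reading order, monotone in
every reading, and scale-equivariant.

## Efficiency estimators and compliance

* **Safety glasses:** median over procedures of the per-procedure
  outside/inside ratio R, reported as reduction (R−1)/R × 100.
* **Extension tube:** restricted to assisted ventilation; per-procedure
  Hp(3) is normalized by DLP (reported ×10⁻⁴ mSv·mGy⁻¹·cm⁻¹) to remove
  scan-length variation, and stratum medians (with/without tube) give
  {1 − with/without} × 100 per placement.
* **Curtain:** from paired phantom means (n = 5 each), same pair formula.
* **Combination:** independent multiplicative transmissions,
  {1 − Π(1 − rᵢ)} × 100 — e.g. 0.31 and 0.51 combine to 66%, adding 0.61
  gives 87%.
* **Compliance:** floor(annual limit / median dose per procedure), with
  the 20 mSv annual limit as default.

Percent rates are rounded half-up to integers (matching every printed
rate); raw fractions are carried alongside so chained calculations never
compound rounding. Zero denominators (inside dose, DLP) are excluded with
a logged warning and a reported exclusion count rather than propagated.

Quantiles use linear interpolation between order statistics (type 7);
95% CIs use Student's t. The underlying campaign never states its
quantile rule, so this is a documented package choice.

## Nonparametric tests

Kruskal–Wallis with mid-ranks and the tie correction
1 − Σ(t³−t)/(N³−N), p from χ²(k−1); Dunn's post hoc z on mean ranks with
the tie-corrected variance and Bonferroni over all k(k−1)/2 pairs
(two-sided). All-tied data gives H = 0, p = 1 rather than an error. The
implementation is verified against an independent one (scipy) to 1e-9 and
calibrated under the null (type-I error within [0.035, 0.065] at α = 0.05).

## Synthetic cohorts

The generator emulates the stratified structure of a 91-procedure
campaign: practice mix 65/12/14 (ventilation/head-holding/observation),
ventilation performed by intensive-care physicians near the gantry
(areas I–II), observation mostly distant (area III). Doses and DLP are
lognormal; defaults are the observed medians (outside Hp(3): 0.51, 0.36,
0.19 mSv; ventilation DLP 1,561 mGy·cm) with geometric SDs (1.7–1.9)
chosen so cohort ranges at n≈65–91 bracket the observed ranges. DLP
medians for head-holding/observation (360, 863 mGy·cm) are pragmatic
placeholders; no per-practice DLP distributions are published.

Design choices that matter:

* **Dose–DLP coupling.** True dose scales with DLP (unit elasticity) with
  residual lognormal noise sized so the total dose GSD matches the
  configured value. Staff scatter dose physically tracks the photon
  output DLP measures — this is why DLP normalization is meaningful at
  all — and it is also what makes the extension-tube estimator
  recoverable at the stated tolerance from a small no-tube stratum.
* **With-tube baseline.** Configured ventilation medians describe the
  predominant with-tube condition (tube-use probability 62/65); the
  no-tube minority is divided by the tube transmission (0.69), so the
  observed median and the recovered 31% reduction hold simultaneously.
* **Centered pair noise.** Side and orientation noise (GSD 1.15) is
  centered so the *maximum* of each pair has median 1, because the
  configured medians and the glasses transmission (0.49) describe the
  aggregated (pair-max) quantities the campaign reports. Without this the
  max-aggregation would inflate every aggregated median by ≈8%.
* **Seeding.** One root seed spawns independent substreams (assignment,
  DLP, dose residual, tube use, reading noise, CT settings), so adding a
  stream never perturbs earlier draws; cohorts are bit-reproducible per
  seed.

What passing the recovery tests shows: the estimators undo the generative
conventions (aggregation, normalization, stratification) and recover the
latent transmissions 0.49/0.69/0.39 as 51/31/61% within ±4 points
(seed-averaged, n = 500). What it does not show: the generator has no
scatter-field physics, no posture/geometry variation, no correlation
between CTDIvol and tube current beyond the practice stratum, and no
dosimeter energy-response error; real-data efficiencies carry
uncertainties (glasses backscatter, posture) the model does not emulate.

## Problem sizes in tests

Convergence checks use one n = 5,000 cohort; recovery suites use 20
cohorts of n = 500; the null calibration uses 2,000 replicates of 3×30
values. These sizes put Monte-Carlo error well inside the asserted bands
while keeping the whole suite in a few seconds.

## Known limitations

* The per-FOV effective energies are calibration anchors, not
  recomputable from measured HVLs (which were never published); the
  spectrum model's constants (self-filtration path, K-line budget) are
  plausible but only the calibrated endpoint is validated.
* The Hp(3)/Ka table is a reconstruction; values away from the 50–60 keV
  anchor region are smooth interpolations of the published curve shape,
  adequate for diagnostic CT beams but not for low-energy or high-energy
  work.
* Dunn p-values are two-sided by convention; one-sided use requires
  halving manually.
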