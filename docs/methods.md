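# Methods

This note documents the model, the numerical choices, and the design
decisions behind `muvi`, and states what the synthetic-data tests do and do
not demonstrate about real instrument data.

## Spectral model and indices

UV-Vis spectra of humified organic matter decay approximately exponentially
with wavelength. The slope indices are obtained by fitting

    a(λ) = a_ref · exp(−S(λ − λ₀)) + K

to the normalized spectrum over two windows, 275–295 nm (S275) and
350–400 nm (S350), with λ₀ fixed at the window start. λ₀ only rescales
`a_ref`, never `S`, so the choice is cosmetic. `K` is a free background
constant; it absorbs offsets but also means the three parameters are nearly
degenerate when the decay within a window is shallow (see *Numerical
behavior*).

The short-window bound deserves a note: slope conventions in the CDOM
literature variously quote 275–290 and 275–295 nm. The slope ratio
SR = S275/S350 is defined on 275–295, and one window must serve both the
slope index and the ratio for SR to be self-consistent, so this package
uses 275–295 nm for both. Window bounds are overridable through
`RunConfig`.

Point indices (a254 … a440, a250/a365) are exact grid lookups on the
canonical 200–800 nm, 1 nm grid — never interpolated — which fixes their
sampling unambiguously. All indices are computed from the unit-maximum
normalized spectrum, making them invariant to concentration, dilution and
pathlength; the raw 254 nm absorbance is kept separately because the
screening gate is deliberately *not* scale-invariant (weak absorbers must
fail it).

Absorbance is used in AU as measured rather than converted to Napierian
absorption coefficients: normalization cancels the constant factor, and
the decision thresholds are defined on measured absorbance in a 1 cm cell.
Non-unit pathlengths are stored but warned about.

## Slope-fit numerics

The fit is a bounded trust-region least-squares problem
(`scipy.optimize.least_squares`, bounds S ∈ (0, 1], K ∈ [−0.1, 1],
a_ref ∈ (0, 10]) with fully deterministic initialization:

* S₀ — slope of an ordinary least-squares line through
  log(a − min(a) + ε) vs λ, with ε = 10⁻³ × (window range);
* K₀ — the window minimum; a_ref₀ — first window value minus K₀;
* tolerances 10⁻¹⁰ on step, cost and gradient; up to three deterministic
  restarts perturbing only K₀ (+0.01, −0.01, +0.005);
* a generous function-evaluation budget (5000), because flat or
  noise-dominated windows put the optimizer on a long degenerate ridge
  before the bound is reached.

There is no randomness anywhere in the fit; identical inputs give
bit-identical results on a given platform.

A fitted decay rate at the numerical floor (≤ 10⁻⁶ per nm) is flagged
non-exponential rather than raised: a flat or peaked adulterant spectrum
should flow through to scoring and fail on percent error, not crash the
pipeline.

**Accuracy.** On noiseless exponentials the fit recovers (a_ref, S, K) to
better than 10⁻⁶ relative error across S ∈ [0.005, 0.05] on both windows.
With additive noise of 10⁻⁴ AU (a typical double-beam instrument floor)
and window amplitude ~0.8, recovery on the 51-point 350–400 nm window is
within 5 % for every seed tested (100-seed empirical check; max ≈ 1.9 %).
The 21-point 275–295 nm window is ill-conditioned for very shallow decay
(S ≈ 0.005: the curve is nearly linear within the window and S trades off
against K), where single-seed errors can exceed 10 %; at fulvic-typical
S ≈ 0.018 it stays within 5 %. These figures were established by
simulation before the test tolerances were frozen.

## Scoring and decision rule

Percent error uses the standard's value as denominator,
PE = |v_a − v_s|/v_s × 100, so the profile is asymmetric by construction
(scoring A against standard B differs from B against A). PE_avg is the
equal-weighted mean of the ten PEs; every report verifies on construction
that its stored PE_avg equals the mean of its own per-index values.
Replicates are aggregated by averaging per-index PEs and recomputing
PE_avg — both steps are linear, so the order does not affect the result,
only the concordance check (which needs per-replicate values).

Both cutoffs are strict inequalities: raw a254 must exceed 0.08 AU and the
minimum PE_avg across standards must be strictly below 70 %. Boundary
values fail — a sample at exactly 0.08 AU does not pass the absorbance
gate. The minimum (not the mean) across SRFA/PPFA is used so that a
product resembling either standard passes; single-standard scoring is
allowed but logged. The 60–90 % gray zone is flagged on every decision; by
default the verdict stays binary (which is what the published validation
tables report), and an opt-in gray-zone mode downgrades gated-in samples
to `indeterminate`.

The replicate-concordance rule — more than 20 percentage points of spread
between replicate PEs on any index — flags but never aborts: the remedy
(re-acquisition) is a laboratory action, not a software one. Note that
against the bundled standards the slope-index PEs are divided by
low-precision reference values (S275 = 0.01), so at a noise floor of
2×10⁻⁴ AU roughly a third of synthetic triplicates trip the flag through
those two indices alone; at 1×10⁻⁴ AU none do (100-seed check). This is a
faithful property of the published reference precision, not a bug.

SSSAD, the prior-art statistic carried for comparison, takes values at
290–330 nm in 5 nm steps, zeroes each series by its minimum, scales by the
zeroed 290 nm value, and sums squared differences. The name ("squared sum
of differences") is ambiguous about whether squaring precedes summation;
the sum of squared differences matches the statistic's intent and is the
default, with a summed-absolute-differences mode available.

## Bundled reference data

The SRFA/PPFA index values ship as published (rounded) figures, because
users without IHSS material cannot re-derive them. Two consequences are
documented rather than patched:

* slope-index percent errors recomputed from the rounded values disagree
  with some published PE cells (which were evidently computed from
  unrounded internal values); regression tests assert only the cells
  consistent with printed precision;
* the published phase-1 table contains one sample (ACFP-09) recorded as
  fulvic despite PE_avg above the cutoff; the strict rule yields
  non-fulvic, and the regression test pins this single known mismatch
  (39/40 phase-1 rows reproduce; 23/23 phase-2 rows reproduce).

## Synthetic-spectrum generator

The generator's default parameters emulate the study conditions: a ~5 ppm C
fulvic dilution in a 1 cm cell (amplitude 0.6 AU at 200 nm, decay 0.015 per
nm, raw a254 ≈ 0.27 AU) with additive Gaussian noise of 2×10⁻⁴ AU.
Noise is additive, not multiplicative, because the dominant
spectrophotometer noise near the detection floor is approximately
signal-independent. Metal-binding difference bands are additive Gaussians
at the literature band centers (200/240/276/316/385/547 nm); no lineshape
or width is established for these features, so width defaults to 15 nm.
At that width a 385 nm band perturbs a412 strongly (~24 % at height
0.03 AU) but barely reaches a440 (~0.2 %), and a 547 nm band reaches
neither — experimentally both 412 and 440 nm respond to metal addition,
implying broader real difference features. The tests therefore assert the
direction and localization of the perturbation, not its published
magnitude. A narrow band inside the 350–400 nm window also corrupts the
S350 fit, inflating the slope-ratio PE well beyond the few-percent effect
seen with real metal additions; this is a property of the narrow-band
assumption.

Adulterant archetypes — `flat`, `gaussian_mixture` (discrete chromophore
peaks), `near_zero` (≈0.005 AU, the weak-absorber case) — are test
constructions with no claim of chemical fidelity; they exercise,
respectively, the non-exponential flag, the shape gate, and the absorbance
gate.

The SRFA-like reference curve (`srfa_like_spectrum`) is a synthetic
fixture: a monotone piecewise-cubic interpolant in log-absorbance through
a frozen anchor table. The anchors pin the published point-index values
exactly and carry pure-exponential runs through both slope windows, with
the long-window rate fixed by the published a355/a412 pair
(ln(0.14/0.05)/57 ≈ 0.0181 per nm) and the short-window rate fixed at
0.703× that by the published slope ratio. Its ten computed indices
reproduce the published SRFA values at printed precision. A sum of
positive exponentials cannot do this — any such sum has a slope ratio
≥ 1, whereas real fulvic spectra steepen toward long wavelengths
(SR ≈ 0.7) — which is why the fixture is anchored rather than parametric.

**What passing tests do not show.** The generator contains no stray-light,
baseline-drift or cuvette-mismatch artifacts, no pH- or aggregation-driven
shape changes, and its adulterant shapes are idealized. Synthetic-cohort
classification accuracy therefore demonstrates the pipeline's internal
consistency, not field performance on real products.

## Problem sizes

Test and acceptance runs use the canonical 601-point grid, triplicate
replicates, 100-seed empirical checks for noise-sensitive claims, and the
full published validation tables (40 + 23 samples). The whole suite runs
in well under a minute on one CPU.
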