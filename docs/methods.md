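# Methods

This note documents the models and numerical choices behind `nirfuse`, what
the synthetic generator does and does not emulate, and the design decisions
taken where the workflow admitted more than one reasonable reading.

## Synthetic spectra and traits

**Traits.** SSC (°Brix), MC (mass fraction) and FF (N) are drawn from a
Gaussian copula: z ~ N(0, I₃) is coloured by a factor L with LLᵀ = R (the
target correlation matrix; Cholesky when positive definite, eigenvalue
square root otherwise) and rescaled to the configured means and SDs. The
default R is the empirical matrix for commercial-maturity apricot plum
(SSC–MC −0.96, SSC–FF +0.81, MC–FF −0.79; smallest eigenvalue ≈ 0.039, so it
is a valid correlation matrix). The measured trait means/SDs were not
published; the defaults — SSC 15 ± 2 °Brix, MC 0.85 ± 0.03, FF 12 ± 3 N —
are typical for ripe stone fruit and give coefficient-of-variation and RMSE
scales consistent with the reported model errors (e.g. an SSC RMSE of
~0.52 °Brix at R² ≈ 0.93 implies an SD near 2 °Brix). MC is clipped to
[0, 1] after generation because it is a mass fraction.

**Spectra.** Each spectrum is
`(1 + slope_i)·clean_i + offset_i + ε`, where
`clean_i = base(λ) + Σ_k (Lᵏ·traits_i)·exp(−(λ−c_k)²/2w_k²) + drift(λ)`.
The base curve carries the characteristic troughs at 1180 nm (cell-wall C–H)
and 1445 nm (O–H of water) and the peak at 1285 nm (sugar C–H combinations);
the per-peak trait loadings make the 1285 nm amplitude affine in SSC, deepen
the 1445 nm trough with MC and the 1180 nm trough with FF. `drift(λ)` is an
additive ramp proportional to the distance outside 1040–1625 nm and exactly
zero inside — this is what makes head/tail trimming and range restriction
meaningful on synthetic data. Scatter slopes/offsets are N(0, 0.05)/N(0, 0.02)
per sample; measurement noise is i.i.d. N(0, 0.002) per point (about 1% of
the trait-induced signal swing — optimistic relative to a handheld
instrument, deliberately so, to keep oracle tests sharp).

Streams: traits use `seed`, scatter `seed+1`, noise `seed+2`, so the three
sources are independent but jointly reproducible; identical config + seed
gives bit-identical output.

**What the generator does not emulate.** Real absorbance is nonlinear in
constituent concentrations (Beer–Lambert deviations, path-length variation),
band positions shift with temperature, instrument noise is heteroscedastic
and wavelength-correlated, and peak shapes are Voigt-like rather than
Gaussian. Passing tests on this generator therefore demonstrate the
correctness and statistical behaviour of the *algorithms* (selection,
fusion, attribution, screening), not field performance on fruit.

## Preprocessing

All transforms are per-spectrum (row-wise), matching how these corrections
are used on NIR curves: min–max maps each spectrum onto [0, 1]; SNV centres
and scales to unit SD with the n−1 divisor (fixed by the (1,2,3) → (−1,0,1)
contract); MSC regresses each spectrum on a reference (default: the block's
column-mean spectrum) and inverts the fitted affine distortion; Savitzky–
Golay is delegated to `scipy.signal.savgol_filter` with `mode="interp"`
(polynomial extrapolation of the terminal windows), which assumes a uniform
grid — the 5.6 nm instrument step satisfies this. Constant rows and
near-zero MSC slopes (|b| < 1e−12) fail loudly with the offending sample
named; returning zeros silently would corrupt coefficient-driven selection
downstream. The default pipeline order is min–max → SNV. "15 points from
head and tail" is read as 15 per end (129 − 30 = 99, the only reading
consistent with the stated final count).

## Splitting and PLSR

Kennard–Stone uses Euclidean distances on the preprocessed spectra: the
first two picks are the maximally distant pair, then greedy max–min; ties
break to the lowest sample index, and calibration indices are returned
sorted, so the split is a pure function of the data. Whether selection runs
on raw or preprocessed spectra is a free choice; the pipeline splits after
preprocessing (flagged in the config by construction, since preprocessing is
part of the recipe).

PLSR is single-response NIPALS with deflation of X only; the aggregate
coefficient vector B = W(PᵀW)⁻¹q reproduces prediction as ŷ = ȳ + (x−x̄)B.
Component extraction stops early when ‖Xᵀy‖ < 1e−12 (the achieved rank is
recorded). With all components on full-rank tall X the fit equals ordinary
least squares, which is the main correctness oracle; score orthogonality is
asserted to 1e−8. The component count is chosen by venetian-blind K-fold CV
(K = 5; fold k holds samples k, k+K, …), minimising CV RMSE with ties going
to the fewest components; the cap is 20 components. Validation R² is
computed against the validation set's own mean, and RMSE uses the divisor n
(the conventional RMSEP definition).

## Wavelength selection

**CARS** defaults: 50 Monte-Carlo runs, 80% random calibration draw per run,
5 PLS components, 5-fold CV scoring, terminal retention of 2 variables.
These constants are the canonical published CARS settings (the study did not
print its own) and are all config-exposed. The retention schedule is
r_i = a·e^(−k·i) with r_1 = 1 and r_N = final_keep/p; each run keeps the
top-|B| variables to that count and then resamples that count with
replacement with probability ∝ |B|, collapsing duplicates. The winner is the
run with minimal CV RMSE.

**SFLA** encodes subsets as binary masks (the continuous frog-leap update
has no canonical discretisation; copying each differing bit with probability
½ toward the target is the natural binary analogue). Fitness is CV RMSE plus
an optional per-band penalty (default 0 — published band counts suggest no
explicit sparsity pressure). Frogs are ranked and dealt round-robin into
memeplexes; the worst frog of a memeplex leaps toward the memeplex best,
then the global best, and is re-randomised if still not improved (standard
censorship, replacing the worst frog unconditionally). All-zero masks are
repaired by activating one random bit. The returned optimum is the best mask
ever evaluated, so the reported trace is non-increasing by construction.

Both selectors are deterministic given (data, config, seed); per-run streams
derive from one master generator.

## Fusion, Shapley attribution and screening

Band lists from different trait models are matched by wavelength value after
rounding to 3 decimals (the precision of reported instrument grids); the
fused set is the sorted union with per-band provenance. One published FF
entry, "1224;131", is canonicalised to 1224.131 nm — the only reading
consistent with the neighbouring grid spacing.

The value function f(S) is mean-imputation over calibration-sample means
(interventional, independence-assuming). This is the only choice under which
the Shapley sum is computable without a data model and under which the
affine closed form φ_ij = B_j(x_ij − m_j) is exact; the full enumeration
(guarded at 20 bands, ~10⁶ subset evaluations) is kept as the oracle. The
background is computed from calibration rows only, avoiding validation
leakage. Per-band importance is the mean of |φ| over calibration samples, in
trait units — the natural scalar summary of a per-band attribution
distribution.

Screening stage 0 fits the full fused set on the calibration rows; each
subsequent stage drops bands whose importance, computed from the *previous*
stage's model (a `one_shot` switch reuses stage-0 importances instead),
falls below that stage's threshold, then refits and re-evaluates. Retained
sets are nested; a stage retaining zero bands is marked degenerate rather
than silently fitted, and later stages inherit the flag. Published absolute
thresholds (2/4/6/8 in trait units) are tied to the scale of the original
unreleased data, so the package treats thresholds as configuration; the
pipeline's default derives them from the quartiles of the stage-0 importance
distribution, which adapts the ladder to any data scale.

## Pipeline

`run_pipeline` executes generate/load → preprocess → Kennard–Stone split →
per-trait selection + PLSR → trait correlation (computed on all samples,
before splitting) → fusion → screening, spawning all per-stage seeds from
one master seed via `SeedSequence`. The report contains no wall-clock or
environment fields, so identical (config, seed) runs produce byte-identical
JSON. Default split is 2/3 calibration (80 of 120).

## Problem sizes in tests

Oracle and property tests run at small n (8–120 samples, 5–99 bands), the
Monte-Carlo checks at the sizes their tolerances are derived from: trait
correlations at n = 2000 (±0.05 covers the sampling SE of r ≈ 0.96 many
times over), CARS planted-band recovery over 20 seeds on the full 120 × 99
study geometry, Shapley oracle equivalence over 20 random models of up to 12
bands. The full suite runs in a few seconds on one core.

## Known limitations

- PLS1 only; no multi-response PLS2 or nonlinear regressors.
- The exact Shapley enumeration is exponential and guarded at 20 bands; for
  affine models the closed form should always be used instead.
- Savitzky–Golay assumes a uniform wavelength grid.
- The synthetic generator's realism limits are listed above; no claim is
  made that selector hyperparameter defaults reproduce the band lists
  obtained on the original fruit data.
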