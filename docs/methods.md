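# Methods

This note documents the statistical models, numerical choices and known
limitations of `biofabopt`, in the spirit of a package vignette.

## Design construction

A rotatable central composite design for k factors holds 2^k factorial
runs at coded ±1, 2k axial runs at ±α with α = (2^k)^(1/4), and n_c
center replicates: for the bundled four-factor study, 16 + 8 + 6 = 30
runs with α = 2 and coded levels {−2, −1, 0, +1, +2}. Rotatability makes
the scaled prediction variance of the quadratic model a function of the
distance from the design center only, which the test suite verifies
numerically for k = 3 by evaluating m(x)'(X'X)⁻¹m(x) on random
equal-radius points.

Standard order is deterministic — factorial core in binary order with
the first factor varying fastest, axial pairs per factor, then centers —
matching the bundled study's standard-order column. Run order is treated
as presentation only; all analyses key on standard order. Coded units are
canonical: fitting in coded space keeps the model matrix well-scaled and
makes coefficients directly comparable across factors (one coded unit =
one step in actual units: 1 pH unit, 4 mg/mL collagen, 24 h, 5 °C).

## Quadratic fit and ANOVA

The 15-term second-order model is fitted by QR-based least squares; rank
deficiency is detected from the R diagonal (tolerance 1e−9 relative) and
reported with the offending column labels. Hat diagonals come from the
thin-Q rows, (X'X)⁻¹ from R⁻¹R⁻ᵀ.

Per-term tests use partial (Type III) sums of squares,
SS_j = β̂_j²/[(X'X)⁻¹]_jj. In this orthogonal design, linear and
interaction partial SS coincide with sequential SS, but the four pure
quadratic columns are mutually correlated (all share the centers/axials
pattern), so partial SS is the convention that reproduces standard DoE
software output; this was verified against the bundled study's printed
table.

Lack of fit splits the residual using replicate groups (identical coded
rows): SS_PE = Σ within-group SS with Σ(n_g − 1) df, SS_LOF the
remainder. With no replicates the split is omitted and the residual row
stands alone. PRESS uses the leave-one-out identity
e_(i) = e_i/(1 − h_ii); an explicit refit oracle in the tests confirms
equality to 1e−8. Derived statistics follow the conventional DoE
definitions: predicted R² = 1 − PRESS/SS_total,
CV% = 100·√MS_res/ȳ, adequate precision
(max ŷ − min ŷ)/√(p·MS_res/n) over the design points. F and χ²
tail probabilities come from scipy's regularized incomplete
beta/gamma implementations.

## Box-Cox profile

For each λ on a grid (default [−3, 3] step 0.01) the response is
transformed with geometric-mean scaling, z = (y^λ − 1)/(λ g^(λ−1)) and
z = g·ln y at λ = 0, so residual SS are comparable across λ; the model is
refitted (one QR of the fixed model matrix, then cheap projections) and
λ_opt is the grid argmin of SS(λ). The confidence region uses the
F-based threshold SS_λ ≤ SS_min·(1 + F(conf, 1, df_res)/df_res). A
χ²(1)/n likelihood-ratio threshold is the textbook alternative; it gives
a visibly narrower interval on the bundled data ((0.57, 1.76) vs
(0.33, 2.10)), and the F form is adopted because it is the construction
used by the DoE software this workflow emulates and it reproduces the
study's printed interval. Responses must be strictly positive.

## Desirability optimization

The Derringer maximize ramp is d = 0 below the observed minimum yield,
1 above the observed maximum, and ((y − low)/(high − low))^w between —
the "in range" defaults of standard DoE software. Because the ramp
saturates at the best observed response, the desirability surface has a
d = 1 plateau wherever the fitted surface predicts above it; any plateau
point is a valid argmax of d. The optimizer therefore breaks ties
deterministically in favor of the larger predicted response: after the
multi-start search (5^k coarse grid, Nelder-Mead polish from the top 10
cells, seed only breaking ties), a final response-polish step maximizes
the raw prediction from the best desirability point. This keeps
argmax(d) = argmax(y) for monotone goals and returns the surface's
stationary point (12.59 mg/mL on the bundled fit) rather than an
arbitrary plateau point. Published plateau optima from interactive
software can sit anywhere on the plateau, which is why reported optima a
few tenths of a mg/mL below the stationary value are consistent with
this fit.

The default search region is the factorial box [−1, 1]^4; the axial box
[−2, 2]^4 is available but extrapolates the quadratic into a region
supported only by single axial runs per factor.

## ANN surrogate

Architecture: inputs in coded units (already centered, ±2 range), one
hidden layer of H = 20 tanh units, linear output; the response is min-max
scaled to [0, 1] for training and inverse-transformed for reporting.
Training is deliberately simple and fully reproducible: full-batch
gradient descent on the training-split SSE, initial learning rate 0.1,
halved on any non-decreasing step (floor 1e−6), stopping at max_epochs
(default 2000) or gradient norm < 1e−10. "Tours" are independent
Gaussian restarts (weights ~ N(0, 1/√fan-in)); the tour with the lowest
validation SSE is kept. The default is 50 tours — enough for the
training fit to interpolate (training R² ≥ 0.999 on the bundled data)
while keeping a full run around three seconds; the original workflow's
5000 tours is a supported setting, not the default, because the retained
model's quality, not the restart count, is the contract. Commercial
implementations train the same architecture with penalized likelihood
and quasi-Newton steps; this package promises the architecture and the
metric definitions, not any particular weight trajectory, so all
network-level acceptance checks are property-based (fit quality,
reproducibility, capacity) rather than weight-for-weight.

Holdback validation withholds round(n·0.2) runs chosen uniformly with
the configured seed, or uses the fixture's published 24/6 labels. With
only 6 validation runs the validation metrics are high-variance;
they are reported but should be read qualitatively. The Gaussian profile
−log-likelihood n/2·(ln(2π σ̂²) + 1) with σ̂² = SSE/n follows the
reporting convention of common statistical software (and goes negative
for near-interpolating fits).

The surrogate optimizer grid-searches the axial box (where a flexible
surrogate may place its optimum on the boundary, e.g. at the collagen
upper level) with optional Nelder-Mead polish, and shares the
desirability ramp with the response-surface optimizer.

## Bioassay effect sizes

All assay formulas are closed-form absorbance ratios; viability +
cytotoxicity = 100 holds identically. Tumor volume is the caliper
approximation V = L·S²/2 and growth inhibition
TGI% = 100 − 100·ΔT/ΔC on day-20 minus day-0 volume changes, with
volumes rounded to 2 dp before differencing to match how published
tables are computed. One important data subtlety: published tumor tables
print group-mean diameters *and* group-mean volumes, and the mean of
per-animal volumes is not the volume of the mean diameters — on the
bundled table the two printed reference volumes cannot both be
regenerated from the diameters under any single rounding rule.
`TumorRecord` therefore carries the published volumes alongside the
diameters and prefers them, which reproduces the published TGI column
exactly; volumes recomputed from diameters agree within one unit in the
last printed digit. The IC50 helper is log-linear interpolation between
the doses bracketing 50% only — dose-response curve fitting is outside
this package's scope.

## Synthetic data

`simulate_campaign` draws y = m(x)'β + N(0, σ²) on the CCRD layout; the
defaults are the bundled study's conditions: its four factors, six
center replicates, its fitted coefficient vector as the true surface,
and σ = 0.163 mg/mL, the residual standard deviation of that fit, so
synthetic campaigns match the study's signal-to-noise. Negative draws
are floored at zero (a yield cannot be negative) with the count
recorded; at the default settings the surface minimum (≈4.3 mg/mL) is
26 standard deviations above zero, so flooring never triggers in
practice. Calibration checks in the test suite: zero-noise campaigns are
recovered to 1e−10; 95% coefficient CIs cover the truth within ±3
points over 1000 campaigns; the lack-of-fit test's size is 5% ± 2 points
over 2000 campaigns under the null. What the generator does *not*
emulate: real batch effects, drift between runs, non-Gaussian or
heteroscedastic noise, and model misspecification (a true surface that
is not exactly quadratic) — passing calibration tests therefore
validates the estimators' arithmetic and distributional theory, not
robustness to those violations. The tumor-table generator inverts the
volume/TGI formulas to construct groups hitting specified inhibition
targets exactly (before rounding), with a small seeded jitter on day-0
dimensions mimicking randomized allocation.

## Problem sizes and determinism

All analyses of the bundled data are desk-scale (30 × 15 least squares).
Simulation-based tests use 200–2000 replicate campaigns and the ANN
tests 2–50 tours; the complete suite runs in about half a minute. Every
source of randomness flows through an explicitly passed seeded
generator; there is no global RNG state, and identical seeds give
bit-identical designs, networks and reports.

## Known limitations

- Single-response optimization only; no multi-response desirability.
- No blocking, face-centered, Box-Behnken or D-optimal designs.
- No robust/mixed-model regression or stepwise term selection.
- The ANN is a fixed shallow architecture; no regularization schedules
  beyond step-halving, no deep variants.
- Assay statistics stop at effect sizes; group-comparison testing
  (ANOVA/Tukey on assay replicates) is out of scope.
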