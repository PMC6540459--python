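# Methods

## Scope

`h2axdose` reconstructs injected Cs-137 activity (and committed whole-body
dose) from the γ-H2AX fluorescence of blood mononuclear cells and the time
since exposure. It covers whole-body biokinetics and dosimetry, the
forward fluorescence-kinetics model, its maximum-likelihood calibration
with profile-likelihood uncertainty, Monte-Carlo inversion of measurements
into activity estimates with correlation/ROC scoring, the per-cell
screening rules that produce group-level means, and a seeded generator of
synthetic studies. Wet-lab protocols, image analysis, phantom calibration
of the whole-body counter, and organ-level (non-whole-body) dosimetry are
out of scope.

## Biokinetics and dosimetry

Whole-body retention is a biexponential in biological half-times,
R(t) = f₁·exp(−ln2·t/T₁) + f₂·exp(−ln2·t/T₂), with mouse defaults
f = 0.20/0.80 and T = 0.6/7.8 d. Two deliberate conventions:

* **Physical decay omitted.** Cs-137's ~30-year half-life contributes
  < 0.1% over a 14-day study; retention is purely biological.
* **ln 2 as printed.** The published curve uses 0.693; that literal value
  is the default (`LN2_PRINTED`) so results match the curve as published,
  and every operation accepts `ln2=math.log(2)` for the exact constant
  (difference ~2×10⁻⁴ relative).

Cumulative disintegrations integrate activity·R(t) in closed form
(cross-checked against numerical quadrature in the tests); committed dose
is disintegrations × SEE (specific effective energy, Gy per
disintegration); daily dose rate is the day-over-day difference of
committed dose on integer days 1–14.

**SEE is configuration, not a constant the package vouches for.** The
published SEE for whole-body Cs-137 (2.41×10⁻¹⁹ Gy/dis) combined with the
average retention curve underpredicts the study's measured committed doses
by orders of magnitude (the measured doses derive from unpublished
per-animal retention fits, and the printed SEE value appears to carry a
unit misprint). `DoseModel` therefore requires SEE explicitly and offers
`DoseModel.calibrated(...)`, which rescales SEE against a measured
(activity, day, dose) anchor. Absolute dose reproduction is not claimed;
dose *conversion* of activity estimates instead uses the measured
committed-dose table directly (below).

Retention-curve fitting (`RetentionModel`) is least squares with
log-parameterised half-times, a logit fraction, Levenberg-Marquardt and 10
seeded multistarts; the fast/slow labels are enforced by relabelling, and
a single-exponential variant (fraction_fast = 0) covers short-duration
animals.

## Forward fluorescence model

F(A, t) = b + k·A·t·exp(−α·A + 1 − (1 + r·t)^p), with b fixed at the
measured control background (1006 AU for blood; the control SEM is 36 AU).
Units are fixed at MBq and days. The published blood calibration
(`presets.BLOOD_BESTFIT`) is k = 4.65×10⁵ AU·MBq⁻¹·d⁻¹, α = 0.255 MBq⁻¹,
r = 1.07×10⁶ d⁻¹, p = 0.153; the day unit for r follows the calibration
table's header. (1 + r·t)^p is evaluated as exp(p·log1p(r·t)) and the
whole signal in log space, so r·t ~ 10⁷ never overflows; the tests verify
agreement with the naive formula to 1e-10 relative wherever the latter is
finite.

Geometry used downstream: the response is separable, F − b = g(A)·h(t)
with g(A) = k·A·e^(−αA), so the activity of maximum response is 1/α
(≈ 3.92 MBq for the published α) at every time, and the peak time (≈ 0.2 d
for the published parameters, i.e. before the first sampling day) is
independent of activity.

## Calibration fit

The likelihood is Gaussian at the group-mean level with known standard
deviations equal to the reported SEMs (weights 1/SEM²); SEMs describe
variation across the 8 animals of a data point, so the group mean — not
the cell — is the sampling unit. b is fixed; (k, α, r, p) are optimised on
transformed scales (log; logit for p) by Nelder-Mead with a BFGS polish,
over seeded multistarts (default 20). Two numerical choices matter:

* **Start sampling in (scale, shape) rather than (r, p).** Most of the
  (r, p) plane puts r^p so high that the signal underflows and the
  likelihood is exactly flat; starts there teach the optimiser nothing.
  Starts draw the decay scale s = r^p log-uniformly in [0.3, 50] and set
  r = s^(1/p).
* **The (k, r, p) ridge.** The data constrain the composite decay scale
  r^p (and the signal level) much better than r or p separately, so the
  likelihood has a long curved ridge: equally good fits exist with very
  different individual k and r. This is reflected honestly in wide or
  open-ended profile intervals for k and r; α is well identified. Profile
  optimisations therefore use, besides the warm start, a structured start
  that preserves r^p when r or p is fixed, plus two deterministic
  perturbations — without these the profile can be grossly overestimated
  on the far side of the ridge.

Data spanning fewer than two distinct activities or times are rejected up
front (k·A·e^(−αA) at a single A collapses to one degree of freedom); a
Hessian condition number is reported on every fit.

Profile CIs bracket the deviance crossing of the χ²(1) 95% quantile
(3.841) by outward scanning with warm continuation and refine it by
bisection (relative tolerance 1e-3); unbracketed bounds are returned
open-ended and flagged. The joint confidence region for ensemble sampling
uses df = number of free parameters (4 → 9.488); both df conventions are
explicit arguments.

## Monte-Carlo inversion

The confidence-region ensemble (≥ 5000 draws) is rejection sampling:
independent log-normal perturbations of the best fit (logit-normal for p,
which must stay in (0,1)), with per-parameter scales set from the profile
CIs inflated to the joint-region radius, accepted iff the deviance is
within the χ²(4) quantile. The sampler is vectorised, reproducible under
its seed, and aborts with a diagnostic if acceptance falls below 10⁻⁴.
This explores the region around the best fit rather than sampling it
uniformly; medians and ranges of the resulting activity estimates are
summaries of calibration uncertainty, not posterior quantiles.

Inverting a measurement minimises f = [F(ψ, t, A) − F_obs]² over A.
Separability reduces this to A·e^(−αA) = C, solved in closed form with the
Lambert-W function (principal branch = rising limb, W₋₁ = falling limb);
this is exact, vectorises over the ensemble, and equals the bounded 1-D
minimiser the tests use as an oracle. The default branch is the falling
limb ("high", A ≥ 1/α) because all study activities lie there for the
calibrated α. Measurements above the response ceiling at A = 1/α return
1/α flagged `saturated`; measurements at/below background or outside the
search interval (default 0.1–20 MBq) return the boundary flagged
`out_of_range`. Flagged draws are excluded from medians/ranges and their
count reported; a point with no unflagged draw is `undefined`.

Scoring: Pearson r with t-distribution p-values (n − 2 df); Spearman ρ
with an exact full-permutation p-value for n ≤ 9 (the study's windows) and
the t-approximation otherwise; default windows 2–3, 2–5, 2–7, 2–14 days.
Activity→dose conversion multiplies by the per-day mean of the measured
committed dose ÷ administered activity over the four groups (0.269 Gy/MBq
at day 2 rising to 0.952 Gy/MBq at day 14); off-grid days require explicit
interpolation. The low/high classifier normalises median estimates by
their maximum; AUC uses the Mann-Whitney identity with tie midpoints
(identical to the trapezoidal area under the empirical threshold-sweep
ROC), and its 95% CI the DeLong structural-components variance with a
normal approximation truncated to [0, 1].

## Cell-level rules

Cells with total fluorescence strictly above 3000 AU (fragmented DNA,
advanced apoptosis) are removed before any mean is formed — the only path
from cells to a calibration point. Damage classes use strict cutoffs:
healthy < 500 AU, damaged > 3000 AU, boundary values intermediate. Group
means and SEMs are computed over per-animal means (n = animals); pooling
cells across animals would understate the SEM that the calibration
weights rely on. Single-animal groups have undefined (flagged) SEM.

## Synthetic-data generator

The generator emulates the study design (activities 5.74/6.66/7.65/9.28
MBq + vehicle control, days 2/3/5/7/14, 8 animals per point, 150–500 cells
per sample) and the statistical structure the analysis assumes:

* **Group means:** per-animal means Gaussian around the model prediction
  with SD √n × 36 AU, so the group SEM matches the measured control SEM in
  expectation (verified by a 500-replicate calibration check). Zero-noise
  data get an SEM floor of 1 AU to keep weights finite.
* **Retention:** per-animal half-times log-normal with 15% CV (a plausible
  inter-animal variability; the study reports none), sampled on the
  counting schedule (daily to day 7, then days 10 and 14).
* **Cells:** a log-normal bulk (σ = 0.5 on the log scale) truncated below
  the 3000 AU cutoff, its location solved by root finding so the
  post-filter mean equals the animal's target, plus an apoptotic tail
  (weight 5%) shifted above the cutoff. The tail is a fixture choice, not
  a measured distribution.

Group-level Gaussian noise is the data-generating path for fitting tests
(the likelihood is defined at that level); the per-cell layer exists to
exercise the screening rules and end-to-end aggregation, which reproduces
the group table to within per-cell Monte-Carlo error. What passing tests
show is therefore internal consistency and statistical calibration under
the assumed noise model — not that real mouse data follow these
distributions, and not a reproduction of the study's measured
correlations or AUC, which would require the original per-group
fluorescence tables.

## Problem sizes and seeds

All randomness flows through explicit seeds. The test suite uses: 200
replicates for profile-CI coverage (checked per parameter against an
88–99% band via the deviance-membership rule, which for a unimodal profile
is the same decision as computing both CI endpoints), 100 replicate
studies for the early-vs-full-window correlation comparison (fixed
calibration ensemble of 1000 draws, mirroring triage use where the
calibration predates the measurement), a 5000-draw ensemble for the
inversion round trip, and 50 replicates for the ROC identities. The
acceptance script fits one 20-point study and inverts it with a 5000-draw
ensemble.

## Known limitations

* k and r are reported with honest but very wide (sometimes open-ended)
  profile intervals; only α, p and the composite r^p are sharply
  identified by a 20-point design. Different seeds can land on distant,
  equally likely ridge points.
* The ensemble is a confidence-region sample, not a posterior; min/max
  ranges depend on the proposal scale through coverage of the region's
  extremes.
* Dose output is only as meaningful as the SEE or the measured
  committed-dose table supplied; absolute dosimetry from the average
  retention curve plus the printed SEE is knowingly inconsistent and not
  attempted.
* Spleen data are supported structurally (background preset 878 AU) but
  no spleen calibration is shipped; the published spleen fits were not
  predictive except at day 14.
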