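# Methods

This note documents the statistical model, the synthetic-data
generator, the numerical choices, and the known limitations of the
`fallrisk` package. Nothing here states an empirical result that the
test suite or `scripts/acceptance.py` does not itself compute.

## The fall model

Falling (≥1 fall in the prior 12 months) is modelled by binary logistic
regression on eight key factors: multidimensional balance B (points,
0–40), lean body mass L (kg), fat body mass F (%), total and vigorous
physical activity TPA/VPA (per 100 MET-min/wk), weekday seated rest R
(h/day), health-condition count HC, and environmental-hazard count H.
Protective factors (B, L, TPA) carry negative coefficients, risk
factors positive ones; the variable registry records this direction for
all 19 candidate variables, and the profile machinery refuses models
whose coefficient signs contradict it (monotonicity along the profile
curve would fail).

The reference equation has coefficients (−0.053, −0.026, +0.027,
−0.012, +0.034, +0.125, +0.112, +0.063) and **no intercept**. Whether
the original fit truly had β0 ≈ 0 or the intercept was omitted in
presentation cannot be determined from the printed equation alone; the
package therefore treats the two uses differently:

* the **stratification engine** uses the equation verbatim (β0 = 0),
  because doing so reproduces the published probability cutoff and
  boundary values;
* the **data generator** treats β0 as a free parameter calibrated so
  that the mean predicted probability equals the target prevalence
  (0.372 by default), because parameter-recovery tests are only
  meaningful when the labelling model's location is known.

## Estimation

`FallRiskLogit` maximizes the binomial log-likelihood by iteratively
reweighted least squares (Newton–Raphson on the observed information):
convergence when the score vector's infinity norm is below 1e-8, at
most 100 iterations, with step-halving (up to 30 halvings) whenever a
full step would decrease the log-likelihood. The coefficient
covariance is the inverse observed information at the optimum. Rank
deficiency is detected up front by SVD rank and attributed to columns
via pivoted QR; separation is flagged when any coefficient exceeds 15
on the standardized scale. The test suite verifies the score equations
to 1e-6 and agreement with an independent reference implementation to
1e-6 in the coefficients.

Model building follows the traditional screening sequence: univariate
odds ratios per variable (physical activity rescaled to 100 MET-min/wk
first), then backward elimination from the full candidate set, dropping
the largest Wald p-value above α = 0.05 per round (ties broken by
candidate order, removals logged). The original analysis did not state
its selection procedure; backward elimination is this package's
operationalization and is configurable at the call site by passing a
different candidate list or α.

Goodness of fit uses the Hosmer–Lemeshow test with 10 groups of
near-equal size over ranked predicted probabilities. Tied
probabilities stay together in the lower group; degrees of freedom are
fixed at `n_groups − 2`; an expected cell count of zero raises an error
suggesting fewer groups.

## Discrimination

ROC points come from cumulative counting over a single sort (all
distinct thresholds kept; positive means score ≥ threshold — the
source analysis did not specify ≥ vs >, so ≥ is fixed here), and the
AUC is the trapezoidal integral, which equals the Mann–Whitney
probability of correct ranking with ties counted ½ (property-tested
against a brute-force pair count at 1e-12). The AUC interval is
DeLong's placement-value variance with a normal-theory interval
truncated to [0, 1]; the method choice is the package's own (the source
analysis did not name one). The Youden cutoff maximizes
sensitivity + specificity; among tied maximizers the smallest candidate
score is returned. Cross-validation partitions participants into k
(default 10) equal groups at random without replacement (remainder
spread one per fold, refolding up to 20 times if a fold lacks a class),
refits on each training complement, and pools the out-of-fold
probabilities into a single ROC — one curve, not an average of per-fold
AUCs.

## Quantile reconstruction and the profile curve

Each variable's quantile function is rebuilt from five percentile
anchors (1st/25th/50th/75th/99th) by piecewise-linear interpolation,
exact at the anchors. For stratification the domain is restricted to
[1, 99]. For data generation the tails continue the nearest segment's
slope and are truncated at physical bounds (0 for counts and activity,
40 for balance, 34 for hazards). When a real cohort is available, its
empirical quantiles (linear-interpolation definition) can replace the
anchors (`RiskStratifier(mode="re-derive")`).

The joint risk profile at percentile p places protective factors at
quantile p and risk factors at quantile 100 − p, with VPA = 0
throughout (its 42nd–69th percentiles are all zero, so it never enters
the inversion band and carries no interval references). The
complement pairing makes the risk-factor percentile exactly 100 minus
the protective percentile at every root. π(profile(p)) is then
strictly decreasing in p, and each cut probability c is inverted by
bisection on [1, 99] to |π − c| < 1e-10.

Note an ordering subtlety: a *higher* cut probability corresponds to a
*lower* percentile root. With the reference equation and anchors the
roots are ≈ 57.0 (π = 0.25), ≈ 45.0 (Youden 0.35939) and ≈ 32.4
(π = 0.50). Prose descriptions that pair the cuts with percentiles in
ascending order should be read against this: the 0.25 cut pairs with
the high percentile, the 0.50 cut with the low one, as direct
evaluation of the equation confirms.

## Presented strata and rounding

Continuous boundaries are rounded to each factor's presentation
precision: nearest integer (balance, lean, fat, counts), nearest 0.1 h
(rest period), and *up* to the next hundred MET-min/wk (activity,
matching the convention that 18.87 model units present as 1900).
Strata are maximal runs of representable values between rounded
boundaries with these conventions, chosen to match the published
interval lists where they are reproducible:

* protective factors — low: v > b₁; moderate: b₂ < v ≤ b₁;
  high: b₃ < v ≤ b₂; very high: v ≤ b₃;
* risk factors — low: v < b₁; moderate: b₁ ≤ v ≤ b₂;
  high: b₂ < v ≤ b₃; very high: v > b₃.

Under this rule the derived table reproduces the published intervals
exactly for balance and lean mass and the published boundary values for
lean 44 kg, balance 33, fat 42 % and hazards 8. Remaining differences
are expected artifacts of rebuilding a 500-person empirical quantile
function from five printed anchors: total-activity boundaries 2900/2400
vs published 2800/2300, rest-period very-high boundary 5.1 vs 5 h/day,
the lean high/very-high boundary rounding to 39 (continuous 38.61), the
health-condition high/very-high boundary 4 (continuous 4.41) vs 5, and
the hazards moderate band 5–7 vs the published singleton 5. These are
flagged, not forced.

Improvement deltas for an individual are computed on representable
steps (1 point, 1 kg, 1 %, 100 MET-min/wk, 0.1 h, 1 count): the
minimum sign-aware change that moves the factor's value into each
strictly lower-risk stratum, holding everything else fixed. The
overall stratum comes from the model probability against the cut
probabilities with half-open intervals (a probability exactly on a cut
belongs to the higher-risk stratum), not from a vote over per-factor
strata.

## Synthetic cohort generator

The generator emulates the study conditions: n = 500 participants,
faller prevalence 37.2%, marginals with the published anchor
percentiles, and a vigorous-activity variable that is zero for 80% of
the cohort. Latent Gaussian vectors with a configurable correlation
matrix are mapped through the normal CDF and each variable's extended
quantile function (Gaussian copula). Integer variables are rounded;
bounds are clipped. Vigorous activity is drawn comonotone with total
activity — the most active participants are the ones performing any
vigorous activity — rising linearly from zero at its 80th-percentile
rank to the 99th-percentile anchor (7200 MET-min/wk); because the
total's quantile dominates the vigorous quantile at every rank, the
TPA ≥ VPA constraint holds without distorting TPA's marginal.
Sociodemographics (sex ~ 27.6% male, age ~ N(72.2, 5.4²) truncated at
65, education ~ N(5.2, 3.9²) truncated at 0) are carried for the
selection stage but never enter the key model.

The default correlation (+0.4 within the protective fitness block,
−0.3 between fat mass and that block, +0.2 between the two counts,
verified positive semidefinite) exists only to make the joint
distribution non-degenerate; no reference quantity depends on it, and a
non-PSD user matrix is rejected with the eigenvalue-clipped nearest
valid matrix attached as a suggestion.

Outcome labels are Bernoulli draws from the reference equation with the
calibrated intercept (Brent root-finding on the strictly increasing
mean-probability map, tolerance 1e-12), using a label RNG stream
decoupled from the covariate stream. Everything is deterministic given
(config, seed), down to byte-identical cohort files.

**What the generator does not emulate.** Real fall cohorts have
measurement error, missingness, digit preference, within-battery
correlations far richer than the three-parameter default, and an
outcome process that no eight-variable logistic model fully captures.
Passing recovery tests therefore shows the *pipeline* is correct —
estimation, inversion and calibration are mutually consistent — not
that the model is adequate for any particular real population.

## Simulation sizes and tolerances in the test suite

Deterministic identities are asserted at tight tolerances (1e-12 for
AUC pair-counting, 1e-10 for inversion consistency, 1e-6 for score
equations and reference-implementation agreement). Stochastic checks
use seeded simulations sized for precision: coefficient recovery over
50 cohorts of n = 5000 (each published coefficient inside its 95% Wald
CI in ≥90% of seeds), Hosmer–Lemeshow null p-values over 200 cohorts of
n = 2000 (Kolmogorov distance to uniform < 0.1), DeLong coverage over
500 binormal cohorts of n = 500 (92–98%), and cross-validated vs
apparent AUC over 50 cohorts of n = 500 (negative optimism on average).
Marginal-recovery checks at n = 20,000 use a tolerance of 2% of the
anchor or three quantile sampling standard errors, whichever is larger
— the 75th total-activity percentile, for instance, has a quantile
slope near 371 MET per percentile, so a single cohort cannot resolve
2% there — plus half a unit for integer-rounded variables.

## Known limitations

* Five anchors cannot recover a 500-point empirical quantile function;
  boundary divergences listed above are inherent, not bugs.
* The published balance coefficient/OR pair (−0.053 / 0.949) is
  internally inconsistent at the third decimal (exp(−0.053) = 0.948);
  odds-ratio identity checks exclude it.
* The stratification assumes a monotone, sign-consistent model; it
  refuses interaction or non-monotone specifications by design.
* Cross-sectional outcome: the model predicts 12-month retrospective
  fall status, not prospective incidence, and carries that design's
  causality limits.
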