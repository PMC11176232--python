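# Methods

This note documents the statistical machinery of `qluc10d`: the models and
algorithms, the defaults and why they were chosen, what the synthetic data
do and do not emulate, and the numerical choices that affect results.

## The valuation model

The QLU-C10D describes a health state by ten dimensions (physical, role,
social and emotional functioning, fatigue, pain, sleep, appetite, nausea,
bowel problems), each on four ordinal levels (1 = no problems … 4 = very
much). A valuation task pairs two states, each with a survival duration
t ∈ {1, 2, 5, 10} years, and asks which the respondent would prefer to live
in until death.

Utility is parameterized to satisfy the QALY model:

U_isj = α·t_isj + β′X_isj·t_isj + ε_isj,

where X collects 30 level dummies (levels 2–4 per dimension, level 1 the
reference) and ε is i.i.d. Gumbel. Because every term interacts with
duration, utility tends to zero as duration tends to zero, which anchors
dead at 0; utility is linear in time (constant proportional trade-off).
The Gumbel errors make P(choose A) = exp(V_A)/(exp(V_A)+exp(V_B)): a paired
conditional logit on the covariate differences. Preference weights are the
ratios β/α, so the value set assigns utility 1 + Σ_d decrement(d, level_d),
with full health exactly 1 and states worse than dead permitted below 0.

State code strings concatenate the levels in the canonical dimension order
`physical, role, social, emotional, fatigue, pain, sleep, appetite, nausea,
bowel` — e.g. `2111121111` is a little impairment in physical functioning
and pain.

## Experimental design

The designed experiment holds 960 choice pairs, each constrained so that
exactly four of the ten dimensions differ between the states (the duration
attribute is free to differ or coincide — the overlap constraint concerns
quality-of-life dimensions only). Design quality is the D-error
det(I(θ₀))^(−1/K) of the per-set conditional-logit information
I = (1/S)·Σ_s p_s(1−p_s)(x_A−x_B)(x_A−x_B)′ evaluated at prior
coefficients θ₀; relative efficiency of design d versus reference r is
100·D-error(r)/D-error(d).

The search is a seeded hill climb: a random constrained design, then
repeated single-pair replacement proposals accepted when D-error falls.
Defaults: priors = the published Japanese unweighted Model 1 coefficients
(zero priors for non-standard attribute spaces), 300 iterations, up to 20
random restarts if the starting information matrix is singular. On
exhaustively enumerable toy spaces the search reaches within 5% of the
global optimum; at instrument scale it makes no optimality claim — the
published design's construction is external to this package, and design
optimality does not affect coefficient recovery, only precision per
respondent. Structurally degenerate requests (fewer sets than parameters)
return a design with infinite D-error rather than failing; evaluating such
a design raises an error naming the collinear parameters.

Per-respondent presentation randomizes three things, matching survey
practice: which 16 sets a respondent answers (uniform without replacement,
independent across respondents — no blocking), which alternative occupies
slot A (fair coin per set), and the personal dimension display order
(uniform permutation, duration always last). The split of physical
functioning into two walk items is presentation metadata only; design and
analysis treat it as one four-level dimension.

## Synthetic cohorts

The simulator is the package's test bed and default data source. Choices
follow exactly the random-utility model above: systematic utilities from a
`TrueModel` (default: the published Japanese unweighted Model 1
coefficients, α = 0.4986), plus independent Gumbel(0, 1) noise per
alternative. The unit noise scale matches the conditional-logit
normalization — the model identifies coefficients only up to the error
scale, so simulating at scale 1 makes the estimand equal the input
coefficients.

Demographics are drawn independently per variable from the valuation
sample's published composition (sex, age band, household income, education,
Kessler-6 band, and an EQ-5D band). No correlation structure is imposed:
the raking tests need known margins, not a realistic joint distribution.
The income, education and Kessler-6 sample/population margins come from the
published survey table (renormalized to sum to 1; the printed columns sum
to 99.3–100.0 due to rounding). The EQ-5D health-status variable is an
exception: the survey reported it only as visual-analogue-scale means by
age and sex, so the package uses a synthetic three-band categorical with
margins chosen to preserve the qualitative pattern (the online panel
slightly less healthy than the population). Raking defaults to the four
variables used in the published weighted analyses: income, education,
EQ-5D band, Kessler-6.

Two data-quality artifacts can be layered on:

* **Straightliners** — a seeded random ⌊rate·n⌋ subset of respondents has
  all choices overwritten with a constant slot (A or B by fair coin). This
  mirrors a sensitivity-exclusion design rather than modelling inattention.
  At the study's 2,435 completers a rate of 3% yields exactly 73 flagged
  respondents.
* **Completion times** — log-normal minutes centred on the study median
  (12.5), σ_log = 0.45, truncated by rejection to the observed range
  [3.75, 69.33]. Optionally, shorter times couple to larger Gumbel scales
  via scale_i = (median/t_i)^γ, which reproduces the qualitative
  speed-quality pattern: the fastest decile then shows the lowest
  pseudo-R² and the fewest significant coefficients.

What passing tests on these cohorts show: the estimation pipeline is
correct and well-calibrated *when the model is true*. What they do not
show: robustness to real response behavior (attribute non-attendance,
lexicographic rules, scale heterogeneity, panel conditioning), none of
which the simulator emulates.

## Estimation

The paired-logit log-likelihood Σ_i w_i Σ_s [V_chosen − log(e^{V_A}+e^{V_B})]
is concave; it is maximized by Newton–Raphson with analytic gradient and
Hessian, step-halving to guarantee ascent, starting at zero, converging
when the gradient max-norm falls below 1e-8 (usually 6–9 iterations at
study scale). Respondent weights enter as pseudo-likelihood multipliers on
each respondent's contribution and score. Failure modes are explicit:
perfectly predicted choices (complete separation, where the MLE is at
infinity and the gradient vanishes) raise a non-convergence error, and a
singular Hessian raises an error naming the collinear columns.

Standard errors: model-based (inverse observed information) and
respondent-clustered sandwich A⁻¹BA⁻¹, with B the sum of outer products of
respondent-summed scores scaled by the finite-cluster correction G/(G−1).
With singleton clusters this reduces to the heteroskedasticity-robust
estimator. The clustered covariance is the default for reporting,
coefficient stars (\*\*\*0.1%, \*\*1%, \*5%, two-sided Wald) and the
delta-method ratios.

Fit statistics follow the conventions that reproduce the published table
from its own log pseudo-likelihood: pseudo-R² = 1 − logL/(S·ln½) with S the
number of choice sets (weighted: the weight total), AIC = 2k − 2·logL, and
BIC = k·ln(N) − 2·logL with **N = the number of alternative rows** (two per
set; 77,920 at study scale). The alternative-rows convention is the only
one consistent with the published AIC/BIC pair (k = 31, logL = −23765 ⇒
AIC 47592, BIC 47879).

Respondents with fewer than the full 16 sets are retained by the estimator;
restricting to completers is a pipeline-level filter, mirroring the
published primary analysis (completers only) without hard-coding it.

## Preference weights and monotonicity repair

Decrements are d = β̂/α̂ with delta-method variance
Var(d) ≈ Var(β̂)/α̂² + β̂²Var(α̂)/α̂⁴ − 2β̂Cov(α̂,β̂)/α̂³ and normal 95%
intervals (±1.96·SE); a non-positive α̂ is an anchoring error since
life-years must carry positive utility. The delta SEs agree with a
parametric bootstrap from the fitted covariance to within a few percent at
study scale.

A monotonicity violation is a *strictly* less negative coefficient at a
worse adjacent level (ties are not violations — pooling equal levels
changes nothing); the level-1 reference counts, so a positive level-2
coefficient violates. Repair pools each dimension's first violating
adjacent pair into one shared-coefficient block and re-estimates,
repeating until monotone; it terminates because every merge removes a
parameter. Blocks are contiguous in level order. A caution from simulation:
when two true adjacent coefficients are exactly equal, the estimated
ordering inverts in about half of replicates — detecting a "violation" in
roughly 50–60% of runs is the expected behavior, not a defect, and the
pooled estimate then recovers the common value. An inversion of the size
seen in the published weighted sleep dimension (0.0094) is detected in
~85% of study-scale replicates.

The default value set is built from the *unweighted* unrestricted model,
matching the published choice (its coefficients were fully monotonic, and
weighting moved estimates little while inflating variance); weighted and
repaired variants are available through the same interfaces.

## Raking and variance inflation

Raking starts from unit weights and cyclically scales, for one variable at
a time, every respondent's weight by target-share/current-weighted-share of
their category, until the worst absolute margin error is below 1e-6 or 100
cycles elapse (both defaults are standard practice; the fixed point does
not depend on cycle order). Weights are renormalized to mean 1; no trimming
by default (a cap is available). An empty sample category with positive
target is a hard error naming the cell. Variance inflation is reported per
coefficient as (weighted SE − unweighted SE)/unweighted SE in percent,
rounded to integers for tables, with min/median/mean/max summaries.

## Data-quality diagnostics

Straightliner flags are respondents whose chosen slot is constant over all
their completed sets. The sensitivity refit re-estimates without them and
reports the maximum absolute and mean coefficient difference. The
time-decile analysis ranks respondents by completion time (ties broken by
respondent id, for determinism), splits them into ten groups differing in
size by at most one, fits the model per decile (unweighted by default) and
reports pseudo-R² and the count of coefficients significant at 5% on
clustered SEs; a failed decile fit is reported in its row rather than
aborting.

## Determinism and problem sizes

Every stochastic stage takes a seed; compound stages spawn per-stage
sub-seeds from one master seed via `numpy.random.SeedSequence`, so a
configuration maps to byte-identical numeric outputs. The test suite runs
study-scale replications (2,435 × 16 on a 960-set design) where the check
is about calibration — parameter recovery, interval coverage, merge
detection — and small enumerable instances (two binary dimensions, two
durations) where an exhaustive or brute-force oracle exists; hill-climb
iteration counts default to 300 at instrument scale, which suffices because
downstream estimates depend on the design only through the overlap
structure and level balance, not on squeezing the last percent of
D-efficiency.

## Known limitations

* The exact published 960-set design is not reconstructable from public
  information; the package builds designs with the same constraints but
  makes no claim of matching the published 90.4% relative efficiency.
* The QLQ-C30 item-to-dimension derivation table is distributed with the
  instrument's supplementary materials, not reproduced here; the default
  `QLQC30Mapping` is a synthetic stand-in with the correct structure
  (13 distinct items; two walk items feeding physical functioning; worst
  response carries) and must be replaced for production scoring.
* The EQ-5D raking margins are synthetic (see above).
* No mixed logit, latent-class or scale-heterogeneity models; no Bayesian
  design criteria; no replicate-weight variance estimators.
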