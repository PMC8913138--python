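# Methods

## The model

A child's PICU-mortality risk is elicited from staff as a trapezoidal fuzzy
set: a short range `[short_lo, short_hi]` (membership 1) nested in a long
range `[long_lo, long_hi]` (support), both percentages. The trapezoid is
equivalent to the four indexes `MID`, `SPR`, `SPRL`, `SPRR` (midpoint and
radius of the short range; left/right spreads of the long range beyond it),
and `parameterize`/`to_trapezoid` are exact inverses. A patient's repeated
evaluations are averaged componentwise, which equals the pointwise
(Minkowski) mean of the trapezoids; because the index constraint set
(`0 ≤ MID−SPR−SPRL`, `MID+SPR+SPRR ≤ 100`, spreads ≥ 0) is convex, the
average of valid evaluations is always valid.

Mortality is modelled as `logit P(death) = β0 + βᵀx` with x drawn from
{MID, SPR, SPRL, SPRR, PIM2, TISS28} on their natural scales (risk
percentages and raw score). Fitting is by IRLS (Newton) with step-halving;
convergence is declared when the relative log-likelihood change falls below
1e-10 (at most 100 iterations, both configurable). Standard errors come
from the inverse observed information at the optimum. Quasi-complete
separation is *flagged*, not penalized: when any fitted linear predictor
exceeds 30 in magnitude (a fitted probability numerically 0 or 1) the fit
carries `separation_flag=True`. No Firth or ridge correction is applied;
with overlapping classes, as here, the flag is diagnostic only. A fit that
stops at the iteration cap is returned with `converged=False` and a logged
warning rather than raising, so large cross-validation loops never abort.

Inference uses the single-coefficient Wald chi-square test and the
likelihood-ratio test (LRT) for nested models, `2(ℓ_full − ℓ_nested) ~
χ²(Δp)`. The selection ladder mirrors the study procedure: univariate Wald
screens (α = 0.05) within the subjective group and the objective group;
LRTs of each significant variable against NULL; within a group, starting
from the single model with the smallest LRT-vs-NULL p, another significant
variable is retained only when the enlarged-vs-current LRT p < α (ties
broken by smaller LRT-vs-NULL p, then fewer predictors — the real data
never tied); finally the hybrid (best-subjective + best-objective) is kept
only when it improves on *both* components.

## Cross-validation at a preset sensitivity

With ~4% mortality, raw accuracy is uninformative, so models are compared
at a fixed mortality-class operating point. For each of B replications a
stratified K-fold partition is drawn (per-class counts differ by ≤ 1 across
folds; every fold gets ≥ `min_deaths_per_fold` deaths, default 2, which at
24 deaths and K=4 forces exactly 6 per fold). In each fold the model is
refit on the K−1 training folds; the threshold is the largest training
nonsurvivor risk t with `fraction(risks ≥ t) ≥ preset` (default 0.70;
classification rule: predict death iff risk ≥ t, ties predict death);
confusion counts are pooled over the K folds of a replication and the
per-class accuracies are averaged over replications (every patient counts
once per replication). Replications whose training split would lose an
outcome class are redrawn and counted (impossible under the default
stratification; the counter is reported regardless). One master seed spawns
an independent substream per replication, so results do not depend on
evaluation order, and model comparisons share the partitions within each
replication (paired design).

Calibrating on the training split keeps the test folds untouched; the
achieved test sensitivity therefore varies around the preset rather than
hitting it exactly. Two small systematic terms are worth knowing. First,
discreteness: with m training deaths the threshold is the
`ceil(preset·m)`-th largest of m order statistics, so the expected
out-of-sample sensitivity is `ceil(preset·m)/(m+1)` — at the study scale
(m=18) that is 13/19 ≈ 68.4%, which is why cross-validated nonsurvivor
accuracies sit a point or two below 70%. Second, optimism: the training
risks are in-sample-optimized, which inflates the threshold by an
O(1/√deaths) amount; at 24 deaths this adds roughly one further point of
survivor specificity and costs the same in sensitivity. Both effects vanish
as the death count grows; the package reports what the procedure actually
achieves. An alternative calibration on pooled out-of-fold predictions is
available (`CvConfig(pooled_calibration=True)`) for sensitivity analysis.

## The synthetic-data generator

The generator emulates the published two-center cohort so the pipeline can
run without the original bedside data. Per center it fixes the exact
patient and death counts (308/15 Oviedo, 291/9 Riga; outcomes assigned by
permutation), then draws MID, PIM2 and TISS28 per outcome class from normal
distributions truncated to their valid ranges ([0,100] for the risk
percentages, [0,∞) for TISS28) with the published class-conditional
means/SDs as the *pre-truncation* location/scale. Within a class, MID and
PIM2 share a Gaussian-copula correlation (default 0.3, reflecting that the
hybrid model outperforms both components, hence partial complementarity);
TISS28 is independent. Each patient receives an evaluation count drawn from
the published per-center frequency table and that many trapezoids: the
evaluation midpoint is the latent MID plus N(0, 5) jitter clipped to
[0,100], and SPR/SPRL/SPRR are half-normal with scales 5/5/10 (long ranges
skew upward for risk), shrunk — never moving MID — until the trapezoid fits
in [0,100]. A `logistic_truth` mode instead draws covariates from the
survivor-weighted mixture and outcomes from a logistic model with known
coefficients (default intercept −4.6, MID 0.045, PIM2 0.07, giving a ~5%
event rate), recorded in a truth sidecar for parameter-recovery tests.

What the generator does *not* reproduce: the real class-conditional
distributions are strongly right-skewed (SDs exceed means for PIM2), and
using the published mean/SD as pre-truncation parameters shifts the
realized moments — e.g. the survivor MID mean rises from 7.6 to ~13 after
truncation at 0. This is a deliberate transparency choice; a
moment-matched option (`CenterProfile(moment_match=True)`) solves for
pre-truncation parameters whose truncated moments equal the published
values. Consequently the published headline survivor accuracies are not
numeric targets for synthetic cohorts: the synthetic classes are cleaner
than real ones and survivor accuracies run higher. The preset mortality
accuracy (~70%) *is* reproduced, because it is calibrated by construction.
Published frequency tables contain two internal inconsistencies that the
generator does not resolve: the Latvia evaluation-count row sums to 293
patients against a cohort of 291 (the frequency vector is normalized by the
row total), and the overall-column PIM2 survivor/nonsurvivor summary values
are interchanged relative to the center columns (only center-level values
are used).

## Numerical and design choices

- Significance level α = 0.05 throughout; SDs use the n−1 denominator.
- Raters are unweighted in the per-patient average regardless of role, and
  the average runs over all evaluations (the evaluation, not the rater, is
  the unit); roles are retained in the data for future weighting.
- Non-nested input ranges are rejected by default; an opt-in repair mode
  expands the long range to the convex hull of both ranges with a logged
  warning (the bedside tool enforced nesting; files may not).
- The elicitation time window is a data-collection constraint, not enforced
  computationally; an optional ISO-8601 timestamp column is validated only
  when present.
- Records missing a used covariate are dropped per model (complete-case)
  with logged counts; LRTs refuse fits with differing case counts.
- Index invariants are checked with a 1e-9 tolerance; threshold ties
  predict death; the `parameterize`/`to_trapezoid` round trip is exact on
  dyadic-rational inputs.
- Validation tests run at reduced problem sizes chosen so Monte-Carlo error
  is well inside each assertion band (B=200 replications for calibration
  and complementarity checks, 500 replications of n=5000 for Wald-interval
  coverage, 25 cohort draws at a 25% event rate for the exchangeability
  limit, where the O(1/deaths) discreteness and calibration-optimism terms
  are second order).

## Limitations

- Separation is reported, not corrected; coefficient estimates under
  flagged separation should not be interpreted, though the preset-threshold
  classification remains well defined because only risk *ranks* matter.
- The generator's truncated-normal families and the single copula
  parameter are assumptions, not estimates; conclusions about real-data
  accuracy levels cannot be drawn from synthetic cohorts (orderings and
  calibration properties transfer, levels do not).
- No ROC/AUC or recalibration analysis is included; the operating point is
  fixed by the preset-sensitivity design.
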