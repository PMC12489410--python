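# Methods

This package implements, end to end, the computation and statistics of a
two-method dietary-intake validation study: prospective image-voice food
records (the test method) compared against interviewer-administered
multiple-pass 24-hour recalls (the reference method), across three
recording periods per participant — test method (week 1), recalls
(weeks 2–3), test method again (week 4) — in mother–child households
where shared-plate eating is common.  Since no raw field data from such
studies are redistributable, a first-class synthetic-data generator
reproduces the study's design and known ground truth, and every
downstream stage is validated against it.

## Nutrient computation

**Units.** All per-100 g profiles and intakes use grams of edible
portion; energy in kcal; macronutrients in g; micronutrients in mg or µg
as configured.  The nutrient panel is run configuration: the default
adult panel has 20 nutrients (including alcohol), the child panel the
same 19 without alcohol.

**Analyst reconciliation.** Portion amounts estimated from images carry
two independent blinded analyst estimates.  If the estimates agree
within 25% relative difference they are combined; beyond 25% a third
(reviewing) analyst's value decides; beyond 25% with no third estimate
the amount is unresolved and falls through to imputation.  Two choices
the procedure leaves open are fixed here: in-tolerance estimates are
combined by their arithmetic mean, and the relative difference is
normalized by the mean of the two estimates.

**Imputation hierarchy.** Unresolved portions are imputed as (1) the
median of the same participant's (or the same shared-serving context's)
resolved portions of the same item, else (2) the median over all
resolved portions of that item from the same participant type (mother or
child), else (3) a reference-portion default.  Medians use only directly
resolved portions, never previously imputed ones, so imputation cannot
feed back on itself.  The level that fired is logged per serving.

**Recipes.** A home recipe's per-100 g profile is the
retention-adjusted ingredient sum: for each nutrient,
Σ (grams/100 × per-100 g value × retention factor for the cooking
method), divided by the per-100 g basis.  The basis is the measured
final prepared weight when recorded; otherwise the raw ingredient mass
sum (no yield factors are applied).  Retention lookup is total: an
unknown (nutrient, method) pair means no loss (factor 1.0); factors are
validated into [0, 1] at load time.  Recipe profiles are computed once
and reused across all of the household's eating occasions.

**Leftovers and shared plates.** Consumed amount is served minus
leftover (zero when a serving was refused; full amount when eaten
completely); leftovers of shared servings are subtracted from the shared
total before apportioning, because attributing a leftover to an
individual is impossible under even-split semantics.  A shared serving's
consumed total is divided evenly over the total number of eaters —
participants and non-participants, adults and children all counting as
one share — and only the shares of study participants are retained.  A
serving shared by one participating adult and two non-participating
adults therefore assigns exactly one third to the participant.

**Observation unit.** Daily intakes are summed per participant-day;
period intakes are arithmetic means over the period's recorded (2–3)
days.  The dropped training/test recording day carries a `training` flag
(reserved day index 0) and never enters any computation.

**Inclusion rule.** A participant enters the analysis with at least 2 of
the 3 recording periods having 2 or 3 recorded days of food/beverage
intake; children additionally need any intake data at all.  A "day with
data" for participant *p* is any non-training household day containing a
consumed serving whose eater roster includes *p*: the household scope
matters because a child's intake may be recorded entirely through shared
servings on the mother's day records.

## Statistical model

For each nutrient and role separately, the long dataset has one row per
included participant and period (the period mean).  The model is

y_ij = μ_period(j) + a_i + b_ij + e_ij,  a_i ~ N(0, σ²_p),
b_ij ~ N(0, σ²_pp),  e_ij ~ N(0, σ²_e / w_ij)

with a fixed recording-period effect and two random intercepts: one per
participant and one per period nested within participant.  Estimation is
REML (the conventional default for variance components).  Because the
covariance is block diagonal by participant with rank-one participant
and cell updates, the likelihood is evaluated in closed form via nested
Sherman–Morrison identities over grouped sums; only the 3×3 fixed-effect
cross-product is ever factored.  The three variance parameters are
optimized by L-BFGS-B from two starting points, on data standardized to
unit variance, with box constraints at zero.

**Bland–Altman screen.** Before modelling, per method pair: bias (mean
difference), 95% limits of agreement (bias ± 1.96 SD of differences) and
the Spearman correlation of differences against pair means, which
screens for a trend in the bias.  The screen is reported, never used to
gate the mixed-model path.

**Heteroscedasticity weighting.** Residual spread grows with intake, so
the residual SD is modelled as a function of the predicted value:
ordinary least squares of |residual| on the prediction (linear, or cubic
in the second iteration), floored at the larger of the 10th percentile
of |residuals| and a tiny scale-relative constant so weights
w = 1/SD² stay finite.  Four candidates are fitted: M0 unweighted; M1
weighted by a linear SD function of M0's residuals; M2/M3 weighted by
linear/cubic SD functions of M1's residuals.  "Predicted value" here is
the fixed effect plus the participant intercept BLUP — with one row per
(participant, period) cell the nested intercept's BLUP would absorb
nearly the whole residual, leaving nothing to regress; including only
the participant level retains the between-person intake differences
that drive the heteroscedasticity.

**Model selection.** Visual inspection of standardized-residual plots
is operationalized as a trend statistic: |Spearman ρ| between
|standardized residual| (residual over its conditional SD) and the
predicted value.  Among converged candidates the smallest statistic
wins; exact ties and non-improvements go to the earlier candidate (fewer
weighting iterations, lower polynomial order), and if every weighted fit
fails the unweighted model is reported, flagged as such.

**Effects.** Reported effect sizes are the three pairwise differences of
the selected model's marginal period means with Wald 95% CIs from the
fixed-effect covariance, plus a single omnibus Wald chi-square p-value
(2 df) for the period effect, evaluated against a normal/chi-square
reference.  A degrees-of-freedom refinement (e.g. Kenward–Roger) is a
noted extension point; at the default study sizes (~110–150 participants)
the normal reference is adequate, and calibration simulations in the
test suite put the observed CI coverage at roughly 92–97% per pair
(nominal 95%) and the omnibus type-I error near 5%.

**Numerical notes.** Weights are normalized by their geometric mean and
canonicalized to 9 significant digits before fitting, which makes
results exactly invariant to rescaling all weights by a constant (the
residual scale absorbs the normalization).  With exactly one row per
(participant, period) cell and constant weights, σ²_pp and σ²_e are
identified only through their sum; the REML surface is flat along that
ridge, fixed effects and their covariance are unaffected, and the
reported split between the two components is the optimizer's point on
the ridge.  Degenerate inputs (constant values, a constant-prediction SD
regression, fewer than 3 Bland–Altman pairs) return flagged results
rather than raising, and one nutrient's failure never aborts the others.

## Synthetic data

The generator's defaults are the study's conditions: 148 households
(one mother, one child each) across rural/semirural/urban sites in equal
expected proportion; 27.7% household withdrawal (withdrawn households
retain only the first period); 3 recording days per period, one flagged
as the weekend day; an occasional training day that the engine must
drop.  True energy period means default to (1406, 1712, 1424) kcal for
mothers and (617, 793, 646) kcal for children — the recall period higher
than both image-voice periods, a systematic between-method bias on the
order of −300 kcal (mothers) and −150 kcal (children).  Variance
components default to σ_p = 550 and σ_pp = 250 kcal with residual
SD(pred) = 100 + 0.1·pred, chosen so the marginal per-period SD is
around 620 kcal, the order observed in adult energy intakes; a cubic
SD option exists to exercise the second weighting iteration.  All draws
flow from a single seeded generator, so output is byte-identical for a
given seed; negative simulated intakes are truncated at zero and
counted, with a warning if the rate exceeds 1% (it is far below that at
the defaults).

`generate_records` converts model draws into servings against a small
illustrative food-composition table: each participant-day's energy
target is partitioned over 2–3 servings; servings become shared plates
(mother-recorded, child and 1–3 bystanders on the roster), household
recipe dishes, partially eaten or refused servings, and analyst-estimate
sets (both the in-tolerance mean path and the >25% third-analyst path)
at configurable rates.  True intakes are accumulated analytically during
generation with the same leftover, reconciliation and even-split
arithmetic the engine applies, so the engine must reproduce them to
float precision — the end-to-end correctness oracle.  About 5% of
servings are refused, so realized period means sit at ≈0.95 of the
configured targets with between-method differences preserved at the
same factor.  The unresolved-portion imputation path is not exercised
by the generator (embedding its truth would require duplicating the
median hierarchy); it is covered by dedicated unit tests instead.

**What the simulation does not emulate** — and hence what passing tests
do not establish about real data: food-frequency/menu realism and
seasonality, misreporting and memory biases of either method, breastmilk
intake (excluded from child intakes, as no quantification method exists
in this pipeline), correlated mother–child day-to-day intake beyond the
shared-plate mechanism, and measurement error in the food-composition
values themselves.  The statistics are validated for calibration under a
correctly specified generating model, not for robustness to these
real-world departures.

## Problem sizes used in checks

Calibration suites use 150 participants with σ_p = 100, σ_pp = 50 kcal
and SD(pred) = 50 + 0.1·pred: CI coverage over 200 replicates, type-I
error over 500 null replicates, selection behaviour over 100 replicates
under SD(pred) = 10 + 0.3·pred.  Engine-vs-truth runs at 30 households;
the full worked pipeline at the 148-household study scale.
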