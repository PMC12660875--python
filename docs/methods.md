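# Methods

## Model

The fitted object is always one additive linear equation estimated by
ordinary least squares. What the search chooses is, for every numeric
predictor, one of four representations:

| representation  | design columns                              | parameters |
|-----------------|---------------------------------------------|------------|
| excluded        | —                                           | 0          |
| linear          | `x`                                         | 1          |
| single split    | `I(x > c)`                                  | 1          |
| double split    | `I(c1 < x ≤ c2)`, `I(x > c2)`               | 2          |

Single splits are coded `I(x > c)` (strict), so segments are left-closed at
the cutpoint. In the double split the lowest segment is the reference
category, matching ordinary treatment coding. Categorical predictors enter
through reference coding of their sorted levels and are never
threshold-transformed. Double-split columns move atomically: stepwise moves
and transformation proposals add or drop both indicators together.

Model comparison uses AIC or BIC computed from the full Gaussian
log-likelihood at the MLE of the error variance, with the variance counted
as a free parameter (`df = k + 1`). R's `extractAIC` drops an additive
constant; criterion *differences* — the only thing the search consumes —
are identical under either convention, and the RSS-convention value is
reported alongside for auditability. Rank-deficient candidate designs are
rejected outright rather than aliased, keeping the search deterministic and
auditable. A zero-residual fit is ordered below every finite criterion
value and raises a warning, so it can never be selected silently.

## Threshold proposal trees

Candidate cutpoints come from a depth-≤2 regression tree of the working
target (the response in univariate mode, partial residuals in iterative
mode) on one predictor:

- candidate thresholds are midpoints between consecutive distinct sorted
  values (the CART convention — this is what makes thresholds like
  "101.55" exactly reproducible);
- each split minimises the summed within-child SSE; ties go to the
  smallest cutpoint, so the procedure is platform-independent;
- a split is pruned when its SSE reduction is below `cp` times the
  root-node SSE (`cp = 0.01` by default, the conventional tree default);
- every leaf must keep at least `ceil(min_support · n)` observations,
  with `n` the full sample size at every node, so min_support bounds the
  segments of any encoding that can ever be accepted;
- the single-split candidate is the root cutpoint; the double-split
  candidate pairs the root with the child split of larger SSE gain.

Because thresholds are optimised over ~n candidate positions, a "best"
split exists even for pure noise, and its apparent criterion improvement
regularly clears any fixed margin. The proposal step therefore also prunes
by 10-fold cross-validation: each fold re-grows the tree on the training
part and predicts the held fold with its own thresholds and segment means,
and a structure (1 or 2 cutpoints) is offered only when its CV risk beats
the fold-mean model's. The fold assignment derives from one fixed internal
seed, keeping the whole pipeline bit-for-bit deterministic. We use the
minimum-risk rule rather than the one-standard-error rule deliberately:
the information criterion and the `min_improvement` margin already
penalise complexity downstream, and in experiments the one-SE band also
suppressed genuine weak structure (the shallow U-shaped signal below)
that the criterion should be allowed to judge. Setting `cv_folds = 0`
disables the gate and recovers the plain cp-pruned tree.

## Search modes

**Univariate.** Each predictor is scored independently against the
response under the null, linear, single-split and double-split
single-predictor models. A split form competes only if it beats the linear
form by at least `min_improvement` criterion points; a predictor whose
best form is the null model is excluded; ties go to the simpler form. A
global stepwise selection (configured direction) over the transformed
candidate set then builds the final model.

**Iterative.** The search starts from an intercept-only model (forward) or
the full linear model (backward/both) and alternates: (a) a classic
stepwise pass in which any strict criterion improvement is accepted; (b) a
transformation pass over numeric predictors not currently dummy-encoded in
the model, in fixed input-column order, where a tree grown on the
predictor's partial residuals (residuals plus the predictor's own fitted
contribution) proposes encodings, the model is refit with the predictor's
linear term replaced by the encoding, and the best proposal is accepted
only when it lowers the criterion by at least `min_improvement`. The loop
ends when a full pass changes nothing (or after `max_iterations = 20`,
with a recorded warning); a final global stepwise selection over the
transformed candidate set produces the model. If that greedy restart ends
above the incumbent's criterion the incumbent is kept (recorded in the
trace), so the final criterion never exceeds the plain-stepwise solution's.

`min_improvement` gates *transformations only*; plain additions and
removals of untransformed terms follow classic stepwise (any strict
improvement). Stepwise ties prefer removals over additions, then the
lexicographically smaller term name — a bias toward sparsity that also
fixes the trajectory completely.

## Parameters

| parameter        | default | meaning                                                        |
|------------------|---------|----------------------------------------------------------------|
| `mode`           | iterative | transformation search (see above)                            |
| `direction`      | both    | stepwise move set and starting model                           |
| `criterion`      | AIC     | selection objective (AIC or BIC)                               |
| `min_support`    | 0.2     | minimum fraction of observations per induced segment           |
| `min_improvement`| 3.0     | criterion points a transformation must gain to be accepted; 5 is used in the synthetic study, 3 for small real tables |
| `cp`             | 0.01    | relative SSE gain below which a tree split is pruned           |
| `cv_folds`       | 10      | folds of the cross-validation pruning gate (0 disables)        |
| `max_iterations` | 20      | cap on iterative loop passes                                   |

## Synthetic benchmark

The generator draws `n = 500` observations of `p = 20` i.i.d. standard
normal predictors and builds

    y = β1·X1 + β2·I(X2 > 0.2) + β3·[−8(X3* − 0.5)² + 2] + ε,

where `X3*` is X3 min-max rescaled to [0, 1] within the realised sample
(so the quadratic term spans [0, 2] with its peak at the sample midpoint)
and all non-zero coefficients are 1. Four scenarios toggle `(β2, β3)`:
linear (0,0), step (1,0), U-shaped (0,1), complete (1,1). The noise
variance is calibrated per realised draw, `σ² = Var(signal)/SNR` with the
sample variance (ddof = 1) and `SNR = 5`, making the signal-to-noise ratio
exact for every dataset rather than only in expectation. The rescaling of
X3 uses the full dataset's min/max before the train/test split.

The benchmark protocol regenerates a fresh dataset per replication (seed =
master seed + replication index, kept below 2³¹), splits 70/30, fits every
method adapter on the training part, and records test RMSE and MAE, the
number of selected source predictors, and the Matthews correlation of the
selection against the known truth set, where a predictor counts as
selected when any encoding of it appears in the final model. Summaries are
medians and standard deviations; all methods see identical replications,
so comparisons are paired. The transformation mode per scenario is chosen
once by training-set RMSE on a preliminary draw and then fixed (ties go to
the cheaper univariate mode); applied to the four scenarios this selects
univariate for linear/U-shaped and iterative for step/complete. The study
and `scripts/acceptance.py` use 100 replications per scenario, which runs
in a few minutes on one CPU while holding the median's sampling error well
below the reporting precision.

What the generator deliberately does not emulate: correlated predictors,
heavy-tailed or heteroscedastic noise, categorical predictors, and
threshold effects that interact. Passing benchmarks therefore demonstrate
threshold detection and selection behaviour under clean, independent
Gaussian designs, not robustness to real-data pathologies.

## Numerical and degenerate-input conventions

- OLS via `numpy.linalg.lstsq`; candidates whose design loses full column
  rank are rejected (`DegenerateDesignError`), e.g. a dummy duplicating an
  existing column.
- A perfect fit (rss ≤ ~1e−12 · ‖y‖²) yields a −∞ criterion sentinel plus
  a `PerfectFitWarning`, avoiding `log(0)`.
- Threshold encodings whose indicator is constant, or with an empty
  segment, raise `DegenerateEncodingError`; proposal candidates that do so
  are skipped.
- Prediction applies stored cutpoints and categorical levels as-is; rows
  outside the training range encode deterministically (an indicator is
  simply 0 or 1), and no threshold is ever re-estimated at prediction
  time.
- A constant signal calibrates to zero noise variance with a warning.

## Known limitations

- Greedy search: no optimality guarantee; the trace records every
  considered transformation for audit.
- Post-selection inference is not addressed; reported p-values are the
  usual OLS values conditional on the selected model and should be read
  accordingly.
- At most two cutpoints per predictor; no interactions between dummies;
  no GLM families or weighted least squares.
- On very small samples (tens of rows) the cross-validation gate becomes
  noisy; results remain deterministic but individual fold assignments can
  matter.
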