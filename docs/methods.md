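# Methods

## The problem

Predicting a drug's effect on a cancer cell line from its genomic profile
is a sparse ultrahigh-dimensional regression: a panel contributes tens of
thousands of features (gene expression, mutation status, copy-number
status) per cell line but only a few hundred cell lines per drug.  The
phenotype is the *activity area*, the area under the 8-point
dose-response curve, consumed here as given (no curve fitting).  The
working assumption is a linear model

    y_i = beta_0 + sum_j beta_j x_ij + eps_i

in which only a handful of coefficients are nonzero.

A one-shot marginal screen (rank all features by |Pearson r| with the
response, keep the top k — *sure independence screening*, SIS) is the
standard way to make p tractable, but it has two failure modes this
package targets:

1. **marginally weak, jointly strong features.**  A predictor whose
   effect is masked by the other predictors can have essentially zero
   marginal correlation with the response; any screen with an |r| cutoff
   discards it.
2. **redundant marginally strong features.**  Mutually correlated
   proxies of one true predictor all rank high and crowd the list
   without adding joint information.

## The iterative scheme

With target model size `d` (selected by cross-validation, capped at 40):

1. **First screen.**  Recruit the top `k1 = max(1, floor(2d/3))`
   features by |Pearson r| with `y` (set A1).  Taking fewer than `d`
   up front guarantees room for at least one residual round.
2. **Select.**  Lasso on the recruited candidates against `y`, penalty
   chosen by inner cross-validation; the nonzero-coefficient set is M1.
3. **Iterate (s >= 2).**  Fit OLS on M_{s-1}, take residuals `r`, and
   recruit the top `d - |M_{s-1}|` features from outside M_{s-1} by
   |Pearson r| with `r`.  Lasso on the union M_{s-1} ∪ A_s against the
   *original* `y` gives M_s.  Because OLS residuals are exactly
   orthogonal to the fitted columns, recruitment is scored on signal the
   current model does not already explain: proxies of current members
   lose their priority, and masked predictors surface.
4. **Stop** when |M_s| = d, when the size stalls (|M_s| = |M_{s-1}|),
   when the set repeats exactly, when M_s is empty, or after 50
   iterations; the trace records which rule fired.  The size-stall rule
   compares sizes only and could in principle oscillate between
   different same-size sets, hence the additional set-equality guard.
5. **Refit.**  The final coefficients come from OLS on M_s — the lasso
   is a good selector but a biased estimator.  If a round at s >= 2
   empties the active set, the previous (non-empty) set is kept as the
   final model; an empty first round yields the intercept-only model.

Ties in screening break toward the lower feature index; all randomness
(fold partitions, inner CV) derives from one integer seed, so a run is
bit-reproducible.

## Lasso conventions

The objective is `sum_i (y_i - b0 - x_i.b)^2 + lambda * sum_j |b_j|`
with the intercept unpenalised and **no 1/(2n) factor**, so lambda values
are comparable across implementations of the printed formula.  Columns
are standardised to zero mean and unit population (ddof=0) variance
before penalisation — a raw-scale penalty would weight binary mutation
columns and continuous expression columns incoherently — and
coefficients are reported on the original scale.  The solver is
scikit-learn coordinate descent (its objective is ours divided by 2n,
i.e. `alpha = lambda / (2n)` exactly).

`select_lambda` evaluates 100 log-spaced values spanning three decades
below `lambda_max = 2 max_j |x_j.(y - ybar)|` with seeded 10-fold CV and
takes the **minimum-MSE** value (no 1-SE rule); exact ties resolve to the
larger, sparser lambda.  Columns are standardised once on the full
candidate matrix before the inner CV (glmnet-style); only the scaling,
not any fit, crosses fold boundaries.  A fresh penalty is selected at
every iteration of the loop, since each iteration's candidate set is a
new regression problem.

The minimum-MSE rule is deliberately prediction-oriented and only mildly
conservative under the null: on pure-noise responses it keeps a nonzero
handful of spurious coefficients in a substantial minority of runs
(roughly 20-30 % of seeds exceed 2 active features in our simulations).
A 1-SE rule would be sparser but is not what "smallest prediction error
by cross validation" describes.  Downstream, the OLS t-tests — not the
lasso — arbitrate which selected coefficients are credible.

## Cross-validation protocol

Performance for a given `d` is measured by 10 repeats of 10-fold CV:
every repeat partitions samples uniformly at random (repeat r uses seed
`seed + r`); the entire pipeline — screening, penalty selection, OLS —
runs inside each training fold; each sample's out-of-fold predictions
are averaged over repeats, and the Pearson correlation of those averages
with the observed responses is the score.  `d` is chosen from
{2, 4, ..., 40} by maximising that score, ties to the smaller `d`, and
the final model is then refit on all data at the chosen `d`.  Selecting
`d` on the same CV curve that is later reported is mildly optimistic;
a nested CV would remove this but is out of scope, and the optimism
applies equally to all methods compared.

A fold whose training responses are constant is skipped with a warning
(its samples get no prediction that repeat); this can only occur with
degenerate response vectors.

## Baselines

* **STF (simple top features):** the top-m features by |marginal r|
  with an OLS refit, m always matched to the iterative method's realised
  model size.  Shares every component except the iteration, so the
  contrast isolates the recruitment mechanism.
* **ENR:** discard features with |r| < 0.1, then elastic net with mixing
  parameter in {0.1, ..., 1.0} and a 50-point penalty path, both by
  seeded 10-fold CV.  This is an approximate re-implementation of the
  screen-then-elastic-net pipeline used in large panel analyses; the
  original's hyperparameters are unpublished.  Its reported coefficients
  are the elastic net's own (no OLS refit).

## Inference on the selected model

Each refit coefficient gets `t_j = beta_j / SE_j` with `n - |M| - 1`
degrees of freedom and a two-sided p-value; the test is algebraically
identical to the df-1 F-test of the nested model without x_j (asserted
to 1e-10 in the tests).  Significance is declared at alpha = 0.01 with
no multiple-testing correction across the (at most 40) coefficients —
a deliberate convention, documented rather than corrected.  A feature is
*marginally weak* when its full-data |Pearson r| with the response is
below 0.1; weak-and-significant features are the class the method exists
to surface.  Marginal correlations are computed on the full assembled
data, not per fold.  Exact fits (RSS at rounding level) are flagged and
reported with p = 0 rather than feeding meaningless SEs into the t
distribution.

**Redundancy.**  The mean redundancy score (MRS) of a selected set is
the mean pairwise similarity over unordered feature pairs: |Pearson r|
(range [0,1]) or mutual information in nats.  The MI estimator bins each
variable into 10 equal-width bins (binary features keep their natural
two) and computes plug-in MI from the joint histogram — simple,
deterministic, and adequate for a comparative score; it is biased
upward at small n like all plug-in estimators.  A single-feature set
scores 0 by convention; constant columns contribute 0 to their pairs and
are flagged.  Method-vs-method redundancy and CV-correlation contrasts
use a paired t-test across datasets/drugs.

## The synthetic generator

Real expression/CNV panel matrices are not redistributable, so the
generator emulates the statistical structure the method assumes, at
configurable scale:

* **blocks:** p splits into expression / mutation / copy-number blocks
  at the proportions of a large cell-line panel (20069 : 1667 : 21217 by
  default).  Expression features come in equicorrelated sub-blocks of
  width 50 (pairwise correlation `rho`, default 0.5), emulating
  co-expression modules; mutation features are Bernoulli(0.1);
  copy-number features are independent standard Gaussians.
* **signal:** `s_strong` strong predictors (default 3, coefficient 1)
  head distinct expression sub-blocks, so they are exactly N(0,1) and
  mutually independent for any `rho`, while each drags rho-correlated
  neighbours up the marginal ranking — the redundancy a top-k list
  falls for.
* **the weak feature:** `x_w = sum(strong) + eta`, `eta ~ N(0,1)`, with
  coefficient `beta_w = -cov(x_w, sum(strong)) / var(x_w) = -s/(s+1)`.
  This makes `cov(x_w, y)` exactly zero in population (the direct effect
  cancels the indirect one) while the partial coefficient is large
  (-0.75 at s = 3).  Its empirical |r| therefore shrinks as 1/sqrt(n).
* **noise:** `eps ~ N(0, sigma^2)`; `sigma_for_r2` inverts the
  closed-form signal variance `s/(s+1)` to hit a target population R^2
  (0.8 gives sigma ≈ 0.433 at s = 3).

Defaults (n = 400, p = 1000, s = 3, rho = 0.5, R^2 ≈ 0.8) are the study
conditions used throughout the tests.  What the generator does **not**
emulate: heavy-tailed and skewed expression distributions, batch
effects, missing values, mutation co-occurrence structure, arm-level CNV
correlation, and lineage effects — so passing tests demonstrate the
selection mechanics under the model's assumptions, not robustness to
real-panel artefacts.

## Numerical and engineering choices

* Pearson correlations of constant columns are defined as 0 (an all-zero
  mutation column inside a CV fold must never rank or crash).
* OLS uses pivoted QR for rank detection and names a collinear column
  pair on failure; SEs come from `sigma_hat^2 (X'X)^{-1}`.
* Lasso convergence tolerance 1e-10 (dual-gap based), iteration cap
  2e5; non-convergence raises with diagnostics rather than returning a
  silently inaccurate fit.
* File round-trips are bit-exact (`float_precision="round_trip"` on
  read; full-precision repr on write).
* Problem sizes in the test suite and acceptance script (e.g. 50
  generator seeds at n = 400 / p = 1000 for recovery rates; 20 seeds at
  n = 200 / p = 500 with 2 CV repeats for null calibration; 3 CV repeats
  for the strong-signal check) were chosen to make the Monte-Carlo error
  comfortably smaller than the effects being asserted while keeping the
  default run quick on one CPU.

## Known limitations

* The recruitment count `d - |M|` at iterations beyond the second
  generalises the rule stated for the second round; other choices
  (fixed k per round) are conceivable.
* With strongly correlated sub-blocks a true predictor is occasionally
  shadowed by a neighbour; the weak feature is still recovered because
  recruitment operates on residuals, but exact support recovery of the
  strong set is not guaranteed at high rho.
* `d`-selection optimism (see above); no multiple-testing correction;
  plug-in MI bias; the MRS normalisation (mean |r|, not squared r) is
  one reasonable reading of "mean redundancy" and is fixed here for
  reproducibility.
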