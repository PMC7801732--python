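# Methods

## The problem

Inferential studies on high-dimensional tabular data (epidemiological
questionnaires, sensor capture, omics panels) need to identify which of
hundreds to thousands of candidate covariates plausibly drive a continuous
outcome.  Different variable-selection methods — stepwise criteria,
convex and nonconvex penalties — disagree substantially on the same data,
both in which covariates they select and in the coefficients they assign.
`triboot` implements a formal triangulation of several methods: each method
is bootstrapped, the resulting coefficient matrices are stacked into one
*combined model*, and covariate importance is read off the combined
selection stability and sign consistency.

## The combined model

For a method *m*, a conventional nonparametric bootstrap (resampling the n
observations with replacement, refitting the entire selection pipeline
including hyperparameter tuning) yields a B × p coefficient matrix; entry
(b, j) is covariate j's coefficient in replicate b, zero when unselected.
With equal B per method, the row-wise stack of M such matrices gives every
method equal weight.  From any matrix (single-method or combined) we
compute per covariate:

* **selection stability** — 100 × (number of rows with a nonzero
  coefficient) / (number of rows).  For the combined matrix at equal B this
  is exactly the arithmetic mean of the per-method stabilities.
* **Bootstrap P value** — among the nonzero coefficient values, the smaller
  of the two sign-side proportions: min(#positive, #negative)/#nonzero.
  A covariate selected 80 times with 70 positive values gets
  (80 − 70)/80 = 0.125.  It is undefined (reported missing, never imputed)
  when the covariate is never selected, and bounded above by 0.5.
* **coefficient distribution** — median and 2.5/97.5 percentiles of the
  nonzero values.  Because zeros are excluded, the combined distribution is
  implicitly weighted by how often each method selects the covariate.

## Change-point threshold

Covariates are ranked by descending stability (ties broken by ascending
Bootstrap P, then descending |median coefficient|, then name, so rankings
are deterministic).  In sparse problems the ranked profile falls steeply
through the genuinely important covariates and then flattens — the classic
scree-plot shape.  The change point is detected from the consecutive drops
d_r = s_(r) − s_(r+1) (percentage points of stability per rank step):
a rolling mean of `window` consecutive drops, attributed to the rank at the
*top* of the window (i.e. the smoothed rate of descent just below rank r),
is scanned down the ranking; once it has exceeded 1 and then falls back to
≤ 1, the covariates above that point are deemed important.  A profile whose
smoothed rate never exceeds 1 has no demarcation and nothing is selected —
this is what makes the rule safe on no-signal data, where stabilities vary
smoothly at a low level.

The forward (down-ranking) attribution of the window is deliberate: a
covariate belongs above the elbow when the profile is still dropping
steeply *after* it.  On the canonical fixture — ten covariates near 90%
stability followed by a flat tail — the rule puts the threshold exactly at
rank 10.  The default window of 15 follows a sensitivity analysis pattern
in which windows of 10–20 give near-identical selections (asserted as a
test on the regenerated benchmarks); below 10 the mean is under-smoothed,
above 20 discrimination degrades.

The rule is applied to any matrix but is primarily meant for the combined
model; per-method reports carry the same statistics for comparison.

## Selection methods

All six fitters share one contract: given (X, y) return a full-length
coefficient vector whose nonzero entries (|β| > 1e-8 on standardized data)
define the support.  The intercept is always unpenalized and excluded from
the support.  Penalized objectives use the 1/(2n)-scaled residual sum of
squares convention throughout, with λ grids derived from the data's λ_max,
so the parametrization matches the standard coordinate-descent literature.

* **Stepwise AIC** — covariates whose univariate Pearson correlation test
  p-value exceeds 0.80 are dropped, then greedy forward OLS selection
  minimizes AIC = 2k − 2 ln L̂ (Gaussian likelihood).  Forward-only by
  default since p ≫ n makes backward elimination infeasible; steps stop
  before the model becomes non-estimable.  Implemented with incremental
  Gram–Schmidt orthogonalization (O(np) per step).
* **Elastic net** — (1/2n)‖y − Xβ‖² + λ[(1−α)/2 ‖β‖² + α‖β‖₁], solved by
  sklearn's coordinate descent (this maps exactly onto sklearn's
  `ElasticNet(alpha=λ, l1_ratio=α)`); (λ, α) tuned by repeated k-fold CV
  minimizing mean absolute error, ties resolved toward the sparser fit.
* **SCAD / MCP** — nonconvex penalties whose shrinkage vanishes for large
  coefficients.  The SCAD penalty is defined through its clipped-linear
  derivative (λ flat region, linear descent to zero at γλ); MCP through
  λ|β| − β²/2γ saturating at 0.5γλ².  Solved by an active-set coordinate
  descent with warm starts along a decreasing λ path and full KKT screening
  sweeps (numba-compiled kernel); coefficients are standardized internally
  and reported on the original scale.  Defaults γ = 3.7 (SCAD) and γ = 3
  (MCP), the conventional values; λ by CV-MAE.
* **SparseStep** — penalty λ β²/(β² + γ²), a smooth ℓ0 surrogate.  Solved
  by iterative majorization: each step is a diagonally-weighted ridge solve,
  with γ tightened geometrically from 1 toward 1e-6 so the penalty
  approaches λ‖β‖₀; coefficients below 1e-3 (standardized scale) are
  hard-zeroed at the end.  λ by CV-MAE from a geometric grid — since the
  saturated penalty acts like an entry toll of ≈ λ per covariate, the grid
  spans entry thresholds √(2λ) from ≈ 0.35 to ≈ 4 standardized units.
* **mBIC** — greedy forward selection maximizing
  logL − ½k log n − k log((1−pr)/pr), where pr is the prior probability
  that a random candidate is a true predictor.  The auto rule pr = 4/p
  (expected four true predictors, the standard recommendation), clamped
  below 0.5 so the extra term never rewards complexity on toy problems.

### Numerical choices

* Zero-penalty limits (λ = 0) are special-cased to exact least squares, so
  the solvers coincide with OLS on well-conditioned problems to 1e-6.
* The nonconvex CD solver flags (rather than hides) non-convergence after
  200 sweeps; with warm starts along the path this is rare.
* During cross-validation the penalized paths carry a `dfmax` guard
  (150 in the reduced presets, off at full scale): models whose support
  outgrows it are excluded from evaluation and the rest of the path is
  abandoned.  The dense deep end of a λ path is useless for sparse
  selection and, on weak-signal data, dominates runtime; the guard never
  removes a model a sparse-selection CV would choose at these scales.
  CV-stage coordinate descent also runs at a relaxed tolerance (1e-3) —
  only the error ranking matters there — while tuned models are refit at
  1e-4.
* Forward stepwise freezes out candidates whose residualized norm falls
  below 1e-10 of its initial value (collinearity guard).
* SparseStep's dense solves cost O(K³); above K = 400 candidates the fitter
  first screens to the top-K covariates by absolute marginal correlation
  (sure-independence-screening style).  The elastic net applies the same
  screening only on very wide designs (top 1000 of p > 2000 in the reduced
  presets).  Screening can alter which marginal-noise covariates are
  available to a single fit, but the covariates it removes are precisely
  those a sparse fit at the tuned penalty would almost never select.

## Bootstrap design

Hyperparameters are re-tuned inside every bootstrap replicate by default:
stability is meant to reflect the variability of the *whole* selection
pipeline, tuning included.  A `fixed_hyperparams` mode pins the grids for
speed.  Replicate sub-seeds derive from (master seed, CRC32 of the method
label, replicate index, retry counter), so results are bit-identical under
any worker count or execution order.  A replicate whose fit raises is
retried with a fresh sub-seed and, after exhausting retries, recorded as an
all-zero row with a logged warning — row counts are exact by construction.

## Synthetic benchmarks

The generator reproduces six benchmark datasets:

| dataset | n | p | signal | noise SD of v |
|---|---|---|---|---|
| 1 | 1000 | 910 | 10 true covariates | 15 |
| 2 | 1000 | 910 | 10 true covariates | 6.5 |
| 3 | 200 | 10,010 | 10 true covariates | 6.5 |
| 4 | 200 | 10,010 | 10 true covariates | 23 |
| 5 | 1000 | 910 | none (y iid N(0,1)) | — |
| 6 | 200 | 10,010 | none (y iid N(0,1)) | — |

The outcome of the signal datasets is
y = 1 + 2.5(x₁+x₂+x₃+x₄) + x₅ + 2.5(x₆+…+x₁₀) + v, where x₁…x₅ are
multivariate normal with exchangeable correlation 0.6 (correlated causes,
as in real epidemiological data), x₆…x₁₀ iid standard normal, and
v ~ N(0, sd²) stands for real but unmeasured influences.  Noise covariates
mimic realistic correlation structure: blocks of 50 at within-block
correlation 0.7 and 0.8 (4 + 4 blocks for p = 910; 40 + 40 for p = 10,010)
plus an iid remainder.  All covariates have population mean 0 and SD 1 and
are used as simulated; user-supplied real data are standardized empirically
before selection.

With these constants the analytic signal variance is c'Σc = 114.25, giving
population R² = 0.730 for noise SD 6.5 (dataset 2/3), 0.337 for SD 15 and
0.178 for SD 23.  MVN sampling goes through the Cholesky factor of the
exchangeable correlation matrix; the master seed splits into independent
sub-seeds for the true block, the noise block and the outcome.

Dataset 6's dimensions are set to 200 × 10,010 for structural comparability
with datasets 3/4 (its false-positive rate is then measured against 10,000
true negatives).

**What the generator does not emulate:** non-Gaussian marginals, missing
data, heteroscedastic or non-linear outcome dependence, categorical
covariates, and the long-range correlation patterns of real omics data.
Passing benchmarks therefore demonstrate correct behaviour under a sparse
linear Gaussian regime, not performance guarantees on arbitrary real data.

## Study scale used by the tests and the acceptance script

The full presets mirror the benchmark study: B = 500 bootstrap replicates
(p = 910 datasets) or B = 100 (p = 10,010), 10 × 10-fold CV.  The shipped
tests and `scripts/acceptance.py` run the same workflow at reduced scale,
chosen as this package's own study conditions: B = 50 with 1 × 5-fold CV
inside replicates, with further reduced grids (15-point λ paths,
α ∈ {0.1, 1}, screening as above) for the 200 × 10,010 datasets; one
regeneration per dataset and ten regenerations for the cheap R² quantity.  At this scale stability percentages carry a
Monte-Carlo standard error of a few points, so error-rate checks allow a
±2-covariate margin around the reference counts.

Two consequences of the reduced scale are worth keeping in mind when
comparing against full-scale runs.  Single-repeat few-fold CV has a nearly
flat validation curve on no-signal data, so the penalized methods land on
overfit λ values in a sizeable fraction of replicates, which lifts the
stability of the strongest marginal noise correlates; and the maximum of
per-covariate stabilities estimated from few bootstrap rows is biased
upward relative to the same maximum at full B.  Both effects shrink as B
and the CV budget grow; neither affects the rank ordering of true versus
noise covariates on the signal datasets.

## Known limitations

* Nonconvex objectives (SCAD, MCP, SparseStep) admit local minima; the
  solvers return the standard path/majorization solutions, which match the
  univariate global minimizers in oracle tests but are not certified global
  in general — the same caveat applies to any coordinate-descent
  implementation of these penalties.
* The change-point rule assumes a sparse truth; profiles with many
  moderately stable covariates produce no demarcation by design.
* Gaussian outcomes only; no GLMs, random effects or categorical outcomes.
* CV fold assignment is seeded but arbitrary; selections on data with
  strong observation clustering would need grouped resampling, which is
  not implemented.
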