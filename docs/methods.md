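# Methods

## Model and estimation

`scoreinv` fits confirmatory factor models by multivariate-normal maximum
likelihood in casewise form. For individual i in group g with indicator
vector xᵢ ∈ ℝᵖ,

ℓ(θ; xᵢ) = log N(xᵢ | μ_g(θ), Σ_g(θ)),  μ_g = ν_g,  Σ_g = Λ_g Φ_g Λ_gᵀ + Θ_g,

with loadings Λ, intercepts ν, diagonal unique variances Θ, factor
covariance Φ, and factor means fixed to 0 in every group. Two
identification conventions are available and matter for which parameters can
be tested:

- **marker** (default): the first loading per factor is fixed to 1, factor
  variances free. This is the convention of the multi-group questionnaire
  workflow (`equal=["loadings"]` etc.).
- **variance**: factor variances fixed to 1, all loadings free. The
  simulation designs use this convention, because they test individual
  loadings (a marker loading has no score).

Cross-group equality constraints collapse parameter-table rows onto shared
free indices; the table enumerates loadings first, then intercepts, unique
variances and factor (co)variances, so the lavaan-style positional
addressing `parm="1:4"` picks the free loadings of the constrained
multi-group model.

Optimization runs L-BFGS-B on a transformed scale (log for variances) with
an analytic gradient assembled from the matrix identities
∂ℓ/∂Σ = ½(Σ⁻¹uuᵀΣ⁻¹ − Σ⁻¹), ∂ℓ/∂μ = Σ⁻¹u (u = x − μ), chained to Λ, Θ, Φ,
ν. A Newton polish with a finite-difference Hessian then drives the
infinity norm of the per-observation gradient below 10⁻⁸ (convergence is
accepted below 10⁻⁵; otherwise up to three jittered restarts, then an
explicit `ConvergenceError` — never a silent partial result). Non-positive-
definite implied covariances encountered during the search are handled by a
penalty that makes line searches back off; such a point is never returned.
Likert items are treated as continuous multivariate-normal data throughout —
no polychoric machinery — matching standard practice for seven-point scales
in this family of tests. Missing data are handled by complete-case deletion
with a logged row count; nothing beyond that is implemented.

Casewise scores are analytic (a finite-difference fallback,
`score_matrix(..., method="fd")`, anchors their correctness in the tests).
Three per-observation information estimates are available: **observed**
(numeric Hessian of the mean log-likelihood; the default, and the choice a
user of the questionnaire workflow would make), **opg** (outer product of
scores) and **expected** (via implied-moment Jacobians). A numerically
indefinite observed information logs a warning and falls back to the outer
product.

## Fluctuation process and statistics

Scores are ordered by the auxiliary variable (stable sort; ties keep input
order under the continuous treatment, which is flagged with a warning
because the resulting statistics depend on that arbitrary order) and
accumulated into B(t) = Î^{−1/2} n^{−1/2} Σ_{i≤⌊nt⌋} s(θ̂; x₍ᵢ₎).
Decorrelation always uses the full k×k information; testing a subset selects
columns of the decorrelated process afterwards. Decorrelating a sub-block
instead would change results — the implemented semantics mirror testing a
subset of a jointly estimated model. The inverse square root is an
eigendecomposition with a relative eigenvalue tolerance of 10⁻¹⁰; a
rank-deficient information fails loudly, naming the parameters loading on
the null space.

The six functionals are pure functions of the process (see the README table).
Two definitions deserve a note:

- the trimmed window of `maxLM` defaults to (0.1, 0.9); the weight
  {t(1−t)}⁻¹ diverges at the endpoints, and this trimming matches common
  structural-change practice. It is user-overridable (`TrimSpec`).
- `LMuo` weights each level block's squared increment by the inverse block
  proportion: LMuo = Σ_ℓ (Δt_ℓ)⁻¹ Σ_j (B_{i_ℓ j} − B_{i_{ℓ−1} j})².
  The weights are what make the statistic χ²_{k(m−1)} under the null and
  asymptotically equivalent to the multi-group likelihood-ratio statistic
  (both are verified in the tests; the equivalence holds to 0.3% at
  n = 4000 in the two-group check).

## Null distributions

Under stability the components of B are asymptotically independent standard
Brownian bridges, so:

- **DM**: P(sup|BB| ≤ c) = 1 − 2Σ_{i≥1}(−1)^{i+1}exp(−2i²c²), truncated at
  relative 10⁻¹²; k independent components give p = 1 − F(c)ᵏ.
- **WDMo**: the tie-point values are jointly Gaussian with
  Cov(B(t_a), B(t_b)) = t_a(1 − t_b) for a ≤ b. The rectangle probability is
  computed by deterministic density propagation along the bridge's Markov
  chain (trapezoidal quadrature, 401-point grids), which is reproducible
  bit-for-bit, unlike QMC multivariate-normal integration; the scipy MVN CDF
  serves as an independent cross-check in the tests (agreement ≈ 10⁻⁴).
- **maxLMo**: simulated from the exact finite-dimensional law — only m−1
  Gaussian draws per bridge component are needed, not a path grid. The
  default table uses 50,000 replications and covers k = 1..20 in one sweep
  (cumulative sums over components), records its seed and replication count,
  reproduces bit-identically from them, and is reusable only for identical
  tie proportions (enforced).
- **LMuo**: χ² with k(m−1) degrees of freedom.
- **CvM / maxLM**: simulated from Gaussian-increment bridge paths on a
  1000-point grid, 20,000 replications by default. A convergence check in
  the tests shows the 5% DM quantile moving toward the analytic value as the
  grid is refined (within 2% at 2000 points); the grid sup is biased
  slightly low relative to the continuous-time sup, which also makes it the
  better match for the finite-n statistic.

Monte-Carlo p-values use (1 + #{v ≥ s}) / (nrep + 1).

## Simulation engine

The default data-generating process is a two-factor model with three
indicators per factor under the variance identification. True values:
all loadings 1, intercepts 0, unique variances 1, factor covariance 0.5;
the misspecification design adds an unmodeled cross-loading (factor 2 →
indicator 1) of 0.5 to the generating model only. These values are the
package's fixed study conditions; they are user-overridable
(`two_factor_dgp(**{"f1~~f2": 0.3})`) but the shipped tests and the
acceptance script use the defaults.

An instability of magnitude d shifts one parameter upward by d × SE_n for
every individual below the changepoint level 1 + m/2 of the m-level ordinal
variable, where SE_n is the parameter's asymptotic standard error at the
simulated n (inverse expected information at the true values, divided
by n). Because SE_n ∝ n^{−1/2}, a given d is comparable across sample
sizes. Level allocation is balanced (largest-remainder when m ∤ n). A
deviation that breaks positive definiteness raises an error naming the cell.

`run_power_study` fits the (correctly specified or misspecified) pooled
model per replication, evaluates every functional × tested-subset
combination against α-level critical values (maxLMo tables cached per tie
structure and k; WDMo by inverting the analytic rectangle probability; LMuo
by the χ² quantile), drops and counts non-converged replications (flagged
above 5%), and emits a TSV/JSON table with binomial MC standard errors. One
master seed spawns an independent stream per cell.

Problem sizes in the shipped tests are scaled down to keep the suite fast:
500 replications for the size/power and misspecification checks (the full
designs used 5000; `nrep` is an argument), 1000 replications in the
acceptance script, 200 replications at n = 10,000 for parameter recovery.
At 500 replications a rejection proportion carries an MC standard error of
up to 0.022, which the assertions account for.

## The synthetic fixture

`make_fixture` emulates the shape of a youth gratitude questionnaire: one
factor, five seven-point Likert items (continuous normal responses rounded
and clipped to 1..7), six ordered age groups of near-equal size assigned
independently of the responses. It reproduces the *shape* of such data —
number of items, response range, group structure — but not features of real
surveys: the discretization is coarse rounding rather than threshold-based
ordinal response, there are no skewed category distributions, no missing
data, and invariance holds exactly. Passing tests on the fixture therefore
demonstrate correct mechanics and calibrated nulls, not robustness to the
messiness of real questionnaire data. An opt-in integration test documents
how to export the real dataset from R and reproduces the published
multi-group arithmetic when that CSV is present.

## Design choices and limitations

- The Wishart (moment-based) likelihood variant is not implemented: scores
  are casewise by definition, and the casewise normal likelihood is what the
  tests consume. Likewise out of scope: GLS/WLS discrepancy functions,
  incomplete-data scores, Bayesian approximate invariance, and IRT/Rasch
  recursive partitioning.
- AIC/BIC are −2ℓ + 2k and −2ℓ + k·log n on the casewise log-likelihood;
  other software may differ by a likelihood constant.
- p-values are not adjusted for multiple testing; the CLI offers a
  `--bonferroni K` convenience flag only.
- Under the shipped DGP values, the misspecification design allocates the
  unmodeled-loading artifact almost entirely to the first loading (and, to a
  lesser degree, the factor covariance); the unique-variance component picks
  up almost none of it. How the artifact distributes across parameters is
  sensitive to the true parameter values, so conclusions from that design
  should be read as specific to these study conditions.
- Empirical Type-I error of the ordinal tests at n = 480 is within
  Monte-Carlo error of the nominal 5% level; smaller samples (n = 120) show
  the usual mild finite-sample distortion of score tests and are exercised
  only in the power-study grids, not asserted against nominal bands.
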