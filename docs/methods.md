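# Methods

## Models

### Proportional-odds DIF testing

Each item is analyzed marginally. With Y the item's ordinal response
(1..J), θ the matching criterion and G ∈ {0,1} the group indicator, three
nested cumulative-logit models are fitted by maximum likelihood:

1. `logit P(Y ≤ j) = γ_j + β θ`
2. `logit P(Y ≤ j) = γ_j + β θ + β_G G`
3. `logit P(Y ≤ j) = γ_j + β θ + β_G G + β_I θG`

Uniform DIF is tested by 2(logL₂ − logL₁) against χ²(1) (group main
effect), nonuniform DIF by 2(logL₃ − logL₂) against χ²(1) (trait × group
interaction). The matching criterion defaults to the observed **total test
score including the studied item**; a rest-score option (total minus the
studied item) is available. The latent trait used to generate synthetic
data is deliberately never consumed by the detection code.

### Elastic net regularization

The penalized objective, on the mean-log-likelihood scale, is

    l(γ, β) = −(1/N) log L + λ [ w Σ_j |β_j| + (1−w)/2 Σ_j β_j² ].

Only slopes are penalized. Intercepts must remain free: they encode the
category split points, and shrinking them would distort every cumulative
probability rather than regularize an association. λ = 0 recovers the ML
fit exactly; w = 1 is the LASSO, w = 0 the ridge.

λ is selected per fitted model by BIC = −2 logL_λ + log(N) · N_nonzero,
where logL_λ is the *unpenalized* log-likelihood at the penalized solution
and N_nonzero counts parameters (intercepts included) with magnitude above
1e−8 on the standardized scale. Each of the nested models gets its own path
and its own BIC minimum: sharing one λ across models of different dimension
has no defensible definition under this BIC. Ties break toward the larger
(more regularized) λ.

For the regularized LR comparison the default statistic is
2(logL₂ − logL₁) with each logL the unpenalized log-likelihood at that
model's BIC-selected estimates, referred to χ²(1); shrinkage breaks exact
nesting, so a negative difference is clipped to zero (p = 1) rather than
treated as an error. The literal alternative — differencing the penalized
objectives themselves (`lr_loglik="penalized_objective"`) — is implemented
behind a switch and recorded in output metadata. The default was chosen
because it keeps the statistic on the χ² scale and, in validation runs,
reproduces published behavior of this procedure class (see "Validation"
below).

## Tunable parameters

| parameter | default | meaning / rationale |
|---|---|---|
| `weight_w` | — | elastic net mixing weight in [0,1]; the study grid is {0, 0.01, ..., 0.1, 0.5, 1} |
| `n_lambda` | 20 | points on the geometric λ path; common path granularity |
| `min_ratio` | 0.01 | λ_min / λ_max; the path head λ_max is the KKT bound at the intercept-only fit, with the mixing weight floored at 0.01 in that formula only (pure ridge has no finite zeroing λ) |
| `standardize` | True | unit-SD scaling of covariates before penalized fitting (penalties are scale-sensitive); coefficients are mapped back |
| `alpha` | 0.05 | flagging level; rejection is strict (p < α) |
| `score_type` | "total" | matching criterion; "rest" available |
| `tol`, `max_iter` (ML) | 1e−10 / 1e−8, 100 | relative log-likelihood change and gradient max-norm; tighter than any test tolerance |
| zero tolerance | 1e−8 | magnitude below which a standardized coefficient counts as zero in BIC |

## Optimization

The cumulative-logit log-likelihood is concave in (γ, β) (logistic density
is log-concave), so the ML fit uses exact Newton steps with analytic
gradient and Hessian and step-halving; any intercept crossing makes a
category probability negative and is rejected by the line search, which is
the only monotonicity enforcement needed. Intercepts start at the logits of
the empirical cumulative proportions, slopes at zero. If no descent
direction remains, the iterate is the optimum to within rounding and is
accepted.

The penalized fit is proximal Newton: the smooth part is replaced by its
local quadratic model, which is minimized **exactly** by a small active-set
solver (slopes enter/leave by the KKT conditions of the L1 term; each
iteration is one linear solve in ≤ a dozen dimensions), followed by a
backtracking line search on the true objective. Convergence is declared on
the KKT subgradient residual (≤ 1e−7). Paths are fitted from λ_max
downward with warm starts. The solver was checked against an independent
generic minimizer (L-BFGS-B on the split β = β⁺ − β⁻ reformulation) to
1e−4 in objective value for w ∈ {0, 0.5, 1}.

Degenerate inputs: outcome categories unobserved in a given item/sample are
collapsed onto the observed ordered categories (recorded in
`category_map`); a single-category item raises a degenerate-outcome error,
which the scale sweep records per item and the simulation engine treats as
a discarded-and-redrawn replication. Slopes with |estimate| > 30 trigger a
separation warning.

## Synthetic data generator

The generator emulates two-group Likert-type questionnaire data from
Samejima's graded response model: P(Y ≥ j+1 | θ) = logistic(a_i (θ − b_ij)),
with a_i ~ U(1, 2), per-item thresholds obtained as J−1 independent N(0,1)
draws sorted ascending, and θ ~ N(0,1) in both groups (no impact). Uniform
DIF of magnitude δ adds δ to every threshold of the target item in the
focal group only. Group sizes follow n_ref = round(N·R/(R+1)) for ratio R.

Ordering mechanism: a distribution over *ordered* thresholds has to be
chosen; sorting independent draws is the simplest mechanism consistent with
"standard normal thresholds", and unordered thresholds would produce
negative category probabilities. Item parameters are redrawn each
replication, treating the bank as random and averaging operating
characteristics over banks; a `fixed_bank` switch holds one bank fixed
across replications instead.

What the generator does **not** emulate: group impact (different θ means),
nonuniform DIF, missing responses, multidimensionality, local dependence,
and real-scale threshold spacing. Passing simulation tests therefore show
correct operating characteristics *under this idealized GRM world*, not
performance guarantees on any particular real instrument.

## Monte Carlo engine

Each replication draws a bank, injects DIF into item 1, simulates one
dataset, and applies every configured method to that same dataset (paired
design — method contrasts are variance-reduced). Power is the rejection
proportion on item 1; type-I error pools rejections over the DIF-free
items. Replications with a degenerate or non-convergent required fit are
redrawn from a derived seed (≤ 10 attempts) and counted. Seeding is
hierarchical — (base seed, replication index, attempt) through NumPy seed
sequences — so any condition, replication or grid is reproducible
independently of worker count and execution order. Reported proportions
carry the Monte Carlo standard error sqrt(p̂(1−p̂)/n).

Problem sizes: the bundled reproduction checks in `tests/` run the study
cells at 300 replications with correspondingly widened sampling-error
tolerances; `scripts/acceptance.py` uses 1000 replications (500 for the
N = 400 LASSO type-I cell), which resolves proportions to about ±0.03 at
three standard errors.

## Validation and known limitations

The fitting layers are verified against independent oracles: the ML fit
against `statsmodels.OrderedModel` (log-likelihood and coefficients), the
penalized fit against a generic bound-constrained minimizer, intercept-only
fits against the closed form, and the whole ML DIF pipeline against an
independent R implementation (`MASS::polr` on R-simulated GRM data), which
reproduces this package's rejection rates.

Under these generating conditions the ML uniform-DIF test is essentially
calibrated on truly null data (empirical size ≈ 0.05–0.06 at N = 100,
→ 0.05 as N grows) but inflates on DIF-free items when another item in the
total score carries DIF — the matching criterion is then differentially
contaminated — and the inflation grows with N and DIF magnitude. The
LASSO-regularized test inflates type-I error further on short scales
(to ≈ 0.25 at I = 5, N = 400, severe DIF), while ridge-heavy weights
(w ≤ 0.02) are strongly conservative; the practical sweet spot for small
samples is the 0.03 ≤ w ≤ 0.1 range. Published rejection rates for this
class of procedure vary with unreported details of the generating and
fitting pipelines; several nonregularized-column values reported elsewhere
are lower than what this implementation (and its independent R cross-check)
produces under the stated conditions, which is why the bundled reproduction
checks pass for some published cells and not others.

Out of scope: partial proportional-odds models, Wald-based DIF tests,
cross-validated λ selection, effect-size (pseudo-R²) DIF criteria,
iterative purification/anchor selection, and missing-data handling.
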