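# difnet

Differential item functioning (DIF) detection for ordinal questionnaire
items, using nonregularized and **elastic net regularized proportional-odds
(cumulative logit) regression**, together with a graded-response-model (GRM)
simulator and a Monte Carlo engine for power and type-I-error studies.

## Who this is for

Psychometric and health-outcomes researchers (e.g. quality-of-life scales)
who need to check measurement invariance between two groups — a reference
and a focal group — when sample sizes are small. Ordinary
maximum-likelihood ordinal regression relies on asymptotics that degrade
below roughly 200 respondents per group; penalized (elastic net) estimation
is a practical alternative in that regime, and this package implements both
plus the simulation machinery to compare them.

## The method

For each item with ordinal response Y in 1..J, three nested
proportional-odds models are fitted, with the observed total test score
θ as the matching criterion and G the 0/1 group indicator:

    model 1:  logit P(Y ≤ j) = γ_j + β θ
    model 2:  logit P(Y ≤ j) = γ_j + β θ + β_G G
    model 3:  logit P(Y ≤ j) = γ_j + β θ + β_G G + β_I (θ × G)

*Uniform DIF* (a constant group offset across the trait range) is the 1-df
likelihood-ratio comparison of models 1 vs 2; *nonuniform DIF* (a group
difference that changes along the trait) is models 2 vs 3. Both statistics
are referred to χ²(1).

The regularized variant replaces each ML fit by the minimizer of the
elastic net penalized objective

    −(1/N) log L + λ [ w Σ|β_j| + (1−w)/2 Σ β_j² ],

where w ∈ [0,1] mixes the LASSO (w = 1) and ridge (w = 0) penalties and the
category intercepts γ_j are never penalized. λ is chosen per model by
minimizing BIC = −2 log L_λ + log(N) · N_nonzero (intercepts counted) over a
descending geometric λ path fitted with warm starts; the LR comparison then
uses the unpenalized log-likelihood evaluated at the selected estimates.

The simulator generates responses from Samejima's graded response model
(discriminations a ~ U(1,2), sorted N(0,1) thresholds, θ ~ N(0,1)) and
injects uniform DIF by adding a constant to the focal group's thresholds of
one item.

## Worked example

```python
import numpy as np
import difnet as dn

bank  = dn.sample_item_bank(n_items=5, n_categories=5, seed=11)
focal = dn.apply_uniform_dif(bank, dn.DIFSpec(target_item=1, magnitude=0.8))
data  = dn.simulate_responses(bank, focal, n_ref=100, n_focal=100, seed=12)

scan = dn.analyze_scale(data, dn.DIFConfig(method="ml"))
print(scan.summary())
```

```
DIF scan: 5 items, method = ml, alpha = 0.05; 1 flagged for uniform DIF
 item  uniform_stat  uniform_p  nonuniform_stat  nonuniform_p  flagged_uniform ...
    1      5.964443   0.014597         0.000178      0.989353                1
    2      0.399217   0.527494         0.013314      0.908140                0
    3      2.346998   0.125525         1.196420      0.274038                0
    4      3.695089   0.054573         0.870284      0.350877                0
    5      2.130319   0.144411         0.447950      0.503310                0
```

Item 1 — the item that actually carries the simulated DIF of 0.8 — is the
one flagged: its group coefficient improves the model-2 fit by a
likelihood-ratio statistic of 5.96 (p = 0.015 on χ²(1)), while the
interaction test (nonuniform DIF) is null, as it should be for a uniform
shift. Items 2–5 stay below the α = 0.05 threshold.

The penalized fit behind the regularized variant is a model object in the
statsmodels style:

```python
y     = data.responses[:, 0]
score = dn.matching_score(data.responses, 1, "total")
X     = np.column_stack([score, data.group])
path  = dn.ElasticNetOrdinalLogit(y, X, weight_w=0.05,
                                  exog_names=["score", "group"]).fit_path()
print(path.selected.summary())
```

```
Elastic net penalized proportional-odds fit
lambda = 0.0682504   w = 0.05   logL = -219.0166   objective = 1.141384
n_nonzero (incl. intercepts) = 6   converged = True
parameter           estimate
gamma_1|1             2.8066
gamma_2|2             3.5113
gamma_3|3             4.1061
gamma_4|4             4.3321
score                -0.2252
group                 0.4913
```

BIC selected λ = 0.068 on the 20-point path; both slopes survive the
penalty (6 nonzero parameters = 4 intercepts + 2 slopes), and the positive
group coefficient reflects the focal group's shifted thresholds on item 1.

## Command line

```
difnet simulate --n 200 --ratio 1 --items 5 --dif 0.8 --seed 7 -o data.csv
difnet dif data.csv --method elastic_net -w 0.05 -o results.tsv
difnet power-study grid.yaml -o summary.tsv --jobs 4
```

`simulate` writes a response CSV (`item_1..item_I`, `group` 0 = reference /
1 = focal, optional `theta`); `dif` scans any CSV of that shape (use
`--zero-based` for 0-coded Likert items) and writes a per-item TSV;
`power-study` runs a condition grid from a YAML config (keys: `grid:
{n_total, ratio, n_items, dif}`, `w_grid`, `include_ml`, `replications`,
`seed`, ...) and writes a long-format summary with Monte Carlo standard
errors. Every output file carries `#` header comments with the seed and a
config hash so it can be regenerated exactly.

## Layout

- `src/difnet/grm.py` — GRM item banks, DIF injection, response simulation
- `src/difnet/ordinal.py` — proportional-odds ML fit (Newton), LR test
- `src/difnet/penalized.py` — elastic net fit, λ path, BIC selection
- `src/difnet/dif.py` — per-item nested-model DIF tests and scale sweeps
- `src/difnet/study.py` — Monte Carlo conditions, replication engine, grids
- `src/difnet/io.py`, `src/difnet/cli.py` — CSV/TSV formats and the CLI
- `docs/methods.md` — modelling and simulation details, numerical choices
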