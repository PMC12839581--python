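# dcrank — distributed high-dimensional convoluted rank regression

`dcrank` estimates sparse linear models from data that is partitioned
across many machines, when the noise may be heavy-tailed, heteroscedastic
or outlier-ridden. It is aimed at statisticians and analysts fitting
high-dimensional regressions (p ≫ n per machine) on sharded data — e.g.
multi-site biomedical cohorts or any setting where raw data cannot be
pooled — who need coefficient estimates and variable selection that do not
collapse when the errors have no finite variance (Student t(2), Cauchy,
contaminated normals).

## The method

The Wilcoxon rank loss Σ_{i≠j}|r_i − r_j| (r_i the i-th residual) is robust
— it needs **no moment assumptions** on the noise — but is not smooth.
`dcrank` minimises its kernel-smoothed version

    L̂_h(β) = 1/(N(N−1)) Σ_{i≠j} L_h((Y_i − X_i′β) − (Y_j − X_j′β)),
    L_h(u)  = ∫ |u − v| K_h(v) dv    (Epanechnikov kernel, bandwidth h = 1),

whose population minimiser equals the true β\* for every h > 0, plus a
folded-concave SCAD penalty (a = 3.7) for sparsity. In the distributed
setting the full loss is never formed: each communication round t the
central machine solves the surrogate problem

    β̂^(t) ∈ argmin_β  L̂_{1,h}(β) − ⟨∇L̂_{1,h}(β̂^(t−1)) − ∇L̂_h(β̂^(t−1)), β⟩
                       + Σ_j p_λ(|β_j|),

which tilts its local loss toward the global one using only gradient
vectors (p numbers per machine per round). After T = ⌈log m⌉ rounds the
estimator matches the pooled-data convergence rate. The inner problem is
solved by local linear approximation (LLA) with closed-form coordinate
updates, and λ is tuned by a high-dimensional BIC — no cross-validation.

Baselines included: the machine-1 **local** fit, one-shot **divide and
conquer** averaging, and the pooled **global** fit. See
[docs/methods.md](docs/methods.md) for the full account.

## Worked example

```python
import numpy as np
from dcrank import DCRConfig, SimulationConfig, generate_dataset, fit_dcr, rmse, f1_support

cfg = SimulationConfig(p=400, n=200, m=10, error_family="cauchy")
dataset = generate_dataset(cfg, seed=42)      # 10 machines x 200 rows, Cauchy noise

fit = fit_dcr(dataset, DCRConfig())           # T = ceil(log 10) = 3 rounds
print("rounds:", fit.rounds_used)
print("selected lambda:", round(fit.selected_lambda, 4))
print("support:", fit.support + 1)            # 1-based indices
print("rmse:", round(rmse(fit.beta, cfg.beta_star), 4))
print("f1:", f1_support(fit.beta, cfg.beta_star))
```

prints

```
rounds: 3
selected lambda: 0.0943
support: [1 2 3 4 5]
rmse: 0.0019
f1: 1.0
```

Despite Cauchy noise (no finite mean) the fit recovers exactly the five
true predictors (F1 = 1.0: the estimated and true nonzero sets coincide)
with a per-coordinate root-mean-square coefficient error of 0.0019, i.e. an
ℓ₂ error of about 0.04 against signal coefficients of size 3.

The same is available from the shell:

```sh
dcrank fit --x X.csv --y Y.csv --m 10 --method dcr --penalty scad --out results/
dcrank reproduce-table1 --families normal,cauchy --m 10 --reps 20 --out results/
```

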