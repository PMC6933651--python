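# flowtrack

Model-based clustering and cell-population tracking for **time-series flow
cytometry** data.

Flow cytometry measures the expression of up to ~20 protein markers per
cell for thousands of cells per second. Classifying cells into populations
("gating") is increasingly done by unsupervised clustering, but standard
tools treat each timepoint in isolation and cannot say *how* populations
move, grow, shrink, or abruptly reorganise over a time course — exactly the
questions asked in longitudinal immune monitoring (stimulation assays, drug
response, immunotherapy follow-up).

`flowtrack` fits one coherent model to the whole time course, for one or
several *cases* (subjects / conditions) at once:

- cells `y ∈ R^K` at timepoint `t` and case `d` follow a multivariate
  Gaussian mixture with **global** cluster means `μ_l` and covariances
  `Σ_l` (shared across all timepoints and cases, so cluster identities are
  directly comparable over time),
- the mixture proportions evolve under a Dirichlet chain
  `π_{t,d} | α_{t,d}, π_{t−1,d} ~ Dirichlet(α_{t,d} · π_{t−1,d})`,
- the concentration `α_{t,d}` — the **persistency parameter** — is
  estimated per timepoint and case. A small `α̂_{t,d}` means the population
  composition at `t` is inconsistent with `t−1`: a **change-point**.

Priors: `μ_l | τ, Σ_l ~ N(0, τ⁻¹ Σ_l)` and `Σ_l⁻¹ ~ Wishart(ν, Λ⁻¹)`.
Fitting is stochastic EM: each sweep draws every cell's cluster label once
by Gibbs sampling from

`η_{t,d,n,l} ∝ exp{ −½ (y−μ_l)ᵀ Σ_l⁻¹ (y−μ_l) + ½ log|Σ_l⁻¹| + log π_{t,d,l} }`,

then updates `α̂_{t,d}` by fixed-point iteration on the
Dirichlet-multinomial likelihood, `π̂_{t,d}` by its posterior mean
`(N_{t,d,l} + α̂ π̂_{t−1,d,l}) / (N_{t,d} + α̂)`, and `μ̂_l`, `Σ̂_l` by MAP
(Normal–Wishart) updates from the pooled assigned cells.

## Worked example

```python
import numpy as np
from flowtrack import (TimeSeriesGaussianMixture, default_simulation_config,
                       simulate_dataset, match_clusters)

# benchmark design: K=10 markers, T=5 timepoints, D=2 cases,
# 1000 cells per (t, d); composition shifts at t=3,5 (case 1), t=2,4 (case 2)
data, truth = simulate_dataset(default_simulation_config(seed=1))

est = TimeSeriesGaussianMixture(n_clusters=3, tau=1e-5, nu=12,
                                n_iter=40, random_state=1).fit(data)

perm = match_clusters(est.means_, truth.mu)
print("max |mu_hat - mu|:", float(np.max(np.abs(est.means_[perm] - truth.mu))))
print("mean |pi_hat - pi|:", float(np.mean(np.abs(est.proportions_[..., perm] - truth.pi))))
print("alpha_hat:\n", np.array2string(est.persistency_, precision=2))
print("change points:", est.change_points(0.5).flagged)
```

prints

```
max |mu_hat - mu|: 0.049544202057386855
mean |pi_hat - pi|: 0.010816368108821594
alpha_hat:
 [[  5.59   4.26]
 [129.09   2.6 ]
 [  2.96 215.33]
 [193.08   3.12]
 [  2.18 190.57]]
change points: [[3, 5], [2, 4]]
```

Every element of the 3 cluster means (10 markers each) is recovered within
0.05, the proportion trajectories within ~0.01 on average, and `α̂` drops by
two orders of magnitude exactly at the designed change timepoints — column 1
(case 1) dips at t=3 and t=5, column 2 (case 2) at t=2 and t=4 — which is
what `change_points` reports. (The first row measures divergence from the
uniform anchor before t=1 and is excluded from flagging; with only four
candidate timepoints the median quantile flags both dips per case, while
the conservative default 0.25 flags only the deepest one.)

## Command line

```bash
flowtrack simulate --out-dir sim --seed 1            # benchmark design
flowtrack fit sim/data.csv --n-clusters 3 --seed 1 --out-dir fit
flowtrack elbow sim/data.csv --l-values 1,2,3,4,5,6 --out-dir elbow
flowtrack changepoints fit --quantile 0.25
```

`fit` reads long-format delimited text (`time,case,<marker...>` columns;
FCS 2.0/3.0/3.1 files via a YAML manifest and `--fcs`) and writes cluster
means, covariances, proportion trajectories, the persistency table,
per-cell labels (1-based clusters) and the log-likelihood trace as CSV.
`elbow` reports within-cluster SSE per candidate L for user-interactive
cluster-number choice — no automatic selection is attempted, since
likelihood criteria over-split near-continuous cell phenotypes.

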