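# mcpgraph

Graph-based closed multiple test procedures for confirmatory clinical
trials: weighted Bonferroni, correlation-aware parametric (min-p) and
weighted Simes tests, driven by a graphical weighting strategy.

## The problem

A pivotal trial rarely tests one hypothesis. Two doses against control, a
primary and a secondary endpoint, non-inferiority then superiority — the
study's objectives form a family H₁,…,H_m with logical structure (a
secondary claim is worthless without its primary), and the familywise error
rate (FWER) must be controlled in the strong sense at level α.

The closed testing principle rejects H_i only if every intersection
hypothesis H_J = ⋂_{j∈J} H_j with i ∈ J is rejected by a local α-level
test. That requires a weight vector w_j(J) for each of the 2^m − 1
intersections. `mcpgraph` generates all of them from a single directed
weighted graph: node i carries an initial weight w_i (its share of α), and
edge i → j carries the fraction g_ij of H_i's level propagated to H_j once
H_i is rejected. Removing the hypotheses outside J one at a time — updating

    w_l ← w_l + w_j g_jl,      g_kl ← (g_kl + g_kj g_jl) / (1 − g_kj g_jk)

— yields w_j(J), independent of the removal order. The weighting strategy
is then decoupled from the local test applied to each intersection:

- **weighted Bonferroni**: reject H_J if some p_j ≤ w_j(J)·α; admits an
  m-step sequentially rejective shortcut;
- **weighted parametric (min-p)**: reject H_J if some
  p_j ≤ c_J·w_j(J)·α, with c_J ≥ 1 calibrated from the (blockwise known)
  joint multivariate normal null distribution of the test statistics;
- **weighted Simes**: reject H_J if some p_j ≤ α·Σ_{k: p_k ≤ p_j} w_k(J);
  valid under positive regression dependence, optionally applied per block
  of a user-asserted dependence partition.

Consonance diagnostics, adjusted p-values, standard constructors (Holm,
fixed sequence, fallback, truncated-Holm gatekeeping, endpoint
hierarchies), a Monte-Carlo FWER/power validator and a CLI are included.

## Worked example

Two doses, each with a primary (H₁, H₂) and secondary (H₃, H₄) endpoint in
strict hierarchy; initial weights (½, ½, 0, 0); the correlation within each
endpoint pair is 0.5, across pairs unknown:

```python
import numpy as np
import mcpgraph as mg

graph = mg.make_standard_graph("hierarchical")
corr = np.full((4, 4), np.nan); np.fill_diagonal(corr, 1.0)
corr[0, 1] = corr[1, 0] = corr[2, 3] = corr[3, 2] = 0.5
model = mg.CorrelationModel(corr)          # blocks {H1,H2}, {H3,H4}

p = [0.0131, 0.1, 0.012, 0.01]
par = mg.closed_parametric(graph, p, model, alpha=0.025)
print(par.rejected_names)                  # ('H1', 'H3')
print(np.round(par.adjusted_p, 8))         # [0.02431856 0.1  0.02431856 0.1]

bon = mg.closed_bonferroni(graph, p, alpha=0.025)
print(bon.rejected_names)                  # ()  -- the correlation buys both rejections
```

The parametric closure sharpens each intersection's Bonferroni levels by a
critical constant; for the pair {H₁, H₂} at ρ = 0.5, α = 0.025:

```python
c = mg.critical_constant([0.5, 0.5], model.restrict([0, 1]), alpha=0.025)
print(round(c, 4))                         # 1.0783  -> local levels 1.35% instead of 1.25%
```

This procedure is not consonant (no sequential shortcut): H₁'s local level
drops from 1.35% to 1.25% once H₂ leaves the intersection. Consonance can
be enforced by adding δ-weight edges between the primaries:

```python
delta = mg.min_consonance_delta(model, alpha=0.025)
print(round(delta, 4))                     # 0.0783
```

The same session from the shell:

```sh
mcpgraph test --kind hierarchical --pvalues 0.0131,0.1,0.012,0.01 \
    --method parametric --corr corr.csv --alpha 0.025
mcpgraph weights --kind hierarchical          # the 15-row closure weight table
mcpgraph check --kind hierarchical_delta --delta 0.0783 --corr corr.csv
mcpgraph simulate --kind hierarchical --corr full.csv --nsim 100000
```

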