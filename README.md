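# agrifuse

Precision-agriculture decision support asks two coupled questions about a
field split into N management zones: **which zones are stressed?** (pest
outbreaks, fungal infection, drought, nutrient deficiency) and **how should
limited water, fertilizer and pesticide budgets be spread across zones in
response?** `agrifuse` is a seedable, CPU-only toolkit that answers both on
a fully synthetic multi-zone field with known ground truth, so every stage
— sensing, detection, optimization, feedback control — is testable without
any external data. It is aimed at researchers prototyping detection and
allocation strategies, and at anyone who wants a transparent, verifiable
implementation of the underlying math.

## What is inside

**Synthetic field simulator** (`agrifuse.synthetic_field`). N zones on a
row-major grid, each carrying an AR(1) environmental state (soil moisture,
temperature, nutrient index, canopy vigor) with spatially correlated
innovations (Gaussian kernel over grid distance). Four injectable stress
archetypes shift these variables by documented amounts per unit severity.
Four sensor modalities are rendered per step: a satellite grid, a strictly
finer UAV grid, point ground sensors, and a weather series. Realized yield
per zone follows a diminishing-returns response,

    Y_i = β₁u_w + β₂u_f + β₃u_p − γ(u_w + u_f + u_p)² + w·Δp_i + η_i,

where Δp_i is the stress-induced environmental shift and η ~ N(0, σ²).

**Anomaly detection** (`agrifuse.anomaly`). A Gaussian normal model
(mean μ, shrinkage-regularized covariance Σ) scores each zone by
s_i = D(x_i, μ) with D Euclidean or Mahalanobis; a zone is anomalous when
s_i > τ, with τ calibrated as an empirical quantile of held-out normal
scores so the false-positive rate is controlled by design.

**Multimodal fusion math** (`agrifuse.fusion`). Linear modality encoders
into a shared latent space, softmax modality weighting, spatial attention
maps (softmax over grid locations), pairwise cross-modal scaled dot-product
attention softmax(QKᵀ/√d_k)V, residual fusion F_final = F_fused + Σ_m F_m,
single-token self-attention refinement, and a temporal aggregator
(one-layer transformer by default, Elman recurrence as an option). A toy
training loop fits the modality weights plus a logistic head on simulated
stress labels.

**Resource optimization** (`agrifuse.optimize`). Maximizes
O(U) = Y(U) − λ₁C(U) − λ₂E(U) over the N×3 allocation matrix subject to
per-resource budgets and per-zone caps. O is concave, so projected gradient
ascent with an exact capped-simplex projection finds the global optimum;
every returned plan carries a projected-gradient KKT residual as a
certificate, and closed-form and brute-force oracles are cross-checked in
the tests.

**Priority allocation** (`agrifuse.allocation`). Priority scores
r_i = w_h H_i + w_y ŷ_i + w_pᵀp_i, proportional budget splits
u_i = r_i/Σr_j · B, and cap enforcement with proportional surplus
redistribution that conserves Σu = min(B, Σcaps).

**Feedback control** (`agrifuse.feedback`). A closed loop applying the
literal update rules U_i(t+1) = U_i(t) + α_r·ΔY_i(t) and
r_i(t+1) = r_i(t) + β·Δp_i(t) against the simulator, with clipping and
re-projection so feasibility is preserved at every step.

## Worked example

```python
import numpy as np
from agrifuse import (ScenarioConfig, generate_scenario, solve_constrained,
                      objective_value, train_toy_detector)

config = ScenarioConfig(n_zones=16, seed=0)
scenario = generate_scenario(config)

plan = solve_constrained(scenario.true_params, scenario.budgets,
                         scenario.caps, scenario.n_zones)
O, Y, C, E = objective_value(plan.U, scenario.true_params)
print(f"objective O = {O:.3f}  (yield {Y:.3f}, cost {C:.3f}, env impact {E:.3f})")
print(f"water allocated: {plan.U[:, 0].sum():.1f} of budget {scenario.budgets[0]:.0f}")
print(f"KKT residual: {plan.kkt_residual:.2e}")

model, result = train_toy_detector(scenario, epochs=300, lr=0.5, seed=0)
m = result.metrics
print(f"held-out detection: F1 = {m['f1']:.3f}, recall = {m['recall']:.3f}")
```

prints

```
objective O = 160.000  (yield 220.000, cost 40.000, env impact 20.000)
water allocated: 400.0 of budget 400
KKT residual: 0.00e+00
held-out detection: F1 = 0.975, recall = 0.981
```

With the default coefficients only water and fertilizer carry positive net
margins (β − λ₁c − λ₂e = 0.65, 0.35, −0.10), so the optimizer exhausts the
water budget first, spends fertilizer where marginal yield remains
positive, and applies no pesticide; the zero KKT residual certifies global
optimality of the concave program. The toy detector separates drought-
stressed zones (soil moisture displaced by four render-noise standard
deviations) from normal zones almost perfectly on held-out samples.

A command-line pipeline mirrors the library:

```
agrifuse simulate --config scenario.yaml --out runs/sim --seed 7
agrifuse detect   --config scenario.yaml --features runs/sim/features.csv --out runs/det
agrifuse allocate --config scenario.yaml --scores runs/det/scores.csv --out runs/alloc
agrifuse control  --config scenario.yaml --out runs/ctrl --steps 50
```

Every command writes a manifest (seed, config hash, version) and re-running
with the same seed reproduces each output table byte for byte.

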