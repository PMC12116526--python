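# Methods

This note records the models implemented by `agrifuse`, the conventions
and defaults chosen where the design was genuinely open, and what the
synthetic experiments do and do not establish.

## The synthetic field

The world is a field of N management zones on an R×C grid (zone k at row
k//C, column k%C; 0-based, row-major). The per-zone environmental state
p_i(t) holds soil moisture [0,1], temperature (°C), a nutrient index
[0,1] and canopy vigor [0,1] (an NDVI-like vegetation proxy; emulated,
not computed from spectral bands). Each variable follows AR(1) dynamics
around a baseline,

    p(t) = base + ρ·(p(t−1) − base) + ε(t),

with innovations spatially correlated across zones through a Gaussian
kernel K_ij = exp(−d²_ij / 2ℓ²) on grid distance (one length-scale knob
ℓ = `env_corr_length`, default 1.5 cells; ρ = 0.7, innovation sd 0.05 on
unit-interval variables, scaled ×20 for temperature). Bounded variables
are clipped to [0,1] after every update. This is the simplest correlated
field generator with a single spatial knob; it does not model
topography, soil maps, or seasonal trends.

### Stress archetypes

Four stress types are encoded as per-variable mean shifts scaled by
severity ∈ [0,1]:

| stress              | soil moisture | nutrient index | canopy vigor |
|---------------------|--------------:|---------------:|-------------:|
| drought             | −0.40         | —              | −0.30        |
| nutrient deficiency | —             | −0.50          | −0.25        |
| fungal infection    | —              | —             | −0.35        |
| insect pest         | —              | —             | −0.30        |

Magnitudes are config-exposed conventions chosen so a full-severity
event is an unambiguous, multi-sigma signal against the default sensor
noise while a mild event (severity ≲ 0.2) is not. All four depress
canopy vigor so every stress type reduces yield monotonically; fungal
infection additionally excites a lesion channel in the UAV imagery and
insect pests add texture noise there, mirroring the fact that these two
are primarily imagery-visible. The nominal (pre-clipping) shift is
accumulated separately in `EnvState.stress_delta` so downstream code can
distinguish stress-induced displacement from ordinary weather variation.

### Sensors

Satellite and UAV grids are block-upsampled zone states (2 and 4 pixels
per zone side by default — the UAV modality is strictly finer) smoothed
with a small Gaussian blur (σ = 0.5 px) and perturbed with i.i.d. noise
(sd 0.05). Ground sensors read the raw zone state plus the same noise;
the weather modality is a short AR(1) series of air temperature,
humidity, wind and precipitation shared by all zones. Real remote
sensing has georeferencing error, illumination drift, cloud occlusion
and heteroscedastic noise; none of those are modeled, so detector
results here bound what matters under clean, well-registered data only.

### Yield

Realized yield per zone is

    Y_i = β₁u_w + β₂u_f + β₃u_p − γ(u_w+u_f+u_p)² + w_env·Δp_i + η_i,

with defaults β = (0.8, 0.6, 0.4), γ = 0.01, w_env = (4, 0, 3, 5) over
(moisture, temperature, nutrient, vigor) shifts, and η ~ N(0, 0.5²).
The environmental modifier is deliberately linear in the *stress-induced
shift* Δp rather than in the raw state: the quadratic response is then
the exact closed form for unstressed noiseless realizations (asserted to
1e-12), making it the single ground truth shared by the optimizer and
the parameter-recovery study. Units are fixed by convention — water mm,
fertilizer kg/ha, pesticide L/ha, yield in index units — since none are
inherent to the math.

All randomness flows through named `SeedSequence` sub-streams of the
scenario seed (`env`, `weather`, `render`, `yield`, `dataset`), so every
scenario, trajectory, observation and yield draw is bit-reproducible.

## Anomaly detection

Normal conditions are modeled as a Gaussian fitted on normal-zone
feature vectors: μ is the column mean and

    Σ = (1 − s)·S + s·diag(S),   s = shrinkage (default 0.1),

a diagonal-target shrinkage that keeps marginal variances and
regularizes correlations for small n; positive definiteness is verified
by Cholesky and a clearer error suggests more shrinkage when it fails.
The anomaly score is either the Euclidean or (default) Mahalanobis
distance from μ. Thresholding the score at τ is equivalent, under the
fitted Gaussian, to thresholding the likelihood p(x|θ), since the
Mahalanobis score is a monotone transform of the negative log-density —
one threshold reconciles the probabilistic and distance views. τ is the
empirical q-quantile (linear interpolation, default q = 0.95) of
held-out normal scores, which directly targets a false-positive rate of
1 − q; the binomial check in the acceptance suite uses independently
drawn zones because spatially correlated zones within one snapshot
violate the i.i.d. assumption the binomial band is computed under.
Anomalous means strictly `score > τ`; ties are normal. Degenerate 0/0
metric ratios (no predicted positives, or no true positives) are
reported as 0.0 and flagged.

## Fusion stack

Each modality is flattened to tokens (grid cells, sensor locations, or
time steps) and mapped by a linear encoder and projection into a shared
d-dimensional latent space (d = 16 default; no biases, so zero input
gives zero tokens). Choices made where the formulation was open:

- **Modality weights.** The modality score is the mean entry of W_m F_m
  and weights are the softmax across modalities — the minimal reading
  that produces one convex weight per modality from a matrix-valued
  score.
- **Global fusion query.** The fused vector Σ_m C_m V_m needs a query to
  define C_m; a single learned global query token attends to each
  modality's keys, making the sum well-typed with one documented choice.
- **Residual across cardinalities.** The residual F_final = F_fused +
  Σ_m F_m adds token sets of different sizes; each modality is
  mean-pooled to one d-vector first, the only way the addition is
  well-defined without extra structure. The identity is preserved
  exactly (bitwise) and asserted.
- **Temporal default.** A one-layer self-attention encoder with
  sinusoidal positions, returning the last token; the Elman recurrence
  h_t = tanh(W_h x_t + U_h h_{t−1} + b_h) is kept as an option and for
  the recurrent contract tests.
- **Pipeline order** is encode → spatial attention → cross-modal fusion
  → temporal aggregation.

Attention everywhere is scaled dot-product softmax(QKᵀ/√d_k)V with
d_k = 8 by default; row-stochasticity, saturation behavior, key-
permutation equivariance, and agreement with a naive double-loop oracle
(≤ 8 tokens, 1e-10) are all tested.

The **toy training loop** fits the modality softmax logits plus a
logistic head by full-batch gradient descent (stable softplus loss,
analytic gradients); the random-init encoders and projections stay
frozen. This is the smallest trainable slice that exercises the fusion
weighting end to end at desk scale; it is a demonstration of
separability on clean synthetic shifts, not a claim about training the
full attention stack. Training data: drought at severity 0.5 displaces
soil moisture by 0.2 = 4 render-noise sigmas — linearly separable by
construction, so near-perfect held-out F1 is the expected outcome and
deviations from it indicate pipeline defects rather than modeling
limits.

## Resource optimization

The scalarized objective O(U) = Y − λ₁C − λ₂E is concave in U (linear
minus a positive-semidefinite per-zone quadratic), so first-order
stationarity certifies global optimality. The solver is projected
gradient ascent with fixed step 1/L, L = 6γ (the per-zone Hessian is
−2γ·J₃ with spectral norm 6γ), guaranteeing a monotone objective
sequence. Constraints decouple into three per-resource capped simplices
{0 ≤ u ≤ caps, Σu ≤ B}, each projected exactly: clip to the box, and if
the budget still binds, water-fill clip(v − τ, 0, caps) with τ found by
200 bisection steps. Iteration stops when the projected-gradient
fixed-point residual max|Π(U + ηg) − U|/η falls below `tol` (default
1e-8; the acceptance runs use 1e-10) or `max_iter` is hit, in which case
the plan is flagged unconverged. The same residual is reported as the
KKT certificate on every plan.

The unconstrained optimum has a closed form used as an oracle: with net
margins m_r = β_r − λ₁c_r − λ₂e_r, each zone puts total s* = m_max/2γ on
the argmax-margin resource (lowest index on ties), worth m²_max/4γ; if
no margin is positive the optimum is zero. Brute-force grid oracles
back both the unconstrained and the binding-budget cases; for the
binding case instances are generated so every margin stays positive at
full spend (2γ·ΣB < min β), which makes budget exhaustion provably
optimal and reduces the exhaustive search to a 3-D grid over one zone's
allocations. The trade-off surface over (λ₁, λ₂) is exposed as a
weighted-sum sweep utility rather than a vector optimizer.

## Priority allocation and feedback

Priorities r_i = w_h H_i + w_y ŷ_i + w_pᵀp_i use the convention that
higher H means worse condition, so detector anomaly scores plug in
directly and stressed zones draw more resources. Negative scores are
floored at zero before the proportional split (no negative
allocations); an all-nonpositive score vector is an error unless the
uniform fallback is requested. Cap enforcement redistributes clipped
surplus proportionally to the original scores among zones still below
cap (preserving proportionality among unconstrained zones); each pass
saturates at least one zone so at most N passes run. When every
positive-score zone is capped with budget remaining, the remainder is
water-filled uniformly over zones with headroom so conservation
Σu = min(B, Σcaps) holds for arbitrary inputs; budget exceeding total
caps is logged as an unallocated remainder.

The feedback controller applies the literal updates
u_r(t+1) = u_r(t) + α_r·ΔY(t) and r(t+1) = r(t) + β·Δp(t). The yield
update adds yield units to resource units, so α_r carries units of
resource per yield; the rule is kept as printed and feasibility is
restored after each step by clipping to [0, caps] and re-projecting a
violated budget column through the cap-and-renormalize routine with
target min(B, Σproposal) — chosen so a zero deviation is an exact fixed
point. Default gains α_r = (0.1, 0.05, 0.01) are conservative artifact
defaults: with lagged-forecast feedback the deviation dynamics contract
when |Σ_r α_r · dY/ds| < 1, and with the default response slope
(≤ m_max = 0.65) the defaults give a contraction factor ≈ 0.1; the
suite asserts the median-|ΔY| series is non-increasing there, and
non-finite states abort with a diagnostic naming α_r. The predictor is
pluggable (perfect-model oracle, constant-bias, lagged, or the learned
pipeline); priorities updated via Δp re-enter the proportional
allocation only when explicitly requested, since how they re-enter the
loop is otherwise unspecified.

## Problem sizes and scope

Default study conditions: 16 zones on a 4×4 grid; budgets (400, 200,
100) against caps (40, 25, 15) per zone, which makes the water budget
bind at the optimum; yield noise sd 0.5 on yields of order 10. The
acceptance computations use 20 two-zone instances for the grid oracle,
50 draws for the closed form, 1,000 draws for allocation conservation,
2,000 held-out zones for the false-positive rate, 20 replicates for
power, 500 (U, Y) pairs at 5%-scale noise for parameter recovery, 50
feedback steps, and 80 snapshots (640 zone-samples) for the toy
detector. These sizes were chosen so each check is statistically
decisive for the property it tests while the whole suite runs in
seconds on one CPU.

Out of scope by design: georeferenced raster formats, real NDVI from
spectral bands, process-based crop growth models, deep detection
backbones and pretrained weights, GNN spatial modeling (no defining
equations to implement), reinforcement-learning policies (the feedback
loop is the explicit update rules above), evolutionary Pareto-front
enumeration, and any external benchmark data. Passing tests establish
correctness of the implemented math and calibration under the
simulator's assumptions — Gaussian noise, linear stress signatures, a
quadratic response — not performance on real agricultural imagery or
sensor networks.
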