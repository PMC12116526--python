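"""Seeded synthetic multi-zone field simulator with known ground truth.

The simulator provides everything downstream stages are tested against:

* a field of N management zones laid out row-major on a grid, with true
  yield-response parameters, resource budgets and per-zone caps;
* an AR(1) environmental state per zone (soil moisture, temperature,
  nutrient index, canopy vigor) whose innovations are spatially
  correlated through a Gaussian kernel over grid distance;
* four injectable stress archetypes (nutrient deficiency, fungal
  infection, drought, insect pests) encoded as documented per-variable
  mean shifts scaled by severity;
* a four-modality sensor renderer (satellite grid, finer UAV grid,
  point ground sensors, weather series);
* a stochastic yield realization: the quadratic diminishing-returns
  response plus a linear stress modifier plus Gaussian disturbance.

All randomness flows through numpy ``SeedSequence`` sub-streams derived
from the scenario seed by documented stream keys, so every output is
bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage

from .config import (
    BOUNDED_VARIABLES,
    ENV_VARIABLES,
    STRESS_TYPES,
    WEATHER_VARIABLES,
    ScenarioConfig,
)
from .optimize import ObjectiveParams

__all__ = [
    "FieldScenario",
    "EnvState",
    "StressEvent",
    "MultiModalObservation",
    "STRESS_SIGNATURES",
    "stream_rng",
    "generate_scenario",
    "sample_environment",
    "inject_stress",
    "render_observations",
    "realize_yield",
    "noiseless_yield",
    "fit_yield_response",
    "zone_modality_features",
    "make_stress_dataset",
]

# Documented per-unit-severity mean shifts on the environmental state.
# Drought and nutrient deficiency act through the physical variables the
# ground sensors measure; fungal infection and insect pests act mostly on
# canopy condition (and, in rendering, on imagery texture/lesion channels).
STRESS_SIGNATURES: dict[str, dict[str, float]] = {
    "nutrient_deficiency": {"nutrient_index": -0.5, "canopy_vigor": -0.25},
    "fungal_infection": {"canopy_vigor": -0.35},
    "drought": {"soil_moisture": -0.4, "canopy_vigor": -0.3},
    "insect_pest": {"canopy_vigor": -0.3},
}

# Sub-stream keys: rng = SeedSequence((seed, _STREAMS[name], *extra))
_STREAMS = {"env": 1, "weather": 2, "render": 3, "yield": 4, "dataset": 5}

_BOUNDED_IDX = [ENV_VARIABLES.index(v) for v in BOUNDED_VARIABLES]


def stream_rng(seed: int, stream: str, *extra: int) -> np.random.Generator:
    """Named, reproducible random sub-stream for a scenario seed."""
    return np.random.default_rng(np.random.SeedSequence((int(seed), _STREAMS[stream], *map(int, extra))))


@dataclass(frozen=True)
class FieldScenario:
    """The ground-truth world: layout, response parameters, constraints."""

    n_zones: int
    grid_shape: tuple[int, int]
    true_params: ObjectiveParams
    budgets: np.ndarray  # (3,)
    caps: np.ndarray  # (N, 3)
    noise_sd: float
    env_corr_length: float
    yield_env_weights: np.ndarray  # (d_p,)
    events: tuple["StressEvent", ...]
    config: ScenarioConfig
    seed: int

    @property
    def zone_rows(self) -> np.ndarray:
        return np.arange(self.n_zones) // self.grid_shape[1]

    @property
    def zone_cols(self) -> np.ndarray:
        return np.arange(self.n_zones) % self.grid_shape[1]


@dataclass(frozen=True)
class StressEvent:
    """One stress episode on a subset of zones over [onset, onset+duration)."""

    zone_ids: tuple[int, ...]
    stress_type: str
    severity: float
    onset: int = 0
    duration: int = 1

    def __post_init__(self):
        if not self.zone_ids:
            raise ValueError("zone_ids must be nonempty")
        if self.stress_type not in STRESS_TYPES:
            raise ValueError(f"unknown stress_type {self.stress_type!r}; known: {STRESS_TYPES}")
        if not 0.0 <= self.severity <= 1.0:
            raise ValueError(f"severity must be in [0, 1], got {self.severity}")

    def active_at(self, t: int) -> bool:
        return self.onset <= t < self.onset + self.duration


@dataclass(frozen=True)
class EnvState:
    """Per-zone environmental state at one time step.

    ``p`` holds the N x d_p variable matrix (order: ENV_VARIABLES),
    ``weather`` a T_w x d_w series, and ``stress_delta`` the cumulative
    stress-induced shift applied to ``p`` (zero when unstressed) — the
    quantity the yield modifier is linear in.
    """

    t: int
    p: np.ndarray
    weather: np.ndarray
    stress_delta: np.ndarray


@dataclass(frozen=True)
class MultiModalObservation:
    """One time step's four-modality sensor snapshot."""

    X_sat: np.ndarray  # H_s x W_s x d_s
    X_uav: np.ndarray  # H_u x W_u x d_u
    X_sens: np.ndarray  # N_g x d_g
    X_weather: np.ndarray  # T_w x d_w


def generate_scenario(config: ScenarioConfig) -> FieldScenario:
    """Instantiate the ground-truth world described by a validated config.

    Deterministic given the config (including its seed): zone k maps to
    grid cell (k // cols, k % cols), row-major, 0-based.
    """
    if not isinstance(config, ScenarioConfig):
        config = ScenarioConfig.model_validate(config)
    grid = config.resolved_grid()
    params = ObjectiveParams(
        beta=config.objective.beta,
        gamma=config.objective.gamma,
        costs=config.objective.costs,
        env_costs=config.objective.env_costs,
        lambda1=config.objective.lambda1,
        lambda2=config.objective.lambda2,
    )
    caps = np.tile(np.asarray(config.cap_per_zone, dtype=float), (config.n_zones, 1))
    events = tuple(
        StressEvent(
            zone_ids=tuple(ev.zone_ids),
            stress_type=ev.stress_type,
            severity=ev.severity,
            onset=ev.onset,
            duration=ev.duration,
        )
        for ev in config.stresses
    )
    return FieldScenario(
        n_zones=config.n_zones,
        grid_shape=grid,
        true_params=params,
        budgets=np.asarray(config.budgets, dtype=float),
        caps=caps,
        noise_sd=config.noise_sd,
        env_corr_length=config.env_corr_length,
        yield_env_weights=np.asarray(config.yield_env_weights, dtype=float),
        events=events,
        config=config,
        seed=config.seed,
    )


def _spatial_chol(scenario: FieldScenario) -> np.ndarray:
    """Cholesky factor of the Gaussian-kernel correlation over grid distance."""
    rr, cc = scenario.zone_rows, scenario.zone_cols
    d2 = (rr[:, None] - rr[None, :]) ** 2 + (cc[:, None] - cc[None, :]) ** 2
    K = np.exp(-d2 / (2.0 * scenario.env_corr_length**2))
    K[np.diag_indices_from(K)] += 1e-9  # jitter for numerical PD
    return np.linalg.cholesky(K)


def sample_environment(
    scenario: FieldScenario, t: int, prev: Optional[EnvState] = None
) -> EnvState:
    """Draw the environmental state at step t.

    Each variable follows AR(1) around its baseline,
    ``p_t = base + rho * (p_{t-1} - base) + eps_t``, with innovations
    spatially correlated across zones through the Gaussian kernel
    (length scale ``env_corr_length`` in grid cells) and scaled per
    variable.  Bounded variables are clipped to [0, 1] afterwards.
    """
    if t < 0:
        raise ValueError("t must be >= 0")
    env_cfg = scenario.config.environment
    base = np.asarray(env_cfg.baseline, dtype=float)
    scales = np.asarray(env_cfg.variable_scales, dtype=float) * env_cfg.innovation_sd
    rng = stream_rng(scenario.seed, "env", t)
    L = _spatial_chol(scenario)
    eps = L @ rng.standard_normal((scenario.n_zones, len(ENV_VARIABLES))) * scales[None, :]

    if prev is None:
        p = base[None, :] + eps
    else:
        p = base[None, :] + env_cfg.ar_coefficient * (prev.p - base[None, :]) + eps
    p = p.copy()
    p[:, _BOUNDED_IDX] = np.clip(p[:, _BOUNDED_IDX], 0.0, 1.0)

    wrng = stream_rng(scenario.seed, "weather", t)
    T_w, d_w = scenario.config.render.weather_steps, len(WEATHER_VARIABLES)
    w_base = np.array([22.0, 0.6, 3.0, 0.1])
    w_scale = np.array([3.0, 0.1, 1.0, 0.2]) * max(env_cfg.innovation_sd / 0.05, 1e-12)
    weather = np.empty((T_w, d_w))
    state = w_base + w_scale * wrng.standard_normal(d_w)
    for k in range(T_w):
        state = w_base + 0.8 * (state - w_base) + w_scale * wrng.standard_normal(d_w)
        weather[k] = state
    weather[:, 3] = np.maximum(weather[:, 3], 0.0)  # precipitation is nonnegative

    return EnvState(
        t=t,
        p=p,
        weather=weather,
        stress_delta=np.zeros_like(p),
    )


def inject_stress(env: EnvState, events: Sequence[StressEvent]) -> EnvState:
    """Apply the mean-shift signatures of all events active at ``env.t``.

    Shifts are additive in severity and disjoint events commute; the
    nominal (pre-clipping) shift is accumulated in ``stress_delta`` so
    the yield modifier sees the intended stress magnitude even when a
    bounded variable saturates.
    """
    delta = np.zeros_like(env.p)
    for ev in events:
        if ev.stress_type not in STRESS_SIGNATURES:
            raise ValueError(f"unknown stress_type {ev.stress_type!r}")
        if not ev.active_at(env.t):
            continue
        sig = STRESS_SIGNATURES[ev.stress_type]
        ids = np.asarray(ev.zone_ids, dtype=int)
        for var, shift in sig.items():
            delta[ids, ENV_VARIABLES.index(var)] += shift * ev.severity
    p = env.p + delta
    p = p.copy()
    p[:, _BOUNDED_IDX] = np.clip(p[:, _BOUNDED_IDX], 0.0, 1.0)
    return replace(env, p=p, stress_delta=env.stress_delta + delta)


def _zone_channel_image(values: np.ndarray, grid: tuple[int, int], px: int) -> np.ndarray:
    """Upsample per-zone channel values (N x d) to a (rows*px, cols*px, d) image."""
    rows, cols = grid
    img = values.reshape(rows, cols, -1)
    return np.kron(img, np.ones((px, px, 1)))


def _active_severity(events: Sequence[StressEvent], t: int, n_zones: int, types: tuple[str, ...]) -> np.ndarray:
    sev = np.zeros(n_zones)
    for ev in events:
        if ev.stress_type in types and ev.active_at(t):
            sev[np.asarray(ev.zone_ids, dtype=int)] += ev.severity
    return sev


def render_observations(
    scenario: FieldScenario,
    env: EnvState,
    events: Sequence[StressEvent] = (),
    seed: int = 0,
) -> MultiModalObservation:
    """Render the four-modality sensor snapshot for one time step.

    Satellite and UAV grids are zone-state-driven smooth fields (block
    upsampling followed by a small Gaussian blur) plus i.i.d. sensor
    noise; the UAV grid is strictly finer and carries a lesion channel
    excited by fungal infection, with insect pests adding extra texture
    noise inside affected blocks.  Ground sensors read the raw zone state
    plus noise; the weather modality copies the environment's series.
    """
    cfg = scenario.config.render
    rng = stream_rng(scenario.seed, "render", int(seed))
    grid = scenario.grid_shape
    t = env.t

    moisture = env.p[:, ENV_VARIABLES.index("soil_moisture")]
    temp = env.p[:, ENV_VARIABLES.index("temperature")]
    nutrient = env.p[:, ENV_VARIABLES.index("nutrient_index")]
    vigor = env.p[:, ENV_VARIABLES.index("canopy_vigor")]

    sat_channels = np.stack([vigor, moisture, nutrient, temp / 40.0], axis=1)
    X_sat = _zone_channel_image(sat_channels, grid, cfg.sat_px_per_zone)
    if cfg.smooth_sigma > 0:
        X_sat = ndimage.gaussian_filter(X_sat, sigma=(cfg.smooth_sigma, cfg.smooth_sigma, 0))
    X_sat = X_sat + cfg.noise_sd * rng.standard_normal(X_sat.shape)

    fungal = _active_severity(events, t, scenario.n_zones, ("fungal_infection",))
    insect = _active_severity(events, t, scenario.n_zones, ("insect_pest",))
    uav_channels = np.stack([vigor, moisture, 0.8 * fungal], axis=1)
    X_uav = _zone_channel_image(uav_channels, grid, cfg.uav_px_per_zone)
    if cfg.smooth_sigma > 0:
        X_uav = ndimage.gaussian_filter(X_uav, sigma=(cfg.smooth_sigma, cfg.smooth_sigma, 0))
    X_uav = X_uav + cfg.noise_sd * rng.standard_normal(X_uav.shape)
    if np.any(insect > 0):
        texture = _zone_channel_image(insect[:, None], grid, cfg.uav_px_per_zone)
        X_uav = X_uav + 0.3 * texture * rng.standard_normal(X_uav.shape)

    X_sens = env.p + cfg.noise_sd * rng.standard_normal(env.p.shape)
    return MultiModalObservation(
        X_sat=X_sat, X_uav=X_uav, X_sens=X_sens, X_weather=env.weather.copy()
    )


def noiseless_yield(scenario: FieldScenario, U: np.ndarray, env: Optional[EnvState] = None) -> np.ndarray:
    """Per-zone expected yield: quadratic response plus stress modifier."""
    U = np.asarray(U, dtype=float)
    if U.ndim != 2 or U.shape != (scenario.n_zones, 3):
        raise ValueError(f"U must be {scenario.n_zones} x 3, got {U.shape}")
    if np.any(U < 0):
        raise ValueError("allocations must be nonnegative")
    beta = np.asarray(scenario.true_params.beta)
    s = U.sum(axis=1)
    Y = U @ beta - scenario.true_params.gamma * s**2
    if env is not None:
        Y = Y + env.stress_delta @ scenario.yield_env_weights
    return Y


def realize_yield(
    scenario: FieldScenario,
    U: np.ndarray,
    env: Optional[EnvState] = None,
    seed: int = 0,
) -> np.ndarray:
    """Stochastic per-zone yield realization.

    ``Y_i = beta1 u_w + beta2 u_f + beta3 u_p - gamma (u_w+u_f+u_p)^2
    + w_env . stress_delta_i + eta_i`` with eta ~ N(0, noise_sd^2).
    The modifier is linear in the stress-induced environmental shift, so
    an unstressed noiseless realization equals the closed-form response
    exactly.
    """
    Y = noiseless_yield(scenario, U, env)
    if scenario.noise_sd > 0:
        rng = stream_rng(scenario.seed, "yield", int(seed))
        Y = Y + scenario.noise_sd * rng.standard_normal(scenario.n_zones)
    return Y


def fit_yield_response(U_samples: np.ndarray, Y: np.ndarray) -> tuple[np.ndarray, float]:
    """Least-squares recovery of (beta1..beta3, gamma) from (U, Y) pairs.

    The response is linear in its parameters with design
    [u_w, u_f, u_p, -(u_w+u_f+u_p)^2]; returns (beta_hat, gamma_hat).
    """
    U_samples = np.asarray(U_samples, dtype=float).reshape(-1, 3)
    Y = np.asarray(Y, dtype=float).ravel()
    if len(U_samples) != len(Y):
        raise ValueError("U and Y must have matching length")
    s = U_samples.sum(axis=1)
    X = np.column_stack([U_samples, -(s**2)])
    coef, *_ = np.linalg.lstsq(X, Y, rcond=None)
    return coef[:3], float(coef[3])


def zone_modality_features(
    scenario: FieldScenario, obs: MultiModalObservation
) -> dict[str, np.ndarray]:
    """Per-zone feature vectors for each modality (N x d_m each).

    Spatial grids are mean-pooled over each zone's pixel block; the
    weather series is summarized by its channel means and std-devs and
    broadcast to all zones (it is a field-level signal).
    """
    cfg = scenario.config.render
    rows, cols = scenario.grid_shape

    def pool(img, px):
        h = img.reshape(rows, px, cols, px, img.shape[-1])
        return h.mean(axis=(1, 3)).reshape(scenario.n_zones, -1)

    w_summary = np.concatenate([obs.X_weather.mean(axis=0), obs.X_weather.std(axis=0)])
    return {
        "sat": pool(obs.X_sat, cfg.sat_px_per_zone),
        "uav": pool(obs.X_uav, cfg.uav_px_per_zone),
        "ground": obs.X_sens.copy(),
        "weather": np.tile(w_summary, (scenario.n_zones, 1)),
    }


def make_stress_dataset(
    scenario: FieldScenario,
    n_samples: int = 200,
    severity: float = 0.5,
    stress_type: str = "drought",
    seed: int = 0,
    stress_fraction: float = 0.5,
):
    """Labeled per-zone multimodal samples for detector training/evaluation.

    Each sample draws a fresh environment, stresses a random subset of
    zones at the given severity, renders the sensors, and pools per-zone
    modality features.  With the default render noise (sd 0.05) a drought
    at severity 0.5 displaces the soil-moisture coordinate by 0.2 = 4
    noise-sd, i.e. a linearly separable 4-sigma shift.

    Returns ``(features, labels)`` where ``features`` maps modality name
    to an (n_samples * N) x d_m matrix and ``labels`` is the matching
    0/1 stress indicator.
    """
    rng = stream_rng(scenario.seed, "dataset", int(seed))
    feats: dict[str, list[np.ndarray]] = {m: [] for m in ("sat", "uav", "ground", "weather")}
    labels = []
    n_stressed = int(round(stress_fraction * scenario.n_zones))
    if stress_fraction > 0 and severity > 0:
        n_stressed = max(1, n_stressed)
    for k in range(n_samples):
        env = sample_environment(scenario, t=int(rng.integers(0, 2**20)))
        stressed = rng.choice(scenario.n_zones, size=n_stressed, replace=False)
        events = (
            [
                StressEvent(
                    zone_ids=tuple(int(z) for z in stressed),
                    stress_type=stress_type,
                    severity=severity,
                    onset=env.t,
                    duration=1,
                )
            ]
            if n_stressed and severity > 0
            else []
        )
        env_s = inject_stress(env, events)
        obs = render_observations(scenario, env_s, events, seed=int(rng.integers(0, 2**31)))
        zf = zone_modality_features(scenario, obs)
        for m in feats:
            feats[m].append(zf[m])
        y = np.zeros(scenario.n_zones, dtype=int)
        y[stressed] = 1
        labels.append(y)
    features = {m: np.concatenate(v, axis=0) for m, v in feats.items()}
    return features, np.concatenate(labels)
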