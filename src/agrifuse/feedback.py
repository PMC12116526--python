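"""Closed-loop feedback control of per-zone resource allocations.

At each step the controller compares the observed yield and environment
with a predictor's forecast, then applies the literal update rules

    dY_i(t)   = Y_i_obs(t) - yhat_i(t)
    u_i,r(t+1) = u_i,r(t) + alpha_r * dY_i(t)        (then re-projected)
    dp_i(t)   = p_i_obs(t) - p_i_pred(t)
    r_i(t+1)  = r_i(t) + beta . dp_i(t)

The yield-deviation update adds yield units to resource units, so the
resource-specific learning rates alpha_r carry units of resource per
yield, and every update is clipped to nonnegativity and re-projected
onto caps and budgets — a zero deviation is an exact fixed point.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd

from .allocation import cap_and_renormalize
from .config import RESOURCES
from .synthetic_field import (
    EnvState,
    FieldScenario,
    inject_stress,
    noiseless_yield,
    realize_yield,
    sample_environment,
)

__all__ = [
    "ControllerState",
    "Trajectory",
    "PerfectPredictor",
    "BiasedPredictor",
    "LaggedPredictor",
    "compute_deviations",
    "update_allocation",
    "update_priorities",
    "run_closed_loop",
]


@dataclass
class ControllerState:
    """Feedback gains: per-resource learning rates and the priority map."""

    alpha_r: np.ndarray = None  # (3,) resource-specific learning rates
    beta_vec: np.ndarray = None  # (d_p,) env-deviation -> priority map
    alpha: Optional[float] = None  # optional global rate overriding alpha_r

    def __post_init__(self):
        a = np.asarray(
            [0.1, 0.05, 0.01] if self.alpha_r is None else self.alpha_r, dtype=float
        )
        if a.shape != (3,) or np.any(a < 0):
            raise ValueError("alpha_r must be 3 nonnegative rates (water, fertilizer, pesticide)")
        if self.alpha is not None:
            if self.alpha < 0:
                raise ValueError("alpha must be nonnegative")
            a = np.full(3, float(self.alpha))
        b = np.zeros(0) if self.beta_vec is None else np.asarray(self.beta_vec, dtype=float)
        object.__setattr__(self, "alpha_r", a)
        object.__setattr__(self, "beta_vec", b)


@dataclass
class Trajectory:
    """Closed-loop history: one record per step, fully reproducible."""

    records: list[dict] = field(default_factory=list)

    def to_dataframe(self) -> pd.DataFrame:
        """Long-format frame: t, zone_id, resource, u, y_obs, y_hat, dY, r."""
        rows = []
        for rec in self.records:
            N = rec["U"].shape[0]
            for i in range(N):
                for k, res in enumerate(RESOURCES):
                    rows.append(
                        {
                            "t": rec["t"],
                            "zone_id": i,
                            "resource": res,
                            "u": rec["U"][i, k],
                            "y_obs": rec["Y_obs"][i],
                            "y_hat": rec["y_hat"][i],
                            "dY": rec["dY"][i],
                            "r": rec["r"][i],
                        }
                    )
        return pd.DataFrame(rows)

    @property
    def abs_deviation_series(self) -> np.ndarray:
        """Median |dY| over zones, per step (convergence diagnostic)."""
        return np.array([np.median(np.abs(rec["dY"])) for rec in self.records])


def compute_deviations(Y_obs, y_hat, p_obs, p_pred):
    """Elementwise observation-minus-prediction deviations (dY, dp)."""
    Y_obs = np.asarray(Y_obs, dtype=float)
    y_hat = np.asarray(y_hat, dtype=float)
    p_obs = np.asarray(p_obs, dtype=float)
    p_pred = np.asarray(p_pred, dtype=float)
    if Y_obs.shape != y_hat.shape:
        raise ValueError(f"yield shape mismatch: {Y_obs.shape} vs {y_hat.shape}")
    if p_obs.shape != p_pred.shape:
        raise ValueError(f"environment shape mismatch: {p_obs.shape} vs {p_pred.shape}")
    return Y_obs - y_hat, p_obs - p_pred


def update_allocation(
    U_t: np.ndarray,
    dY: np.ndarray,
    state: ControllerState,
    caps: np.ndarray,
    budgets: Sequence[float],
) -> np.ndarray:
    """One feedback step on the allocation matrix, feasibility preserved.

    Per resource r: u(t+1) = u(t) + alpha_r * dY, clipped to [0, cap] and,
    if the column then exceeds its budget, re-projected through
    ``cap_and_renormalize`` with target min(budget, sum(proposal)) — so
    a feasible proposal (in particular dY = 0) passes through unchanged.
    """
    U_t = np.asarray(U_t, dtype=float)
    dY = np.asarray(dY, dtype=float)
    if U_t.ndim != 2 or U_t.shape[1] != 3:
        raise ValueError(f"U_t must be N x 3, got {U_t.shape}")
    if dY.shape != (U_t.shape[0],):
        raise ValueError("dY must be one deviation per zone")
    caps_m = np.broadcast_to(np.asarray(caps, dtype=float), U_t.shape)
    U_next = np.empty_like(U_t)
    for k in range(3):
        u = np.clip(U_t[:, k] + state.alpha_r[k] * dY, 0.0, caps_m[:, k])
        total = float(u.sum())
        if total > float(budgets[k]) + 1e-12:
            u = cap_and_renormalize(u, caps_m[:, k], min(float(budgets[k]), total))
        U_next[:, k] = u
    return U_next


def update_priorities(r_t: np.ndarray, dp: np.ndarray, beta_vec: np.ndarray) -> np.ndarray:
    """r(t+1) = r(t) + dp . beta, per zone (additive across deviations)."""
    r_t = np.asarray(r_t, dtype=float)
    dp = np.atleast_2d(np.asarray(dp, dtype=float))
    beta_vec = np.asarray(beta_vec, dtype=float)
    if dp.shape[0] != r_t.shape[0]:
        raise ValueError(f"dp has {dp.shape[0]} zones, priorities have {r_t.shape[0]}")
    if dp.shape[1] != beta_vec.shape[0]:
        raise ValueError(f"beta_vec dim {beta_vec.shape[0]} != dp dim {dp.shape[1]}")
    return r_t + dp @ beta_vec


class PerfectPredictor:
    """Oracle predictor: the scenario's own noiseless response and state."""

    def __call__(self, scenario: FieldScenario, U: np.ndarray, env: EnvState):
        return noiseless_yield(scenario, U, env), env.p.copy()


class BiasedPredictor:
    """Perfect model shifted by a constant bias (for sign analyses)."""

    def __init__(self, bias: float = -1.0):
        self.bias = float(bias)

    def __call__(self, scenario, U, env):
        return noiseless_yield(scenario, U, env) + self.bias, env.p.copy()


class LaggedPredictor:
    """Predicts this step's yield as the previous observation."""

    def __init__(self):
        self._last: Optional[np.ndarray] = None

    def __call__(self, scenario, U, env):
        y = noiseless_yield(scenario, U, env) if self._last is None else self._last
        return y, env.p.copy()

    def observe(self, Y_obs: np.ndarray) -> None:
        self._last = np.asarray(Y_obs, dtype=float).copy()


def run_closed_loop(
    scenario: FieldScenario,
    initial_plan: np.ndarray,
    state: ControllerState,
    T: int,
    predictor: Optional[Callable] = None,
    seed: int = 0,
) -> Trajectory:
    """Run the feedback loop against the simulator for T steps.

    Each step samples the environment (AR chain), applies the scenario's
    stress events, realizes the yield for the current allocation,
    computes deviations against the predictor, and applies the
    allocation and priority updates.  Deterministic given seed; every
    logged plan is feasible.  Exploding updates (non-finite state) abort
    with a diagnostic naming alpha_r.
    """
    if T < 1:
        raise ValueError("T must be >= 1")
    predictor = predictor or PerfectPredictor()
    U = np.asarray(initial_plan, dtype=float).copy()
    if U.shape != (scenario.n_zones, 3):
        raise ValueError(f"initial plan must be {scenario.n_zones} x 3, got {U.shape}")
    if np.any(U < 0):
        raise ValueError("initial plan must be nonnegative")

    beta_vec = state.beta_vec
    if beta_vec.size == 0:
        beta_vec = np.zeros(len(scenario.config.environment.baseline))
    r = np.zeros(scenario.n_zones)
    traj = Trajectory()
    env: Optional[EnvState] = None
    for t in range(T):
        env = sample_environment(scenario, t, env)
        env = inject_stress(env, scenario.events)
        Y_obs = realize_yield(scenario, U, env, seed=seed * 100_003 + t)
        y_hat, p_pred = predictor(scenario, U, env)
        dY, dp = compute_deviations(Y_obs, y_hat, env.p, p_pred)
        if hasattr(predictor, "observe"):
            predictor.observe(Y_obs)
        traj.records.append(
            {
                "t": t,
                "U": U.copy(),
                "Y_obs": Y_obs,
                "y_hat": y_hat,
                "dY": dY,
                "dp": dp,
                "r": r.copy(),
            }
        )
        U = update_allocation(U, dY, state, scenario.caps, scenario.budgets)
        r = update_priorities(r, dp, beta_vec)
        if not (np.all(np.isfinite(U)) and np.all(np.isfinite(r))):
            raise FloatingPointError(
                f"feedback state became non-finite at t={t}; "
                f"reduce the learning rates alpha_r={state.alpha_r.tolist()}"
            )
    return traj
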