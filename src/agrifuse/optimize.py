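"""Multi-objective resource allocation under budget and cap constraints.

The scalarized objective over an N x 3 allocation matrix U (columns:
water, fertilizer, pesticide) is

    O(U) = Y(U) - lambda1 * C(U) - lambda2 * E(U)

with a diminishing-returns yield response per zone i,

    Y_i = beta1 u_w + beta2 u_f + beta3 u_p - gamma (u_w + u_f + u_p)^2,

linear resource cost C and linear environmental impact E.  O is concave
in U (linear terms minus a positive-semidefinite quadratic), so any
feasible first-order stationary point is globally optimal; the solver is
projected gradient ascent with an exact per-resource projection onto the
capped simplex {0 <= u <= caps, sum(u) <= B} and the returned plan
carries a projected-gradient (KKT) residual as an optimality certificate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "ObjectiveParams",
    "AllocationPlan",
    "objective_value",
    "objective_gradient",
    "analytic_unconstrained_optimum",
    "project_capped_simplex",
    "project_feasible",
    "solve_constrained",
    "pareto_sweep",
]


@dataclass(frozen=True)
class ObjectiveParams:
    """Coefficients of the scalarized yield/cost/environment objective."""

    beta: tuple[float, float, float] = (0.8, 0.6, 0.4)
    gamma: float = 0.01
    costs: tuple[float, float, float] = (0.1, 0.15, 0.2)
    env_costs: tuple[float, float, float] = (0.05, 0.1, 0.3)
    lambda1: float = 1.0
    lambda2: float = 1.0

    def __post_init__(self):
        if self.gamma <= 0:
            raise ValueError(f"gamma must be > 0, got {self.gamma}")
        for name in ("costs", "env_costs"):
            if any(v < 0 for v in getattr(self, name)):
                raise ValueError(f"{name} must be nonnegative")
        if self.lambda1 < 0 or self.lambda2 < 0:
            raise ValueError("lambda1 and lambda2 must be nonnegative")

    @property
    def margins(self) -> np.ndarray:
        """Net margin per resource: beta_r - lambda1 c_r - lambda2 e_r."""
        return (
            np.asarray(self.beta)
            - self.lambda1 * np.asarray(self.costs)
            - self.lambda2 * np.asarray(self.env_costs)
        )


@dataclass
class AllocationPlan:
    """An N x 3 resource allocation with feasibility metadata."""

    U: np.ndarray
    feasible: bool = True
    binding: dict = field(default_factory=dict)
    converged: bool = True
    kkt_residual: Optional[float] = None
    objective: Optional[float] = None
    history: Optional[list] = None  # per-iteration objective values, when recorded

    def __post_init__(self):
        self.U = np.asarray(self.U, dtype=float)
        if self.U.ndim != 2 or self.U.shape[1] != 3:
            raise ValueError(f"allocation must be N x 3, got shape {self.U.shape}")


def _check_allocation(U: np.ndarray) -> np.ndarray:
    U = np.asarray(U, dtype=float)
    if U.ndim != 2 or U.shape[1] != 3:
        raise ValueError(f"allocation must be N x 3, got shape {U.shape}")
    if np.any(U < 0):
        raise ValueError("allocation entries must be nonnegative")
    return U


def objective_value(U: np.ndarray, params: ObjectiveParams):
    """Evaluate (O, Y, C, E) for an allocation.

    Returns the scalarized objective O = Y - lambda1*C - lambda2*E along
    with its yield, cost, and environmental-impact components.
    """
    U = _check_allocation(U)
    beta = np.asarray(params.beta)
    s = U.sum(axis=1)
    Y = float((U @ beta).sum() - params.gamma * (s**2).sum())
    C = float((U @ np.asarray(params.costs)).sum())
    E = float((U @ np.asarray(params.env_costs)).sum())
    O = Y - params.lambda1 * C - params.lambda2 * E
    return O, Y, C, E


def objective_gradient(U: np.ndarray, params: ObjectiveParams) -> np.ndarray:
    """dO/dU: margin per resource minus 2*gamma*(zone total), per entry."""
    U = np.asarray(U, dtype=float)
    s = U.sum(axis=1, keepdims=True)
    return params.margins[None, :] - 2.0 * params.gamma * s


def analytic_unconstrained_optimum(params: ObjectiveParams, n_zones: int = 1) -> AllocationPlan:
    """Closed-form optimum of O without budgets or caps.

    Per zone the objective reduces to m.u - gamma*(sum u)^2 with net
    margins m; all mass goes on the argmax-margin resource (lowest index
    on ties) at total s* = m_max / (2 gamma), worth m_max^2 / (4 gamma)
    per zone.  If every margin is <= 0 the optimum is U = 0.
    """
    m = params.margins
    U = np.zeros((n_zones, 3))
    k = int(np.argmax(m))  # argmax returns the lowest index on ties
    if m[k] > 0:
        U[:, k] = m[k] / (2.0 * params.gamma)
    O, _, _, _ = objective_value(U, params)
    return AllocationPlan(U=U, feasible=True, kkt_residual=0.0, objective=O)


def project_capped_simplex(v: np.ndarray, caps: np.ndarray, total: float) -> np.ndarray:
    """Euclidean projection of v onto {u : 0 <= u <= caps, sum(u) <= total}.

    If clipping to the box already satisfies the budget the clip is the
    projection; otherwise the projection lies on sum(u) = total and is
    clip(v - tau, 0, caps) for the unique tau >= 0 found by bisection
    (water-filling over the cap breakpoints).
    """
    v = np.asarray(v, dtype=float)
    caps = np.broadcast_to(np.asarray(caps, dtype=float), v.shape)
    if total < 0:
        raise ValueError("budget must be nonnegative")
    u = np.clip(v, 0.0, caps)
    if u.sum() <= total:
        return u
    lo, hi = 0.0, float(np.max(v))
    for _ in range(200):
        tau = 0.5 * (lo + hi)
        if np.clip(v - tau, 0.0, caps).sum() > total:
            lo = tau
        else:
            hi = tau
    u = np.clip(v - hi, 0.0, caps)
    # hi-side guarantees sum <= total up to float error
    return u


def project_feasible(U: np.ndarray, caps: np.ndarray, budgets: Sequence[float]) -> np.ndarray:
    """Project an N x 3 matrix onto the feasible set, column by column.

    Constraints couple entries only within a resource column (its budget)
    plus elementwise boxes, so the joint projection decomposes exactly
    into three capped-simplex projections.
    """
    U = np.asarray(U, dtype=float)
    caps = np.broadcast_to(np.asarray(caps, dtype=float), U.shape)
    out = np.empty_like(U)
    for r in range(3):
        out[:, r] = project_capped_simplex(U[:, r], caps[:, r], float(budgets[r]))
    return out


def _pg_residual(U, g, step, caps, budgets):
    return float(np.max(np.abs(project_feasible(U + step * g, caps, budgets) - U)) / step)


def solve_constrained(
    params: ObjectiveParams,
    budgets: Sequence[float],
    caps: np.ndarray | float,
    n_zones: int,
    tol: float = 1e-8,
    max_iter: int = 10_000,
    U0: Optional[np.ndarray] = None,
    record_history: bool = False,
) -> AllocationPlan:
    """Projected gradient ascent on O over the budget/cap polytope.

    The gradient is 6*gamma-Lipschitz (per-zone Hessian -2*gamma*J_3), so
    a fixed step 1/(6*gamma) guarantees monotone ascent.  Iterations stop
    when the projected-gradient fixed-point residual falls below ``tol``
    (scaled by the step); since O is concave this residual certifies
    global optimality.  A plan that exhausts ``max_iter`` is returned
    with ``converged=False``.
    """
    budgets = np.asarray(budgets, dtype=float)
    if np.any(budgets < 0):
        raise ValueError("budgets must be nonnegative")
    caps_m = np.broadcast_to(np.asarray(caps, dtype=float), (n_zones, 3)).copy()
    if np.any(caps_m < 0):
        raise ValueError("caps must be nonnegative")

    step = 1.0 / (6.0 * params.gamma)
    U = (
        project_feasible(U0, caps_m, budgets)
        if U0 is not None
        else np.zeros((n_zones, 3))
    )
    converged = False
    residual = np.inf
    history: Optional[list] = [] if record_history else None
    for _ in range(max_iter):
        g = objective_gradient(U, params)
        U_next = project_feasible(U + step * g, caps_m, budgets)
        residual = float(np.max(np.abs(U_next - U)) / step)
        U = U_next
        if history is not None:
            history.append(objective_value(U, params)[0])
        if residual < tol:
            converged = True
            break

    O, _, _, _ = objective_value(U, params)
    g = objective_gradient(U, params)
    kkt = _pg_residual(U, g, step, caps_m, budgets)
    atol = 1e-9
    binding = {
        "budget": [r for r in range(3) if U[:, r].sum() >= budgets[r] - atol],
        "cap": [tuple(ix) for ix in np.argwhere(U >= caps_m - atol)],
        "zero": [tuple(ix) for ix in np.argwhere(U <= atol)],
    }
    return AllocationPlan(
        U=U,
        feasible=True,
        binding=binding,
        converged=converged,
        kkt_residual=kkt,
        objective=O,
        history=history,
    )


def pareto_sweep(
    params: ObjectiveParams,
    budgets: Sequence[float],
    caps: np.ndarray | float,
    n_zones: int,
    lambda1_grid: Sequence[float],
    lambda2_grid: Sequence[float],
    **solver_kwargs,
) -> list[dict]:
    """Trace the weighted-sum trade-off surface over a (lambda1, lambda2) grid.

    Returns one record per grid point with the solved plan's (Y, C, E, O).
    """
    records = []
    for l1 in lambda1_grid:
        for l2 in lambda2_grid:
            p = ObjectiveParams(
                beta=params.beta,
                gamma=params.gamma,
                costs=params.costs,
                env_costs=params.env_costs,
                lambda1=float(l1),
                lambda2=float(l2),
            )
            plan = solve_constrained(p, budgets, caps, n_zones, **solver_kwargs)
            O, Y, C, E = objective_value(plan.U, p)
            records.append(
                {"lambda1": float(l1), "lambda2": float(l2), "O": O, "Y": Y, "C": C, "E": E, "plan": plan}
            )
    return records
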