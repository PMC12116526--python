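"""Priority scoring and budget-proportional allocation with per-zone caps.

Each zone gets a priority score r_i = w_h H_i + w_y yhat_i + w_p . p_i
(crop-health estimate, predicted yield, environmental state); a resource
budget B is then split proportionally, u_i = r_i / sum_j r_j * B.  Caps
are enforced by iterative surplus redistribution: clip to the cap,
redistribute the clipped surplus proportionally to the original scores
among zones still below cap, and repeat — each pass saturates at least
one zone, so the loop terminates within N passes, conserving
sum(u) = min(B, sum(caps)).

Sign conventions: higher H means worse condition (an anomaly score plugs
in directly), and negative priorities are floored at zero before the
proportional split — a zone cannot receive a negative allocation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

__all__ = [
    "ZoneAssessment",
    "PriorityWeights",
    "priority_scores",
    "proportional_allocation",
    "cap_and_renormalize",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ZoneAssessment:
    """Per-zone inputs to the priority score (consistent length N)."""

    H: np.ndarray  # crop-health estimate; higher = worse condition
    y_hat: np.ndarray  # predicted yield
    p: np.ndarray  # N x d_p environmental matrix

    def __post_init__(self):
        H = np.asarray(self.H, dtype=float)
        y = np.asarray(self.y_hat, dtype=float)
        p = np.atleast_2d(np.asarray(self.p, dtype=float))
        if not (H.shape[0] == y.shape[0] == p.shape[0]):
            raise ValueError(
                f"inconsistent zone counts: H={H.shape[0]}, y_hat={y.shape[0]}, p={p.shape[0]}"
            )
        if not (np.all(np.isfinite(H)) and np.all(np.isfinite(y)) and np.all(np.isfinite(p))):
            raise ValueError("assessment entries must be finite")
        object.__setattr__(self, "H", H)
        object.__setattr__(self, "y_hat", y)
        object.__setattr__(self, "p", p)


@dataclass(frozen=True)
class PriorityWeights:
    w_h: float = 1.0
    w_y: float = 0.0
    w_p: np.ndarray = None  # d_p-vector

    def __post_init__(self):
        wp = np.zeros(0) if self.w_p is None else np.asarray(self.w_p, dtype=float)
        object.__setattr__(self, "w_p", wp)


def priority_scores(assess: ZoneAssessment, weights: PriorityWeights) -> np.ndarray:
    """r_i = w_h H_i + w_y yhat_i + w_p . p_i, per zone."""
    wp = weights.w_p
    if wp.size == 0:
        wp = np.zeros(assess.p.shape[1])
    if wp.shape[0] != assess.p.shape[1]:
        raise ValueError(
            f"w_p has dim {wp.shape[0]} but environmental vectors have dim {assess.p.shape[1]}"
        )
    return weights.w_h * assess.H + weights.w_y * assess.y_hat + assess.p @ wp


def proportional_allocation(
    r: np.ndarray, budget: float, fallback: str = "error"
) -> np.ndarray:
    """Split a budget proportionally to (nonnegative-floored) priorities.

    u_i = r_i^+ / sum_j r_j^+ * B, summing exactly to B.  If every score
    is <= 0 the split is undefined; ``fallback='uniform'`` divides B
    equally, otherwise a ValueError prescribes that option.
    """
    r = np.asarray(r, dtype=float)
    if budget < 0:
        raise ValueError("budget must be nonnegative")
    rp = np.maximum(r, 0.0)
    tot = rp.sum()
    if tot <= 0:
        if fallback == "uniform":
            return np.full(r.shape, budget / r.size)
        raise ValueError(
            "all priority scores are <= 0; pass fallback='uniform' for an equal split"
        )
    return rp / tot * budget


def cap_and_renormalize(
    u: np.ndarray,
    caps: np.ndarray | float,
    budget: float,
    r: np.ndarray | None = None,
) -> np.ndarray:
    """Enforce per-zone caps, redistributing clipped surplus by priority.

    Starting from a desired allocation ``u`` (weights default to ``u``
    itself, i.e. the original proportional scores), the returned vector
    satisfies 0 <= out <= caps elementwise and
    ``sum(out) = min(budget, sum(caps))`` to float precision.  Surplus
    clipped at a cap is redistributed proportionally to the original
    scores among zones still below cap; when all positive-score zones
    saturate, any remainder is water-filled uniformly over zones with
    headroom.  Each pass saturates at least one zone, so at most N
    passes run.
    """
    u = np.asarray(u, dtype=float)
    caps_v = np.broadcast_to(np.asarray(caps, dtype=float), u.shape).astype(float)
    if np.any(caps_v < 0):
        raise ValueError("caps must be nonnegative")
    if budget < 0:
        raise ValueError("budget must be nonnegative")
    w = np.maximum(np.asarray(u if r is None else r, dtype=float), 0.0)

    target = min(float(budget), float(caps_v.sum()))
    out = np.zeros_like(u)
    remaining = target
    active = w > 0
    for _ in range(u.size):
        active = active & (out < caps_v - 1e-15)
        if remaining <= 1e-15 or not active.any():
            break
        share = np.zeros_like(u)
        share[active] = w[active] / w[active].sum() * remaining
        trial = out + share
        over = trial > caps_v
        if not over.any():
            out = trial
            remaining = 0.0
            break
        out[over] = caps_v[over]
        out[~over] = trial[~over]
        out = np.minimum(out, caps_v)
        remaining = target - out.sum()

    if remaining > 1e-12:
        # all priority-positive zones capped; water-fill the remainder
        # uniformly over zones with headroom so the budget is conserved
        for _ in range(u.size):
            head = caps_v - out
            free = head > 1e-15
            if remaining <= 1e-12 or not free.any():
                break
            add = np.zeros_like(u)
            add[free] = remaining / free.sum()
            grant = np.minimum(add, head)
            out = out + grant
            remaining -= grant.sum()

    if float(budget) > caps_v.sum():
        logger.info(
            "budget %.6g exceeds total caps %.6g; %.6g left unallocated",
            float(budget), float(caps_v.sum()), float(budget) - caps_v.sum(),
        )
    # exact conservation up to accumulated float error
    return out
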