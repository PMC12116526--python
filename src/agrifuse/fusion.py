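"""Multimodal attention fusion at desk scale (CPU, small dense tensors).

The stack mirrors a multimodal sensor-fusion network: modality-specific
linear encoders and projections into a shared latent space of dimension
d, softmax modality weighting, spatial attention over image grids,
cross-modal scaled dot-product attention, a residual fusion step, a
single-token self-attention refinement, and a temporal aggregator
(one-layer transformer encoder by default, an Elman-style recurrence as
the alternative).  Everything is plain numpy; the toy training loop
fits the modality weights and a linear head by full-batch gradient
descent on synthetic stress labels.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .anomaly import classify_and_evaluate
from .synthetic_field import FieldScenario, MultiModalObservation, make_stress_dataset

__all__ = [
    "EncoderParams",
    "FusedRepresentation",
    "softmax",
    "encode_and_project",
    "modality_weights",
    "spatial_attention",
    "temporal_aggregate",
    "cross_modal_attention",
    "cross_modal_fuse",
    "fused_zone_matrix",
    "train_toy_detector",
]

MODALITIES = ("sat", "uav", "ground", "weather")


def softmax(x: np.ndarray, axis: int = -1) -> np.ndarray:
    """Numerically stable softmax along an axis; rows sum to one."""
    x = np.asarray(x, dtype=float)
    z = x - np.max(x, axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


@dataclass
class EncoderParams:
    """All learnable tensors of the fusion stack.

    ``E`` and ``P`` are per-modality encoder (d_in -> d) and projection
    (d -> d) maps; ``W_score`` feeds the modality softmax; ``w_spatial``
    is the 1x1-conv scalar scorer for spatial attention; ``W_q``/``W_k``
    (d x d_k) and ``W_v`` (d x d) drive every attention block, with a
    learned global query ``q_global`` (d_k) for the modality-sum fusion;
    ``W_h``/``U_h``/``b_h`` parameterize the recurrent temporal option.
    """

    d: int
    d_k: int
    E: dict[str, np.ndarray]
    P: dict[str, np.ndarray]
    W_score: dict[str, np.ndarray]
    w_spatial: dict[str, np.ndarray]
    W_q: np.ndarray
    W_k: np.ndarray
    W_v: np.ndarray
    q_global: np.ndarray
    W_h: np.ndarray
    U_h: np.ndarray
    b_h: np.ndarray
    seed: int = 0

    @classmethod
    def init_random(
        cls, modality_dims: dict[str, int], d: int = 16, d_k: int = 8, seed: int = 0
    ) -> "EncoderParams":
        """Glorot-style random initialization, deterministic given seed."""
        rng = np.random.default_rng(np.random.SeedSequence((int(seed), 99)))

        def glorot(n_in, n_out):
            return rng.standard_normal((n_in, n_out)) * np.sqrt(2.0 / (n_in + n_out))

        E = {m: glorot(d_in, d) for m, d_in in modality_dims.items()}
        P = {m: glorot(d, d) for m in modality_dims}
        W_score = {m: glorot(d, 1) for m in modality_dims}
        w_spatial = {m: rng.standard_normal(d) / np.sqrt(d) for m in modality_dims}
        return cls(
            d=d,
            d_k=d_k,
            E=E,
            P=P,
            W_score=W_score,
            w_spatial=w_spatial,
            W_q=glorot(d, d_k),
            W_k=glorot(d, d_k),
            W_v=glorot(d, d),
            q_global=rng.standard_normal(d_k) / np.sqrt(d_k),
            W_h=glorot(d, d),
            U_h=glorot(d, d),
            b_h=np.zeros(d),
            seed=int(seed),
        )


def _to_tokens(X: np.ndarray) -> tuple[np.ndarray, Optional[tuple[int, int]]]:
    """Flatten an H x W x c grid to (H*W) x c tokens; pass matrices through."""
    X = np.asarray(X, dtype=float)
    if X.ndim == 3:
        H, W, c = X.shape
        return X.reshape(H * W, c), (H, W)
    if X.ndim == 2:
        return X, None
    raise ValueError(f"modality array must be 2-D or 3-D, got ndim={X.ndim}")


def encode_and_project(
    obs: MultiModalObservation | dict[str, np.ndarray], params: EncoderParams
) -> tuple[dict[str, np.ndarray], dict[str, Optional[tuple[int, int]]]]:
    """Map each modality to tokens of the shared latent dimension d.

    Spatial modalities keep their (H, W) token layout (returned in the
    shapes dict); sensors give one token per location, weather one per
    time step.  Linear maps with no bias: an all-zero observation yields
    all-zero tokens, and identity E/P reproduce the reshaped input.
    """
    if isinstance(obs, MultiModalObservation):
        raw = {"sat": obs.X_sat, "uav": obs.X_uav, "ground": obs.X_sens, "weather": obs.X_weather}
    else:
        raw = obs
    tokens: dict[str, np.ndarray] = {}
    shapes: dict[str, Optional[tuple[int, int]]] = {}
    for m, X in raw.items():
        if m not in params.E:
            raise ValueError(f"no encoder parameters for modality {m!r}")
        T, shape = _to_tokens(X)
        if T.shape[1] != params.E[m].shape[0]:
            raise ValueError(
                f"modality {m!r}: expected feature dim {params.E[m].shape[0]}, got {T.shape[1]}"
            )
        tokens[m] = T @ params.E[m] @ params.P[m]
        shapes[m] = shape
    return tokens, shapes


def modality_weights(
    F_list: Sequence[np.ndarray], W_list: Sequence[np.ndarray]
) -> np.ndarray:
    """Softmax weights across modalities from per-modality score matrices.

    The scalar score of modality m is the mean entry of W_m F_m (the
    minimal reading of a matrix-valued softmax argument that yields one
    convex weight per modality); adding a constant to all scores leaves
    the weights unchanged.
    """
    if len(F_list) == 0:
        raise ValueError("need at least one modality")
    if len(F_list) != len(W_list):
        raise ValueError("one score matrix per modality required")
    scores = np.array([float(np.mean(np.asarray(F) @ np.asarray(W))) for F, W in zip(F_list, W_list)])
    return softmax(scores)


def spatial_attention(
    F_m: np.ndarray, w_spatial: np.ndarray, bias: float = 0.0
) -> tuple[np.ndarray, np.ndarray]:
    """Location softmax attention over an H x W x d feature map.

    A 1x1 convolution (inner product with ``w_spatial`` per location)
    scores each cell; the softmax over all H*W locations gives the
    attention map A (summing to 1), and the attended map is the
    Hadamard product A ⊙ F broadcast over channels.
    """
    F_m = np.asarray(F_m, dtype=float)
    if F_m.ndim != 3:
        raise ValueError(f"spatial attention expects H x W x d input, got ndim={F_m.ndim}")
    scores = F_m @ np.asarray(w_spatial, dtype=float) + bias
    A = softmax(scores.ravel()).reshape(scores.shape)
    return A, A[..., None] * F_m


def _sinusoid_positions(T: int, d: int) -> np.ndarray:
    pos = np.arange(T)[:, None]
    i = np.arange(d)[None, :]
    angle = pos / np.power(10_000.0, (2 * (i // 2)) / d)
    out = np.empty((T, d))
    out[:, 0::2] = np.sin(angle[:, 0::2])
    out[:, 1::2] = np.cos(angle[:, 1::2])
    return out


def temporal_aggregate(
    seq: Sequence[np.ndarray] | np.ndarray,
    params: EncoderParams,
    mode: str = "transformer",
    positions: bool = True,
) -> np.ndarray:
    """Collapse a sequence of d-vectors into one spatiotemporal vector.

    ``transformer`` (default): one self-attention layer with sinusoidal
    position encodings, returning the last token's attention output.
    ``recurrent``: h_t = tanh(W_h x_t + U_h h_{t-1} + b_h), returning
    h_T — kept as the explicit recurrent contract.
    """
    X = np.asarray(seq, dtype=float)
    if X.ndim == 1:
        X = X[None, :]
    if X.size == 0 or X.shape[0] == 0:
        raise ValueError("temporal_aggregate requires a nonempty sequence")
    if mode == "recurrent":
        h = np.zeros(params.d)
        for x in X:
            h = np.tanh(params.W_h @ x + params.U_h @ h + params.b_h)
        return h
    if mode != "transformer":
        raise ValueError(f"unknown temporal mode {mode!r}")
    Z = X + _sinusoid_positions(X.shape[0], X.shape[1]) if positions else X
    Q, K, V = Z @ params.W_q, Z @ params.W_k, Z @ params.W_v
    attn = softmax(Q @ K.T / np.sqrt(params.d_k), axis=1)
    return (attn @ V)[-1]


def cross_modal_attention(
    F_m1: np.ndarray, F_m2: np.ndarray, params: EncoderParams
) -> tuple[np.ndarray, np.ndarray]:
    """Scaled dot-product attention from modality m1 (queries) into m2.

    C = softmax(Q K^T / sqrt(d_k)) row-wise; the attended representation
    aggregating m2 into m1 is C V with V = F_m2 W_v.
    """
    Q = np.asarray(F_m1, dtype=float) @ params.W_q
    K = np.asarray(F_m2, dtype=float) @ params.W_k
    V = np.asarray(F_m2, dtype=float) @ params.W_v
    C = softmax(Q @ K.T / np.sqrt(params.d_k), axis=1)
    return C, C @ V


@dataclass
class FusedRepresentation:
    """All intermediate and final tensors of one cross-modal fusion pass."""

    tokens: dict[str, np.ndarray]
    C_pairs: dict[tuple[str, str], np.ndarray]
    F_cross: dict[tuple[str, str], np.ndarray]
    C_global: dict[str, np.ndarray]
    pooled: dict[str, np.ndarray]
    F_fused: np.ndarray
    F_final: np.ndarray
    F_refined: np.ndarray


def cross_modal_fuse(
    tokens: dict[str, np.ndarray], params: EncoderParams
) -> FusedRepresentation:
    """Full cross-modal interaction pass over >= 2 modalities.

    Pairwise attention C_{m1,m2} aligns every ordered modality pair; the
    fused vector sums per-modality attention readouts keyed by one
    learned global query; a residual adds the mean-pooled modality
    tokens (F_final = F_fused + sum_m pool(F_m), held exactly); and a
    self-attention step over the single fused token refines the result
    (softmax over one key is 1, i.e. its value projection).
    """
    if len(tokens) < 2:
        raise ValueError("cross-modal fusion needs at least 2 modalities")
    names = list(tokens)
    toks = {m: np.asarray(T, dtype=float) for m, T in tokens.items()}
    C_pairs, F_cross = {}, {}
    for m1 in names:
        for m2 in names:
            if m1 == m2:
                continue
            C, F12 = cross_modal_attention(toks[m1], toks[m2], params)
            C_pairs[(m1, m2)] = C
            F_cross[(m1, m2)] = F12

    C_global: dict[str, np.ndarray] = {}
    F_fused = np.zeros(params.W_v.shape[1])
    for m in names:
        K = toks[m] @ params.W_k
        V = toks[m] @ params.W_v
        c = softmax(params.q_global @ K.T / np.sqrt(params.d_k))
        C_global[m] = c
        F_fused = F_fused + c @ V

    pooled = {m: toks[m].mean(axis=0) for m in names}
    F_final = F_fused + sum(pooled.values())

    # single-token self-attention: the softmax over one key equals 1
    F_refined = F_final @ params.W_v
    return FusedRepresentation(
        tokens=toks,
        C_pairs=C_pairs,
        F_cross=F_cross,
        C_global=C_global,
        pooled=pooled,
        F_fused=F_fused,
        F_final=F_final,
        F_refined=F_refined,
    )


def fused_zone_matrix(
    features: dict[str, np.ndarray],
    params: EncoderParams,
    theta: Optional[np.ndarray] = None,
    norm_stats: Optional[dict[str, tuple[np.ndarray, np.ndarray]]] = None,
) -> np.ndarray:
    """Per-zone fused latent features: x_i = sum_m w_m P_m(E_m(f_{m,i})).

    ``features`` maps modality name to an N x d_m matrix of per-zone
    modality features; ``theta`` overrides the modality-score logits
    (softmax-normalized), defaulting to the learned score maps.
    ``norm_stats`` optionally standardizes each modality with frozen
    (mean, sd) statistics — part of the encoder, recorded at fit time.
    """
    names = [m for m in MODALITIES if m in features]
    Z = {}
    for m in names:
        X = np.asarray(features[m], dtype=float)
        if norm_stats is not None and m in norm_stats:
            mean, sd = norm_stats[m]
            X = (X - mean) / sd
        Z[m] = X @ params.E[m] @ params.P[m]
    if theta is not None:
        w = softmax(np.asarray(theta, dtype=float))
    else:
        w = modality_weights([Z[m] for m in names], [params.W_score[m] for m in names])
    return sum(w[k] * Z[m] for k, m in enumerate(names))


def _sigmoid(z):
    return 0.5 * (1.0 + np.tanh(0.5 * z))


def train_toy_detector(
    scenario: FieldScenario,
    epochs: int = 300,
    lr: float = 0.5,
    seed: int = 0,
    n_samples: int = 80,
    severity: float = 0.5,
):
    """Gradient-descent training of the fusion weighting + linear head.

    Generates labeled per-zone multimodal samples from the simulator
    (drought at the given severity; 0.5 displaces soil moisture by four
    render-noise sigmas), standardizes and projects each modality with
    frozen random encoders, and trains the modality softmax logits plus
    a logistic head by full-batch gradient descent.  Deterministic given
    seed; lr = 0 leaves every trainable parameter unchanged.

    Returns ``(model_dict, DetectionResult)`` where the result is scored
    on a held-out half of the samples (probability > 0.5 is stress).
    """
    features, labels = make_stress_dataset(
        scenario, n_samples=n_samples, severity=severity, seed=seed
    )
    names = [m for m in MODALITIES if m in features]
    dims = {m: features[m].shape[1] for m in names}
    params = EncoderParams.init_random(
        dims, d=scenario.config.fusion.latent_dim, d_k=scenario.config.fusion.key_dim, seed=seed
    )

    n = labels.size
    rng = np.random.default_rng(np.random.SeedSequence((int(seed), 7)))
    perm = rng.permutation(n)
    tr, te = perm[: n // 2], perm[n // 2 :]

    norm_stats = {}
    for m in names:
        mean = features[m][tr].mean(axis=0)
        sd = features[m][tr].std(axis=0)
        sd[sd < 1e-12] = 1.0
        norm_stats[m] = (mean, sd)
    Z = {
        m: ((features[m] - norm_stats[m][0]) / norm_stats[m][1]) @ params.E[m] @ params.P[m]
        for m in names
    }

    theta = np.zeros(len(names))
    W = np.zeros(params.d)
    b = 0.0
    y = labels[tr].astype(float)
    Ztr = {m: Z[m][tr] for m in names}
    for _ in range(int(epochs)):
        w = softmax(theta)
        X = sum(w[k] * Ztr[m] for k, m in enumerate(names))
        z = X @ W + b
        p = _sigmoid(z)
        # stable BCE: softplus(z) - y*z never overflows
        loss = float(np.mean(np.logaddexp(0.0, z) - y * z))
        if not np.isfinite(loss) or loss > 1e8:
            raise ValueError("training diverged (exploding loss); lower the learning rate")
        dz = (p - y) / len(y)
        dW = X.T @ dz
        db = float(dz.sum())
        dx = np.outer(dz, W)
        dw = np.array([float(np.sum(dx * Ztr[m])) for m in names])
        dtheta = w * (dw - float(w @ dw))  # softmax Jacobian-vector product
        W = W - lr * dW
        b = b - lr * db
        theta = theta - lr * dtheta

    w = softmax(theta)
    X_te = sum(w[k] * Z[m][te] for k, m in enumerate(names))
    p_te = _sigmoid(X_te @ W + b)
    result = classify_and_evaluate(p_te, tau=0.5, truth=labels[te])
    model = {
        "params": params,
        "theta": theta,
        "head_w": W,
        "head_b": b,
        "norm_stats": norm_stats,
        "modalities": names,
        "seed": int(seed),
    }
    return model, result
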