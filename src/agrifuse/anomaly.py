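"""Gaussian normal-model anomaly detection with quantile threshold calibration.

A zone's feature vector x is scored by its distance from the mean of
normal samples, s = D(x, mu), with D either Euclidean or Mahalanobis
(covariance-whitened).  A zone is declared anomalous when s > tau.
Under the fitted Gaussian model the Mahalanobis score is a monotone
transform of the negative log-likelihood, so thresholding the score is
equivalent to thresholding the likelihood p(x | theta) — one threshold,
two equivalent views.  tau is calibrated as an empirical quantile of
held-out normal scores, which directly targets the false-positive rate
1 - q.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import linalg

__all__ = [
    "NormalModel",
    "DetectionResult",
    "fit_normal_model",
    "anomaly_score",
    "calibrate_threshold",
    "classify_and_evaluate",
]


@dataclass
class NormalModel:
    """Fitted mean/covariance of normal conditions plus decision threshold."""

    mu: np.ndarray
    sigma: np.ndarray
    shrinkage: float
    metric: str
    tau: Optional[float] = None
    _chol: Optional[np.ndarray] = None  # cholesky factor of sigma, cached

    @property
    def theta(self) -> tuple[np.ndarray, np.ndarray]:
        """Implied Gaussian parameters (mu, sigma)."""
        return self.mu, self.sigma


def fit_normal_model(
    X_normal: np.ndarray, shrinkage: float = 0.1, metric: str = "mahalanobis"
) -> NormalModel:
    """Fit the normal-condition Gaussian from an n x d sample matrix.

    The covariance is shrunk toward its diagonal,
    ``sigma = (1 - shrinkage) * S + shrinkage * diag(S)``, which keeps the
    marginal variances and regularizes correlations; positive
    definiteness is verified by Cholesky.
    """
    X = np.asarray(X_normal, dtype=float)
    if X.ndim != 2:
        raise ValueError("X_normal must be an n x d matrix")
    n, d = X.shape
    if n < 2:
        raise ValueError(f"need at least 2 normal samples, got {n}")
    if not 0.0 <= shrinkage <= 1.0:
        raise ValueError("shrinkage must be in [0, 1]")
    if metric not in ("euclidean", "mahalanobis"):
        raise ValueError(f"metric must be 'euclidean' or 'mahalanobis', got {metric!r}")
    if n <= d and shrinkage == 0.0:
        raise ValueError("singular fit: need n > d samples or shrinkage > 0")

    mu = X.mean(axis=0)
    S = np.cov(X, rowvar=False, ddof=1).reshape(d, d)
    sigma = (1.0 - shrinkage) * S + shrinkage * np.diag(np.diag(S))
    chol = None
    if metric == "mahalanobis":
        try:
            chol = linalg.cholesky(sigma, lower=True)
        except linalg.LinAlgError as exc:
            raise ValueError(
                "shrunk covariance is not positive definite; increase shrinkage"
            ) from exc
    return NormalModel(mu=mu, sigma=sigma, shrinkage=shrinkage, metric=metric, _chol=chol)


def anomaly_score(x: np.ndarray, model: NormalModel) -> np.ndarray | float:
    """Distance of x (d-vector or n x d matrix) from the normal mean.

    Euclidean: ||x - mu||_2.  Mahalanobis: sqrt((x-mu)^T sigma^-1 (x-mu)),
    computed through the cached Cholesky factor.  Always nonnegative.
    """
    x = np.asarray(x, dtype=float)
    single = x.ndim == 1
    X = np.atleast_2d(x)
    d = model.mu.shape[0]
    if X.shape[1] != d:
        raise ValueError(f"feature dimension mismatch: model d={d}, got {X.shape[1]}")
    dev = X - model.mu[None, :]
    if model.metric == "euclidean":
        s = np.linalg.norm(dev, axis=1)
    else:
        chol = model._chol
        if chol is None:
            chol = linalg.cholesky(model.sigma, lower=True)
        z = linalg.solve_triangular(chol, dev.T, lower=True)
        s = np.sqrt((z**2).sum(axis=0))
    return float(s[0]) if single else s


def calibrate_threshold(scores_normal: np.ndarray, q: float = 0.95) -> float:
    """Empirical q-quantile (linear interpolation) of normal scores.

    Scores above the returned tau are flagged anomalous, so fresh normal
    data exceed it with probability ~ 1 - q.
    """
    scores = np.asarray(scores_normal, dtype=float)
    if scores.size == 0:
        raise ValueError("cannot calibrate a threshold from empty scores")
    if not 0.0 < q < 1.0:
        raise ValueError(f"quantile must be in (0, 1), got {q}")
    return float(np.quantile(scores, q, method="linear"))


@dataclass
class DetectionResult:
    """Scores, binary labels and (optionally) classification metrics."""

    scores: np.ndarray
    labels: np.ndarray  # 1 = anomalous
    tau: float
    metrics: Optional[dict] = None


def classify_and_evaluate(
    scores: np.ndarray, tau: float, truth: Optional[np.ndarray] = None
) -> DetectionResult:
    """Threshold scores (anomalous iff score > tau, ties normal) and score.

    With ground truth supplied, computes accuracy, precision, recall and
    F1; any 0/0 ratio is reported as 0.0 and flagged in
    ``metrics['undefined']``.
    """
    scores = np.asarray(scores, dtype=float)
    if not np.all(np.isfinite(scores)):
        raise ValueError("scores must be finite")
    labels = (scores > tau).astype(int)
    metrics = None
    if truth is not None:
        truth = np.asarray(truth).astype(int).ravel()
        if truth.shape != labels.shape:
            raise ValueError(
                f"truth length {truth.shape} does not match scores {labels.shape}"
            )
        tp = int(np.sum((labels == 1) & (truth == 1)))
        fp = int(np.sum((labels == 1) & (truth == 0)))
        fn = int(np.sum((labels == 0) & (truth == 1)))
        tn = int(np.sum((labels == 0) & (truth == 0)))
        undefined = []
        precision = tp / (tp + fp) if tp + fp else 0.0
        if tp + fp == 0:
            undefined.append("precision")
        recall = tp / (tp + fn) if tp + fn else 0.0
        if tp + fn == 0:
            undefined.append("recall")
        if precision + recall > 0:
            f1 = 2 * precision * recall / (precision + recall)
        else:
            f1 = 0.0
            undefined.append("f1")
        metrics = {
            "accuracy": (tp + tn) / labels.size,
            "precision": precision,
            "recall": recall,
            "f1": f1,
            "tp": tp,
            "fp": fp,
            "fn": fn,
            "tn": tn,
            "undefined": undefined,
        }
    return DetectionResult(scores=scores, labels=labels, tau=float(tau), metrics=metrics)
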