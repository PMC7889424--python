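"""Regression heads over a pluggable sentence-pair encoder.

Three pieces live here:

* **M-Heads** — the final affine regression layer is duplicated M times
  with distinct seeded initializations.  Training scales each head's
  squared-error loss by a per-example soft responsibility
  ``α_im = softmax_m(−ℓ_im / T)`` (held fixed within a gradient step), so
  heads specialize on the input regimes they already fit best — a soft
  winner-take-all scheme.  With M = 1 the responsibilities are identically
  1 and training reduces exactly to plain mean-squared-error gradient
  descent.
* **Enhanced features** — concatenation of the encoder vector with a
  similarity-feature block before the regression layer.
* **Voting regression** — plain averaging of the predictions of several
  independently trained estimators.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from sklearn.ensemble import GradientBoostingRegressor
from sklearn.linear_model import Ridge
from sklearn.svm import SVR

from .corpus_io import SCORE_MAX, SCORE_MIN

__all__ = [
    "HeadEnsemble",
    "TrainConfig",
    "init_ensemble",
    "train_ensemble",
    "predict_ensemble",
    "ensemble_loss",
    "voting_predict",
    "enhanced_features",
    "default_estimators",
]


@dataclass(frozen=True)
class TrainConfig:
    """Gradient-descent schedule for head training."""

    epochs: int = 200
    learning_rate: float = 0.05
    temperature: float = 1.0
    anneal: float = 1.0  # temperature multiplier per epoch (0.9 = annealed)

    def __post_init__(self) -> None:
        if self.epochs < 0:
            raise ValueError("epochs must be >= 0")
        if self.learning_rate <= 0 or self.temperature <= 0:
            raise ValueError("learning_rate and temperature must be positive")


@dataclass(frozen=True)
class HeadEnsemble:
    """M parallel affine heads mapping a shared feature vector to a score.

    ``weights`` has shape (M, dim) and ``biases`` shape (M,).
    ``responsibility_mass`` is each head's average responsibility over the
    last training epoch (uniform before training); it drives the optional
    responsibility-weighted aggregation mode.
    """

    weights: np.ndarray
    biases: np.ndarray
    seed: int
    responsibility_mass: np.ndarray

    @property
    def M(self) -> int:
        return self.weights.shape[0]

    @property
    def dim(self) -> int:
        return self.weights.shape[1]


def init_ensemble(M: int, dim: int, seed: int = 0) -> HeadEnsemble:
    """Seeded random initialization; heads are pairwise distinct for M > 1."""
    if M < 1 or dim < 1:
        raise ValueError("M and dim must be >= 1")
    rng = np.random.default_rng(seed)
    weights = 0.1 * rng.standard_normal((M, dim))
    biases = 0.1 * rng.standard_normal(M)
    return HeadEnsemble(
        weights=weights,
        biases=biases,
        seed=seed,
        responsibility_mass=np.full(M, 1.0 / M),
    )


def _head_outputs(e: HeadEnsemble, X: np.ndarray) -> np.ndarray:
    """(n, M) raw affine outputs."""
    return X @ e.weights.T + e.biases


def _responsibilities(losses: np.ndarray, temperature: float) -> np.ndarray:
    """Row-wise softmax of −loss/T; shape (n, M), rows sum to 1."""
    z = -losses / temperature
    z -= z.max(axis=1, keepdims=True)
    expz = np.exp(z)
    return expz / expz.sum(axis=1, keepdims=True)


def ensemble_loss(e: HeadEnsemble, X, y, temperature: float = 1.0) -> float:
    """Responsibility-weighted training loss (mean over examples).

    For M = 1 this is exactly the mean squared error.
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    resid = _head_outputs(e, X) - y[:, None]
    losses = resid**2
    alpha = _responsibilities(losses, temperature)
    return float(np.mean(np.sum(alpha * losses, axis=1)))


def train_ensemble(
    e: HeadEnsemble, X, y, cfg: TrainConfig = TrainConfig()
) -> HeadEnsemble:
    """Full-batch gradient descent on the responsibility-scaled loss.

    Responsibilities are recomputed at the start of each epoch and held
    fixed for that epoch's gradient step.  Zero epochs returns the
    ensemble unchanged.
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    if X.ndim != 2 or X.shape[1] != e.dim:
        raise ValueError(f"expected features of dim {e.dim}, got {X.shape}")
    if len(X) != len(y):
        raise ValueError("X and y must have the same number of rows")
    if len(y) < 2:
        raise ValueError("need at least 2 training examples")
    W = e.weights.copy()
    b = e.biases.copy()
    T = cfg.temperature
    n = len(y)
    alpha = np.full((n, e.M), 1.0 / e.M)
    for _ in range(cfg.epochs):
        resid = X @ W.T + b - y[:, None]  # (n, M)
        alpha = _responsibilities(resid**2, T)
        # d/dW_m of mean_i alpha_im * resid_im^2, alpha fixed
        grad_scale = 2.0 * alpha * resid / n  # (n, M)
        W -= cfg.learning_rate * grad_scale.T @ X
        b -= cfg.learning_rate * grad_scale.sum(axis=0)
        T *= cfg.anneal
    return replace(
        e,
        weights=W,
        biases=b,
        responsibility_mass=alpha.mean(axis=0),
    )


def predict_ensemble(
    e: HeadEnsemble, X, weighted: bool = False
) -> np.ndarray:
    """Aggregate head predictions per row, clipped to [0, 5].

    The default aggregation is the unweighted mean over heads; with
    ``weighted=True`` heads are weighted by their average training
    responsibility instead.
    """
    X = np.asarray(X, float)
    if X.ndim != 2 or X.shape[1] != e.dim:
        raise ValueError(f"expected features of dim {e.dim}, got {X.shape}")
    outputs = _head_outputs(e, X)
    if weighted:
        w = e.responsibility_mass / e.responsibility_mass.sum()
        agg = outputs @ w
    else:
        agg = outputs.mean(axis=1)
    return np.clip(agg, SCORE_MIN, SCORE_MAX)


def voting_predict(estimator_outputs) -> np.ndarray:
    """Row-wise arithmetic mean over estimator columns."""
    out = np.asarray(estimator_outputs, float)
    if out.ndim != 2 or out.shape[1] < 1 or out.size == 0:
        raise ValueError("expected a non-empty (n_samples, n_estimators) matrix")
    return out.mean(axis=1)


def enhanced_features(encoder_vec, fs1) -> np.ndarray:
    """Concatenate the encoder vector with the similarity-feature block."""
    u = np.asarray(encoder_vec, float).ravel()
    v = np.asarray(fs1, float).ravel()
    if u.size == 0 or v.size == 0:
        raise ValueError("both feature blocks must be non-empty")
    return np.concatenate([u, v])


def default_estimators(seed: int = 0) -> list[tuple[str, object]]:
    """Default stacking registry for the voting regressor."""
    return [
        ("ridge", Ridge(alpha=1.0)),
        ("svr_rbf", SVR(kernel="rbf")),
        ("gbrt", GradientBoostingRegressor(random_state=seed)),
    ]
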