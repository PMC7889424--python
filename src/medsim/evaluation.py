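"""Evaluation protocol: Pearson correlation and concatenated k-fold CV.

Performance is measured by the Pearson correlation between predicted and
gold similarity scores.  The k-fold protocol trains on each fold's
complement, predicts the held-out fold, concatenates the out-of-fold
predictions in original pair order, and computes ONE correlation over all
of them — per-fold correlations are never computed, so no variance
estimate is available.  For test-time prediction the k fold models are
ensembled by averaging their predictions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Protocol, Sequence

import numpy as np
from scipy import stats

from .corpus_io import Corpus, SCORE_MAX, SCORE_MIN, SentencePair

__all__ = [
    "EvalConfig",
    "FoldModel",
    "pearson",
    "kfold_concat_eval",
    "fold_ensemble_predict",
    "subset_mse",
]


class FoldModel(Protocol):
    """Minimal contract for models trained inside the fold protocol."""

    def fit(self, pairs: Sequence[SentencePair]) -> None: ...

    def predict(self, pairs: Sequence[SentencePair]) -> Sequence[float]: ...


@dataclass(frozen=True)
class EvalConfig:
    """k-fold protocol settings; k = 150 mirrors the reference protocol,
    any k >= 2 is accepted."""

    k: int = 150
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ValueError("k must be >= 2")


def pearson(pred: Sequence[float], gold: Sequence[float]) -> float:
    """Product-moment correlation; errors on constant input (undefined)."""
    pred = np.asarray(pred, float)
    gold = np.asarray(gold, float)
    if pred.shape != gold.shape or pred.ndim != 1 or len(pred) < 2:
        raise ValueError("pred and gold must be equal-length vectors (>= 2)")
    if np.ptp(pred) == 0 or np.ptp(gold) == 0:
        raise ValueError("Pearson correlation undefined for a constant vector")
    return float(stats.pearsonr(pred, gold).statistic)


def fold_indices(n: int, k: int, seed: int) -> list[np.ndarray]:
    """Seeded uniform shuffle followed by contiguous chunking into k folds."""
    if not (2 <= k <= n):
        raise ValueError(f"k must be in [2, {n}], got {k}")
    rng = np.random.default_rng(seed)
    return [np.sort(c) for c in np.array_split(rng.permutation(n), k)]


def kfold_concat_eval(
    model_factory: Callable[[], FoldModel],
    corpus: Corpus,
    cfg: EvalConfig = EvalConfig(),
) -> tuple[float, list[FoldModel]]:
    """Concatenated k-fold evaluation.

    Each pair is held out in exactly one fold; the model trained on the
    complement predicts it.  A single Pearson correlation is computed over
    the concatenated out-of-fold predictions in original pair order.
    Returns the correlation and the k fitted fold models.
    """
    if not corpus.has_scores:
        raise ValueError("kfold_concat_eval requires gold scores")
    n = len(corpus)
    preds = np.empty(n)
    models: list[FoldModel] = []
    for held in fold_indices(n, cfg.k, cfg.seed):
        held_set = set(int(i) for i in held)
        train = [p for i, p in enumerate(corpus) if i not in held_set]
        model = model_factory()
        model.fit(train)
        preds[held] = np.asarray(model.predict([corpus[int(i)] for i in held]), float)
        models.append(model)
    return pearson(preds, corpus.scores()), models


def fold_ensemble_predict(
    fold_models: Sequence[FoldModel], pair: SentencePair
) -> float:
    """Mean of the fold models' predictions for one pair, clipped to [0, 5]."""
    if not fold_models:
        raise ValueError("need at least one fold model")
    preds = [float(m.predict([pair])[0]) for m in fold_models]
    return float(np.clip(np.mean(preds), SCORE_MIN, SCORE_MAX))


def subset_mse(
    pred: Sequence[float], gold: Sequence[float], mask: Sequence[bool]
) -> float:
    """Mean squared error restricted to the masked indices."""
    pred = np.asarray(pred, float)
    gold = np.asarray(gold, float)
    mask = np.asarray(mask, bool)
    if not (pred.shape == gold.shape == mask.shape):
        raise ValueError("pred, gold and mask must have equal length")
    if not mask.any():
        raise ValueError("mask selects no elements")
    d = pred[mask] - gold[mask]
    return float(np.mean(d * d))
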