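"""Token- and embedding-based sentence similarity features.

Two families of measures are provided: set comparisons over character
n-grams (Jaccard, Dice, plus a normalized longest-common-substring ratio)
and the cosine between sentence embeddings.  All token-based measures are
symmetric and bounded in [0, 1].  The embedder is a pluggable contract —
any deterministic text→vector map — with a hashed bag-of-character-n-grams
projection as the default, so the feature pipeline runs without any
pretrained model.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .corpus_io import SentencePair

__all__ = [
    "FeatureConfig",
    "HashedNgramEmbedder",
    "char_ngrams",
    "jaccard_ngram",
    "dice_ngram",
    "lcs_ratio",
    "cosine_similarity",
    "feature_vector",
    "feature_names",
    "FEATURE_SET_I",
    "FEATURE_SET_II",
]


def char_ngrams(text: str, n: int) -> set[str]:
    """Set of all contiguous length-n character substrings (lowercased)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    t = text.lower()
    return {t[i : i + n] for i in range(len(t) - n + 1)}


def jaccard_ngram(a: str, b: str, n: int) -> float:
    """|Ga ∩ Gb| / |Ga ∪ Gb| over character n-gram sets; 1 when both empty."""
    ga, gb = char_ngrams(a, n), char_ngrams(b, n)
    union = ga | gb
    if not union:
        return 1.0
    return len(ga & gb) / len(union)


def dice_ngram(a: str, b: str, n: int) -> float:
    """Dice coefficient 2|Ga ∩ Gb| / (|Ga| + |Gb|); 1 when both empty."""
    ga, gb = char_ngrams(a, n), char_ngrams(b, n)
    denom = len(ga) + len(gb)
    if denom == 0:
        return 1.0
    return 2 * len(ga & gb) / denom


def lcs_ratio(a: str, b: str) -> float:
    """Longest common substring length over the longer sentence length."""
    a, b = a.lower(), b.lower()
    if not a and not b:
        return 1.0
    if not a or not b:
        return 0.0
    # classic O(len(a)*len(b)) DP over substring endings
    prev = [0] * (len(b) + 1)
    best = 0
    for ca in a:
        cur = [0] * (len(b) + 1)
        for j, cb in enumerate(b, start=1):
            if ca == cb:
                cur[j] = prev[j - 1] + 1
                if cur[j] > best:
                    best = cur[j]
        prev = cur
    return best / max(len(a), len(b))


def cosine_similarity(u: Sequence[float], v: Sequence[float]) -> float:
    """u·v / (‖u‖‖v‖); raises on zero vectors."""
    u = np.asarray(u, float)
    v = np.asarray(v, float)
    if u.shape != v.shape:
        raise ValueError("vectors must have equal length")
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        raise ValueError("cosine similarity undefined for a zero vector")
    return float(np.dot(u, v) / (nu * nv))


class HashedNgramEmbedder:
    """Deterministic sentence embedding by hashing character n-grams.

    Each n-gram is hashed (CRC32, stable across processes) into one of
    ``dim`` buckets with a ±1 sign; the bucket counts are L2-normalized.
    This is a feature-hashing projection, not a learned semantic space:
    it captures surface overlap only.
    """

    def __init__(self, dim: int = 128, n: int = 3) -> None:
        if dim < 1 or n < 1:
            raise ValueError("dim and n must be >= 1")
        self.dim = dim
        self.n = n

    def embed(self, text: str) -> np.ndarray:
        vec = np.zeros(self.dim)
        t = text.lower()
        grams = [t[i : i + self.n] for i in range(len(t) - self.n + 1)] or [t]
        for g in grams:
            h = zlib.crc32(g.encode("utf-8"))
            vec[h % self.dim] += 1.0 if (h >> 31) & 1 else -1.0
        norm = np.linalg.norm(vec)
        if norm > 0:
            vec /= norm
        else:
            vec[0] = 1.0  # degenerate all-cancelling text: fixed unit vector
        return vec

    def __call__(self, text: str) -> np.ndarray:
        return self.embed(text)


#: measure name -> callable(a, b, n) for the token-based family
_TOKEN_MEASURES: dict[str, Callable[[str, str, int], float]] = {
    "jaccard": jaccard_ngram,
    "dice": dice_ngram,
}


@dataclass(frozen=True)
class FeatureConfig:
    """Which similarity features to compute and in what order.

    The feature vector is the concatenation of every token measure at
    every n-gram order (measure-major), then the LCS ratio if enabled,
    then the embedding cosine if an embedder is set.  Its length is a pure
    function of this config.
    """

    ngram_orders: tuple[int, ...] = (2, 3, 4)
    measures: tuple[str, ...] = ("jaccard", "dice")
    use_lcs: bool = True
    embedder: Callable[[str], np.ndarray] | None = field(
        default_factory=HashedNgramEmbedder
    )

    def __post_init__(self) -> None:
        if not self.measures:
            raise ValueError("measures must be non-empty")
        unknown = set(self.measures) - set(_TOKEN_MEASURES)
        if unknown:
            raise ValueError(f"unknown measures: {sorted(unknown)}")
        if any(n < 1 for n in self.ngram_orders):
            raise ValueError("ngram orders must be >= 1")

    @property
    def dim(self) -> int:
        d = len(self.measures) * len(self.ngram_orders)
        if self.use_lcs:
            d += 1
        if self.embedder is not None:
            d += 1
        return d


#: concatenated to the encoder vector before the regression head
FEATURE_SET_I = FeatureConfig()
#: fed, together with upstream scores, to the stacking estimators
FEATURE_SET_II = FeatureConfig(ngram_orders=(2, 3), measures=("jaccard",))


def feature_names(cfg: FeatureConfig) -> list[str]:
    """Stable column names matching :func:`feature_vector` order."""
    names = [f"{m}_{n}gram" for m in cfg.measures for n in cfg.ngram_orders]
    if cfg.use_lcs:
        names.append("lcs_ratio")
    if cfg.embedder is not None:
        names.append("embedding_cosine")
    return names


def feature_vector(pair: SentencePair, cfg: FeatureConfig) -> np.ndarray:
    """Similarity feature vector for one sentence pair under a config."""
    a, b = pair.sentence_a, pair.sentence_b
    feats = [
        _TOKEN_MEASURES[m](a, b, n)
        for m in cfg.measures
        for n in cfg.ngram_orders
    ]
    if cfg.use_lcs:
        feats.append(lcs_ratio(a, b))
    if cfg.embedder is not None:
        feats.append(cosine_similarity(cfg.embedder(a), cfg.embedder(b)))
    return np.array(feats, dtype=float)


def feature_matrix(pairs: Sequence[SentencePair], cfg: FeatureConfig) -> np.ndarray:
    """Row-stacked feature vectors for a list of pairs."""
    return np.vstack([feature_vector(p, cfg) for p in pairs])
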