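"""Medication similarity graph: construction, inference, and fitting.

The model treats the active agent (drug substance) as the dominant factor
in the similarity of two prescription sentences.  Observed pair scores are
first stripped of the influence of the remaining entities by a bounded
adjustment ``tanh(λ0 + Σk λk Δk)`` and averaged per agent pair, giving an
undirected graph whose edge weights approximate agent–agent similarity.

At inference the similarity of an unseen agent pair is extrapolated along
the shortest path through the graph with the parallel-resistance rule

    1/ŝ = Σm 1 / w(p(m), p(m+1))

which guarantees ŝ never exceeds the smallest weight on the path — low
similarity anywhere along the chain cannot be "restored" downstream.  The
entity adjustment is then subtracted back out, and the resulting graph
score is fused with an external base predictor's score in an RBF-kernel
support vector regression.

λ is learned by an accept-if-better random walk evaluated by out-of-fold
mean squared error, alternating with a grid search over the SVR
hyperparameters.
"""

from __future__ import annotations

import heapq
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from sklearn.model_selection import GridSearchCV
from sklearn.svm import SVR

from .corpus_io import Corpus, SCORE_MAX, SCORE_MIN
from .medication_entities import (
    MedicationRecord,
    N_DELTA_FEATURES,
    build_delta_vector,
    extract_medication,
)

__all__ = [
    "LambdaWeights",
    "GraphConfig",
    "AgentGraph",
    "PathResult",
    "FusionModel",
    "GraphModel",
    "edge_weight",
    "build_graph",
    "path_similarity",
    "predict_pair",
    "random_walk_fit",
    "fit_fusion",
    "alternate_fit",
    "predict_with_replacement",
]


# ---------------------------------------------------------------------------
# Parameters and containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LambdaWeights:
    """Bias λ0 plus the N=5 entity-difference weights."""

    lambda0: float = 0.0
    lambdas: tuple[float, ...] = (0.0,) * N_DELTA_FEATURES

    def __post_init__(self) -> None:
        if len(self.lambdas) != N_DELTA_FEATURES:
            raise ValueError(
                f"expected {N_DELTA_FEATURES} entity weights, "
                f"got {len(self.lambdas)}"
            )
        if not all(map(math.isfinite, (self.lambda0, *self.lambdas))):
            raise ValueError("lambda weights must be finite")

    def as_array(self) -> np.ndarray:
        """(λ0, λ1..λN) as a flat array."""
        return np.array([self.lambda0, *self.lambdas], dtype=float)

    @classmethod
    def from_array(cls, arr: Sequence[float]) -> "LambdaWeights":
        arr = np.asarray(arr, dtype=float)
        return cls(float(arr[0]), tuple(float(x) for x in arr[1:]))

    def adjustment(self, delta: np.ndarray) -> float:
        """The bounded entity adjustment tanh(λ0 + Σk λk Δk)."""
        return float(np.tanh(self.lambda0 + np.dot(self.lambdas, delta)))


@dataclass(frozen=True)
class GraphConfig:
    """Numerical configuration of the graph.

    ``weight_floor`` keeps edge weights strictly positive so the
    parallel-resistance sum is always defined; ``disconnected_fallback``
    is the score reported when two agents have no connecting path
    (``None`` means "skip": callers fall back to the base predictor).
    """

    s_min: float = SCORE_MIN
    s_max: float = SCORE_MAX
    weight_floor: float = 1e-6
    disconnected_fallback: float | None = None

    def __post_init__(self) -> None:
        if not (0 < self.weight_floor < self.s_max):
            raise ValueError("require 0 < weight_floor < s_max")
        if self.s_min >= self.s_max:
            raise ValueError("require s_min < s_max")


DEFAULT_CONFIG = GraphConfig()

#: A training observation: two parsed prescription records plus gold score.
MedPair = tuple[MedicationRecord, MedicationRecord, float]


@dataclass(frozen=True)
class PathResult:
    """Outcome of a shortest-path similarity query."""

    s_hat: float
    path: tuple[str, ...]
    found: bool


@dataclass
class AgentGraph:
    """Undirected weighted graph over active agents.

    ``edges`` maps a sorted agent-name pair to its weight; ``n_obs``
    records how many training sentence pairs produced each edge.
    """

    nodes: set[str] = field(default_factory=set)
    edges: dict[tuple[str, str], float] = field(default_factory=dict)
    n_obs: dict[tuple[str, str], int] = field(default_factory=dict)

    def weight(self, u: str, v: str) -> float | None:
        return self.edges.get((u, v) if u <= v else (v, u))

    def neighbors(self, u: str) -> dict[str, float]:
        out: dict[str, float] = {}
        for (a, b), w in self.edges.items():
            if a == u:
                out[b] = w
            elif b == u:
                out[a] = w
        return out

    # adjacency cache for repeated shortest-path queries
    _adj: dict[str, list[tuple[str, float]]] | None = None

    def adjacency(self) -> dict[str, list[tuple[str, float]]]:
        if self._adj is None:
            adj: dict[str, list[tuple[str, float]]] = {u: [] for u in self.nodes}
            for (a, b), w in self.edges.items():
                adj[a].append((b, w))
                adj[b].append((a, w))
            for lst in adj.values():
                lst.sort()
            self._adj = adj
        return self._adj

    def to_json(self, path: str | Path) -> None:
        payload = {
            "nodes": sorted(self.nodes),
            "edges": [
                {"u": u, "v": v, "w": w, "n_obs": self.n_obs.get((u, v), 1)}
                for (u, v), w in sorted(self.edges.items())
            ],
        }
        Path(path).write_text(json.dumps(payload, indent=1), encoding="utf-8")

    @classmethod
    def from_json(cls, path: str | Path) -> "AgentGraph":
        payload = json.loads(Path(path).read_text(encoding="utf-8"))
        g = cls(nodes=set(payload["nodes"]))
        for e in payload["edges"]:
            key = (e["u"], e["v"]) if e["u"] <= e["v"] else (e["v"], e["u"])
            g.edges[key] = float(e["w"])
            g.n_obs[key] = int(e.get("n_obs", 1))
        return g


# ---------------------------------------------------------------------------
# Graph construction
# ---------------------------------------------------------------------------

def edge_weight(
    observations: Sequence[tuple[float, np.ndarray]],
    lam: LambdaWeights,
    cfg: GraphConfig = DEFAULT_CONFIG,
) -> float:
    """Entity-adjusted weight for one agent pair.

    Each observed score is shifted by ``+tanh(λ0 + Σ λk Δk)`` (removing the
    estimated entity influence), clipped to [s_min, s_max]; the clipped
    values are averaged over the observation set C and floored at
    ``weight_floor``.
    """
    if not observations:
        raise ValueError("edge_weight requires at least one observation")
    total = 0.0
    for s, delta in observations:
        adj = s + lam.adjustment(np.asarray(delta, dtype=float))
        total += min(max(adj, cfg.s_min), cfg.s_max)
    return max(total / len(observations), cfg.weight_floor)


def _group_observations(
    med_pairs: Sequence[MedPair],
) -> dict[tuple[str, str], list[tuple[float, np.ndarray]]]:
    """Group (score, Δ) observations by sorted agent pair; self-pairs dropped."""
    groups: dict[tuple[str, str], list[tuple[float, np.ndarray]]] = {}
    for rec_a, rec_b, score in med_pairs:
        if not (SCORE_MIN <= score <= SCORE_MAX):
            raise ValueError(f"score {score} outside [{SCORE_MIN}, {SCORE_MAX}]")
        a, b = rec_a.active_agent, rec_b.active_agent
        if a == b:
            continue
        key = (a, b) if a <= b else (b, a)
        groups.setdefault(key, []).append((score, build_delta_vector(rec_a, rec_b)))
    return groups


def build_graph(
    med_pairs: Sequence[MedPair],
    lam: LambdaWeights,
    cfg: GraphConfig = DEFAULT_CONFIG,
) -> AgentGraph:
    """Build the agent graph from training medication pairs.

    Nodes are all agents seen (including agents that only ever occur in
    self-pairs); edges connect agent pairs that co-occur in a sentence
    pair, weighted by :func:`edge_weight` over their observation set.
    """
    g = AgentGraph()
    for rec_a, rec_b, _ in med_pairs:
        g.nodes.add(rec_a.active_agent)
        g.nodes.add(rec_b.active_agent)
    for key, obs in _group_observations(med_pairs).items():
        g.edges[key] = edge_weight(obs, lam, cfg)
        g.n_obs[key] = len(obs)
    return g


# ---------------------------------------------------------------------------
# Inference
# ---------------------------------------------------------------------------

def path_similarity(
    graph: AgentGraph,
    a_i: str,
    a_j: str,
    cfg: GraphConfig = DEFAULT_CONFIG,
) -> PathResult:
    """Shortest-path similarity between two agents.

    Dijkstra with edge length 1/max(w, weight_floor): the selected path
    minimizes Σ 1/w, and the reported similarity is the reciprocal of that
    sum — the parallel-resistance aggregate of the weights along the path.
    Ties are broken by fewer hops, then by lexicographic node sequence.
    """
    if a_i == a_j:
        raise ValueError("self-similarity is not modeled by the graph")
    if a_i not in graph.nodes or a_j not in graph.nodes:
        return _disconnected(cfg)
    adj = graph.adjacency()
    # heap entries: (resistance, hops, path); lexicographic path comparison
    # implements the tie-break and is prefix-monotone, so Dijkstra applies.
    heap: list[tuple[float, int, tuple[str, ...]]] = [(0.0, 0, (a_i,))]
    settled: set[str] = set()
    while heap:
        dist, hops, path = heapq.heappop(heap)
        node = path[-1]
        if node in settled:
            continue
        settled.add(node)
        if node == a_j:
            return PathResult(s_hat=1.0 / dist, path=path, found=True)
        for nbr, w in adj[node]:
            if nbr not in settled:
                heapq.heappush(
                    heap,
                    (dist + 1.0 / max(w, cfg.weight_floor), hops + 1, path + (nbr,)),
                )
    return _disconnected(cfg)


def _disconnected(cfg: GraphConfig) -> PathResult:
    fallback = cfg.disconnected_fallback
    return PathResult(
        s_hat=float("nan") if fallback is None else fallback,
        path=(),
        found=False,
    )


def predict_pair(
    graph: AgentGraph,
    lam: LambdaWeights,
    rec_a: MedicationRecord,
    rec_b: MedicationRecord,
    cfg: GraphConfig = DEFAULT_CONFIG,
) -> float | None:
    """Graph similarity score s_g for one medication sentence pair.

    The agent-level similarity ŝ from the graph is shifted by
    ``-tanh(λ0 + Σ λk Δk)`` — the exact inverse of the edge-construction
    adjustment — and clipped to [s_min, s_max].  Identical agents on both
    sides are assigned the maximal agent similarity ŝ = s_max.  Returns
    ``None`` for disconnected/unseen agents when the config says to skip.
    """
    if rec_a.active_agent == rec_b.active_agent:
        s_hat = cfg.s_max
    else:
        res = path_similarity(graph, rec_a.active_agent, rec_b.active_agent, cfg)
        if not res.found and cfg.disconnected_fallback is None:
            return None
        s_hat = res.s_hat
    delta = build_delta_vector(rec_a, rec_b)
    s_g = s_hat - lam.adjustment(delta)
    return min(max(s_g, cfg.s_min), cfg.s_max)


# ---------------------------------------------------------------------------
# λ learning by random walk
# ---------------------------------------------------------------------------

class _FoldEvaluator:
    """Precomputed fold structure for fast re-evaluation of λ proposals.

    Connectivity of the per-fold graphs does not depend on λ, so the edge
    grouping and the query lists are computed once; only the edge weights
    (and hence shortest paths) are recomputed per proposal.
    """

    def __init__(
        self,
        med_pairs: Sequence[MedPair],
        folds: int,
        rng: np.random.Generator,
        cfg: GraphConfig,
    ) -> None:
        if len(med_pairs) < folds:
            raise ValueError(
                f"need at least {folds} medication pairs, got {len(med_pairs)}"
            )
        self.cfg = cfg
        order = rng.permutation(len(med_pairs))
        chunks = np.array_split(order, folds)
        self.folds: list[tuple[list[MedPair], list[MedPair]]] = []
        for c in chunks:
            held = set(int(i) for i in c)
            train = [med_pairs[i] for i in range(len(med_pairs)) if i not in held]
            test = [med_pairs[int(i)] for i in c]
            self.folds.append((train, test))

    def mse(self, lam: LambdaWeights) -> float:
        """Out-of-fold MSE: predictions from all folds are concatenated and
        a single MSE is computed against the gold scores.  Held-out pairs
        whose agents are unreachable in the fold graph are skipped (the
        skip set is λ-independent)."""
        preds: list[float] = []
        gold: list[float] = []
        for train, test in self.folds:
            graph = build_graph(train, lam, self.cfg)
            for rec_a, rec_b, score in test:
                p = predict_pair(graph, lam, rec_a, rec_b, self.cfg)
                if p is not None:
                    preds.append(p)
                    gold.append(score)
        if not preds:
            raise ValueError("no held-out pair could be scored by the graph")
        d = np.asarray(preds) - np.asarray(gold)
        return float(np.mean(d * d))


def random_walk_fit(
    med_pairs: Sequence[MedPair],
    lam0: LambdaWeights,
    folds: int = 10,
    steps: int = 50,
    seed: int = 0,
    cfg: GraphConfig = DEFAULT_CONFIG,
) -> tuple[LambdaWeights, list[float]]:
    """Accept-if-better random walk over the λ weights.

    Each step picks one coordinate k uniformly from {0..N}, proposes
    λ'k = λk + a standard-normal draw, rebuilds the per-fold graphs, and
    accepts the proposal iff the concatenated out-of-fold MSE strictly
    decreases.  Returns the final λ and the trace of accepted MSE values
    (starting with the initial MSE), which is strictly decreasing.
    """
    rng = np.random.default_rng(seed)
    evaluator = _FoldEvaluator(med_pairs, folds, rng, cfg)
    lam = lam0
    best = evaluator.mse(lam)
    trace = [best]
    n_coords = N_DELTA_FEATURES + 1
    for _ in range(steps):
        k = int(rng.integers(n_coords))
        arr = lam.as_array()
        arr[k] += rng.standard_normal()
        proposal = LambdaWeights.from_array(arr)
        mse = evaluator.mse(proposal)
        if mse < best:
            lam, best = proposal, mse
            trace.append(best)
    return lam, trace


# ---------------------------------------------------------------------------
# SVR fusion
# ---------------------------------------------------------------------------

DEFAULT_GRID_C = (0.1, 1.0, 10.0, 100.0)
DEFAULT_GRID_EPS = (0.01, 0.1, 0.5)


@dataclass
class FusionModel:
    """RBF-kernel support vector regression over (graph score, base score)."""

    C: float
    epsilon: float
    gamma: float
    _svr: SVR | None = None
    _X: np.ndarray | None = None
    _y: np.ndarray | None = None

    def predict(self, graph_scores, base_scores) -> np.ndarray:
        if self._svr is None:
            raise RuntimeError("fusion model is not fitted")
        X = np.column_stack(
            [np.asarray(graph_scores, float), np.asarray(base_scores, float)]
        )
        return np.clip(self._svr.predict(X), SCORE_MIN, SCORE_MAX)


def _median_gamma(X: np.ndarray) -> float:
    """RBF bandwidth from the median pairwise squared distance heuristic."""
    n = len(X)
    if n > 500:  # subsample for the heuristic only
        idx = np.linspace(0, n - 1, 500).astype(int)
        X = X[idx]
    d2 = np.sum((X[:, None, :] - X[None, :, :]) ** 2, axis=-1)
    med = float(np.median(d2[np.triu_indices(len(X), k=1)]))
    if med <= 0:
        return 1.0
    return 1.0 / med


def fit_fusion(
    graph_scores: Sequence[float],
    base_scores: Sequence[float],
    gold: Sequence[float],
    grid_C: Sequence[float] = DEFAULT_GRID_C,
    grid_eps: Sequence[float] = DEFAULT_GRID_EPS,
) -> FusionModel:
    """Grid-searched RBF support vector regression fusing the two scores.

    Hyperparameters C and ε are chosen by 5-fold cross-validated MSE; the
    kernel bandwidth is fixed by the median-distance heuristic.
    """
    g = np.asarray(graph_scores, float)
    b = np.asarray(base_scores, float)
    y = np.asarray(gold, float)
    if not (len(g) == len(b) == len(y)):
        raise ValueError("graph_scores, base_scores and gold must align")
    if len(y) < 10:
        raise ValueError("need at least 10 training rows for fusion")
    X = np.column_stack([g, b])
    gamma = _median_gamma(X)
    # tight solver tolerance keeps the fit invariant to training-row order
    search = GridSearchCV(
        SVR(kernel="rbf", gamma=gamma, tol=1e-8),
        {"C": list(grid_C), "epsilon": list(grid_eps)},
        scoring="neg_mean_squared_error",
        cv=5,
    )
    search.fit(X, y)
    model = FusionModel(
        C=float(search.best_params_["C"]),
        epsilon=float(search.best_params_["epsilon"]),
        gamma=gamma,
        _svr=search.best_estimator_,
        _X=X,
        _y=y,
    )
    return model


# ---------------------------------------------------------------------------
# Full pipeline: alternate fitting and subset replacement
# ---------------------------------------------------------------------------

@dataclass
class GraphModel:
    """Fitted medication-graph pipeline: λ, full-training graph, fusion."""

    lam: LambdaWeights
    graph: AgentGraph
    fusion: FusionModel
    cfg: GraphConfig = DEFAULT_CONFIG
    mse_trace: list[float] = field(default_factory=list)

    def save(self, path: str | Path) -> None:
        """Serialize to JSON.  The SVR is stored as hyperparameters plus
        training rows and deterministically refitted on load."""
        payload = {
            "lambda": list(self.lam.as_array()),
            "config": {
                "s_min": self.cfg.s_min,
                "s_max": self.cfg.s_max,
                "weight_floor": self.cfg.weight_floor,
            },
            "graph": {
                "nodes": sorted(self.graph.nodes),
                "edges": [
                    {"u": u, "v": v, "w": w, "n_obs": self.graph.n_obs.get((u, v), 1)}
                    for (u, v), w in sorted(self.graph.edges.items())
                ],
            },
            "fusion": {
                "C": self.fusion.C,
                "epsilon": self.fusion.epsilon,
                "gamma": self.fusion.gamma,
                "X": self.fusion._X.tolist(),
                "y": self.fusion._y.tolist(),
            },
            "mse_trace": self.mse_trace,
        }
        Path(path).write_text(json.dumps(payload), encoding="utf-8")

    @classmethod
    def load(cls, path: str | Path) -> "GraphModel":
        payload = json.loads(Path(path).read_text(encoding="utf-8"))
        cfg = GraphConfig(**payload["config"])
        lam = LambdaWeights.from_array(payload["lambda"])
        graph = AgentGraph(nodes=set(payload["graph"]["nodes"]))
        for e in payload["graph"]["edges"]:
            key = (e["u"], e["v"]) if e["u"] <= e["v"] else (e["v"], e["u"])
            graph.edges[key] = float(e["w"])
            graph.n_obs[key] = int(e["n_obs"])
        f = payload["fusion"]
        X = np.asarray(f["X"], float)
        y = np.asarray(f["y"], float)
        svr = SVR(kernel="rbf", gamma=f["gamma"], C=f["C"], epsilon=f["epsilon"],
                  tol=1e-8)
        svr.fit(X, y)
        fusion = FusionModel(
            C=f["C"], epsilon=f["epsilon"], gamma=f["gamma"], _svr=svr, _X=X, _y=y
        )
        return cls(lam=lam, graph=graph, fusion=fusion, cfg=cfg,
                   mse_trace=list(payload.get("mse_trace", [])))


def extract_med_pairs(corpus: Corpus) -> tuple[list[int], list[MedPair]]:
    """Indices and parsed records of the medication-pair subset of a corpus."""
    indices: list[int] = []
    med_pairs: list[MedPair] = []
    for i, pair in enumerate(corpus):
        rec_a = extract_medication(pair.sentence_a)
        if rec_a is None:
            continue
        rec_b = extract_medication(pair.sentence_b)
        if rec_b is None:
            continue
        indices.append(i)
        med_pairs.append((rec_a, rec_b, 0.0 if pair.score is None else pair.score))
    return indices, med_pairs


def alternate_fit(
    corpus: Corpus,
    base_scores: Sequence[float],
    seed: int = 0,
    folds: int = 10,
    steps: int = 50,
    iterations: int = 2,
    cfg: GraphConfig = DEFAULT_CONFIG,
    grid_C: Sequence[float] = DEFAULT_GRID_C,
    grid_eps: Sequence[float] = DEFAULT_GRID_EPS,
) -> GraphModel:
    """Alternate the λ random walk with SVR hyperparameter tuning.

    Runs ``iterations`` rounds of {50-step random walk, fusion grid
    search}.  λ starts from a small seeded normal initialization; each
    round's walk continues from the previous round's λ.  The final λ is
    used to build the graph on all training data, and the fusion SVR is
    trained on every training sentence pair: the graph score where the
    graph can produce one, with the base score standing in elsewhere.
    """
    if not corpus.has_scores:
        raise ValueError("alternate_fit requires a fully annotated corpus")
    if len(base_scores) != len(corpus):
        raise ValueError("base_scores must align with the corpus")
    _, med_pairs = extract_med_pairs(corpus)
    if not med_pairs:
        raise ValueError("corpus contains no medication pairs")
    rng = np.random.default_rng(seed)
    lam = LambdaWeights.from_array(0.1 * rng.standard_normal(N_DELTA_FEATURES + 1))
    trace: list[float] = []
    fusion: FusionModel | None = None
    for it in range(iterations):
        lam, t = random_walk_fit(
            med_pairs, lam, folds=folds, steps=steps,
            seed=int(rng.integers(2**31)), cfg=cfg,
        )
        trace.extend(t)
        graph = build_graph(med_pairs, lam, cfg)
        s_g = _graph_scores_with_fallback(corpus, base_scores, graph, lam, cfg)
        fusion = fit_fusion(s_g, base_scores, corpus.scores(), grid_C, grid_eps)
    graph = build_graph(med_pairs, lam, cfg)
    assert fusion is not None
    return GraphModel(lam=lam, graph=graph, fusion=fusion, cfg=cfg, mse_trace=trace)


def _graph_scores_with_fallback(
    corpus: Corpus,
    base_scores: Sequence[float],
    graph: AgentGraph,
    lam: LambdaWeights,
    cfg: GraphConfig,
) -> np.ndarray:
    """Graph score per pair; the base score stands in where the graph is
    silent (non-medication pair, unseen agent, disconnected)."""
    out = np.asarray(base_scores, float).copy()
    for i, pair in enumerate(corpus):
        rec_a = extract_medication(pair.sentence_a)
        if rec_a is None:
            continue
        rec_b = extract_medication(pair.sentence_b)
        if rec_b is None:
            continue
        p = predict_pair(graph, lam, rec_a, rec_b, cfg)
        if p is not None:
            out[i] = p
    return out


def predict_with_replacement(
    corpus: Corpus,
    base_scores: Sequence[float],
    graph: AgentGraph,
    lam: LambdaWeights,
    fusion: FusionModel,
    cfg: GraphConfig = DEFAULT_CONFIG,
) -> np.ndarray:
    """Base scores with the medication subset replaced by fused graph scores.

    Only pairs where both sentences parse as prescriptions AND the graph
    yields a prediction are replaced; everywhere else the base predictor's
    score is kept unchanged.  All outputs lie in [0, 5].
    """
    base = np.asarray(base_scores, float)
    if len(base) != len(corpus):
        raise ValueError("base_scores must align with the corpus")
    out = base.copy()
    for i, pair in enumerate(corpus):
        rec_a = extract_medication(pair.sentence_a)
        if rec_a is None:
            continue
        rec_b = extract_medication(pair.sentence_b)
        if rec_b is None:
            continue
        s_g = predict_pair(graph, lam, rec_a, rec_b, cfg)
        if s_g is None:
            continue
        out[i] = float(fusion.predict([s_g], [base[i]])[0])
    return out
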