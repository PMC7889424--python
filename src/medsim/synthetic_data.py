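"""Synthetic sentence-pair corpora with known latent structure.

The generator emulates a clinical STS medication subset: templated
prescription sentences over a pool of invented drug agents, an underlying
agent–agent similarity structure derived from low-dimensional agent
embeddings (so similarity is approximately transitive and shortest-path
extrapolation is meaningful), a known entity-difference effect λ* applied
through the same bounded tanh adjustment the graph model assumes, and
additive Gaussian observation noise with scores clipped to [0, 5].

Non-medication "filler" pairs are generated from a small narrative
template bank; their scores follow one of several feature→score regimes
(alternating slope sign on sentence overlap) to provide the bimodal
structure needed to exercise head-specializing ensembles.

Every latent quantity (similarity matrix, true records, pre-noise scores,
regime ids) is returned alongside the corpus so recovery can be measured.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .corpus_io import Corpus, SCORE_MAX, SCORE_MIN, SentencePair
from .medication_entities import MedicationRecord, build_delta_vector
from .medication_graph import LambdaWeights

__all__ = [
    "SynthConfig",
    "SynthTruth",
    "make_latent_agents",
    "sample_medication_pair",
    "render_sentence",
    "generate_corpus",
]

#: default entity-difference effect λ* = (bias; strength_amount,
#: strength_unit, dose_amount, dose_unit, frequency).  The strength-amount
#: weight is small because squared mg differences reach ~2.5e5.
DEFAULT_LAMBDA_TRUE = LambdaWeights(0.1, (2e-5, 0.4, 0.15, 0.3, 0.02))

_SYLLABLES = (
    "ba be bi bo bu da de di do du fa fe fi fo fu ga ge gi go gu "
    "la le li lo lu ma me mi mo mu na ne ni no nu pa pe pi po pu "
    "ra re ri ro ru sa se si so su ta te ti to tu va ve vi vo vu"
).split()

_STRENGTHS = (4.0, 10.0, 20.0, 25.0, 40.0, 50.0, 100.0, 150.0, 220.0, 250.0, 325.0, 500.0)
_DOSES = (0.5, 1.0, 2.0, 3.0)
_TIMES_PER_DAY = (1.0, 2.0, 3.0, 4.0)
_EVERY_HOURS = (4.0, 6.0, 8.0, 12.0)

_TOPICS = (
    "chest pain", "shortness of breath", "headache", "nausea",
    "dizziness", "fever", "abdominal pain", "fatigue",
)
_FRAMES = (
    "the patient reports {t} today.",
    "patient denies {t}.",
    "he has a history of {t}.",
    "she was advised to rest because of {t}.",
    "follow up regarding {t} next week.",
)


@dataclass(frozen=True)
class SynthConfig:
    """Study conditions for one synthetic corpus."""

    n_agents: int = 30
    n_pairs: int = 600
    med_fraction: float = 1.0
    noise_sd: float = 0.2
    lambda_true: LambdaWeights = DEFAULT_LAMBDA_TRUE
    n_regimes: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_agents < 2 or self.n_pairs < 1:
            raise ValueError("need n_agents >= 2 and n_pairs >= 1")
        if not (0.0 <= self.med_fraction <= 1.0):
            raise ValueError("med_fraction must lie in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.n_regimes < 1:
            raise ValueError("n_regimes must be >= 1")


@dataclass
class SynthTruth:
    """Latent state behind a generated corpus."""

    agent_names: list[str]
    agent_similarity: np.ndarray  # symmetric, diagonal = 5
    records: list[tuple[MedicationRecord, MedicationRecord] | None]
    true_scores: np.ndarray  # pre-noise, pre-clip scores clipped to [0,5]
    is_medication: np.ndarray  # bool mask per pair
    regimes: np.ndarray  # filler regime id, -1 for medication pairs

    def similarity(self, agent_a: str, agent_b: str) -> float:
        i = self.agent_names.index(agent_a)
        j = self.agent_names.index(agent_b)
        return float(self.agent_similarity[i, j])


def make_latent_agents(
    n_agents: int, seed: int = 0
) -> tuple[list[str], np.ndarray]:
    """Invent agent names and a transitivity-friendly similarity matrix.

    Each agent gets a 3-dimensional latent embedding; similarity is
    ``5 exp(−d/2)`` of the Euclidean distance, giving a symmetric matrix
    in (0, 5] with diagonal exactly 5 in which nearby agents share nearby
    neighbourhoods — the transitive structure the graph model relies on.
    """
    if n_agents < 2:
        raise ValueError("need at least 2 agents")
    rng = np.random.default_rng(seed)
    names: list[str] = []
    seen: set[str] = set()
    suffixes = ("ol", "ine", "ide", "pril", "mab", "statin")
    while len(names) < n_agents:
        k = int(rng.integers(2, 4))
        name = "".join(_SYLLABLES[int(i)] for i in rng.integers(0, len(_SYLLABLES), k))
        name += suffixes[int(rng.integers(len(suffixes)))]
        if name not in seen:
            seen.add(name)
            names.append(name)
    emb = rng.standard_normal((n_agents, 3))
    d = np.sqrt(np.sum((emb[:, None, :] - emb[None, :, :]) ** 2, axis=-1))
    sim = SCORE_MAX * np.exp(-d / 2.0)
    np.fill_diagonal(sim, SCORE_MAX)
    return names, sim


def _agent_popularity(n_agents: int) -> np.ndarray:
    """Zipf-like sampling weights: a few agents dominate prescriptions."""
    w = 1.0 / np.arange(1, n_agents + 1) ** 0.8
    return w / w.sum()


def _sample_record(agent: str, rng: np.random.Generator) -> MedicationRecord:
    unit = "mg" if rng.random() < 0.9 else "mcg"
    form = "tablet" if rng.random() < 0.7 else "capsule"
    if rng.random() < 0.75:
        freq = float(rng.choice(_TIMES_PER_DAY))
    else:
        freq = float(rng.choice(_EVERY_HOURS))
    return MedicationRecord(
        active_agent=agent,
        strength_amount=float(rng.choice(_STRENGTHS)),
        strength_unit=unit,
        dose_amount=float(rng.choice(_DOSES)),
        dose_unit=form,
        frequency=freq,
    )


def sample_medication_pair(
    truth: SynthTruth,
    cfg: SynthConfig,
    rng: np.random.Generator,
    agents: tuple[int, int] | None = None,
) -> tuple[MedicationRecord, MedicationRecord, float, float]:
    """Draw one medication pair and its observed score.

    The observed score is ``clip(sim(a,b) − tanh(λ*·(1,Δ)) + ε, 0, 5)``
    with ε ~ N(0, noise_sd²).  Returns (record_a, record_b, observed
    score, true pre-noise score).  Agents are drawn with Zipf-like
    popularity weights unless given explicitly.
    """
    n = len(truth.agent_names)
    if agents is None:
        p = _agent_popularity(n)
        i, j = int(rng.choice(n, p=p)), int(rng.choice(n, p=p))
    else:
        i, j = agents
    rec_a = _sample_record(truth.agent_names[i], rng)
    rec_b = _sample_record(truth.agent_names[j], rng)
    delta = build_delta_vector(rec_a, rec_b)
    raw = truth.agent_similarity[i, j] - cfg.lambda_true.adjustment(delta)
    true_score = float(np.clip(raw, SCORE_MIN, SCORE_MAX))
    observed = raw + (rng.standard_normal() * cfg.noise_sd if cfg.noise_sd else 0.0)
    observed = float(np.clip(observed, SCORE_MIN, SCORE_MAX))
    return rec_a, rec_b, observed, true_score


def _number_phrase(x: float) -> str:
    if x == 0.5:
        return "one-half"
    return f"{x:g}"


def render_sentence(
    record: MedicationRecord,
    freq_style: str = "times_a_day",
    as_needed: bool = False,
) -> str:
    """Render a record as a templated prescription sentence.

    The rendering is deterministic for a fixed record and round-trips
    through the entity extractor.  ``freq_style`` selects between the
    "N times a day" and "every H hours" phrasings, both of which parse
    back to the same frequency number.
    """
    dose = record.dose_amount
    unit = record.dose_unit
    if dose == 1.0:
        dose_phrase = f"1 {unit}"
    elif dose == 0.5:
        dose_phrase = f"one-half {unit}"
    else:
        dose_phrase = f"{dose:g} {unit}s"
    freq = record.frequency
    if freq <= 0:
        freq_phrase = ""
    elif freq_style == "every_hours":
        freq_phrase = f" every {_number_phrase(freq)} hours"
    elif freq == 1.0:
        freq_phrase = " one time daily"
    else:
        freq_phrase = f" {_number_phrase(freq)} times a day"
    tail = " as needed" if as_needed else ""
    return (
        f"{record.active_agent} {record.strength_amount:g} "
        f"{record.strength_unit} {unit} {dose_phrase} by mouth"
        f"{freq_phrase}{tail}"
    )


def _filler_pair(
    regime: int, rng: np.random.Generator, noise_sd: float
) -> tuple[str, str, float]:
    """A narrative pair whose score follows a regime-specific mapping from
    sentence overlap: even regimes score high for high overlap, odd
    regimes invert the slope."""
    level = int(rng.integers(4))
    frame_a = _FRAMES[int(rng.integers(len(_FRAMES)))]
    topic_a = _TOPICS[int(rng.integers(len(_TOPICS)))]
    if level == 3:  # same frame, same topic
        frame_b, topic_b, overlap = frame_a, topic_a, 1.0
    elif level == 2:  # same topic, different frame
        frame_b = _FRAMES[int(rng.integers(len(_FRAMES)))]
        topic_b, overlap = topic_a, 0.6
    elif level == 1:  # same frame, different topic
        frame_b = frame_a
        topic_b = _TOPICS[int(rng.integers(len(_TOPICS)))]
        overlap = 0.4
    else:
        frame_b = _FRAMES[int(rng.integers(len(_FRAMES)))]
        topic_b = _TOPICS[int(rng.integers(len(_TOPICS)))]
        overlap = 0.1
    slope_up = regime % 2 == 0
    base = SCORE_MAX * (overlap if slope_up else 1.0 - overlap)
    score = base + (rng.standard_normal() * noise_sd if noise_sd else 0.0)
    score = float(np.clip(score, SCORE_MIN, SCORE_MAX))
    return frame_a.format(t=topic_a), frame_b.format(t=topic_b), score


def generate_corpus(cfg: SynthConfig) -> tuple[Corpus, SynthTruth]:
    """Generate a full synthetic corpus plus its latent truth.

    ``round(med_fraction * n_pairs)`` pairs are rendered prescriptions
    scored by the latent agent-similarity model; the rest are narrative
    filler pairs with regime-structured scores.  Medication and filler
    pairs are interleaved at seeded random positions.
    """
    rng = np.random.default_rng(cfg.seed)
    names, sim = make_latent_agents(cfg.n_agents, cfg.seed)
    n_med = int(round(cfg.med_fraction * cfg.n_pairs))
    med_positions = set(
        int(i) for i in rng.choice(cfg.n_pairs, size=n_med, replace=False)
    )
    truth = SynthTruth(
        agent_names=names,
        agent_similarity=sim,
        records=[None] * cfg.n_pairs,
        true_scores=np.zeros(cfg.n_pairs),
        is_medication=np.zeros(cfg.n_pairs, dtype=bool),
        regimes=np.full(cfg.n_pairs, -1, dtype=int),
    )
    pairs: list[SentencePair] = []
    n_filler = 0
    for idx in range(cfg.n_pairs):
        if idx in med_positions:
            rec_a, rec_b, observed, true_score = sample_medication_pair(
                truth, cfg, rng
            )
            style_a = "every_hours" if rng.random() < 0.25 else "times_a_day"
            style_b = "every_hours" if rng.random() < 0.25 else "times_a_day"
            sent_a = render_sentence(rec_a, style_a, as_needed=rng.random() < 0.3)
            sent_b = render_sentence(rec_b, style_b, as_needed=rng.random() < 0.3)
            truth.records[idx] = (rec_a, rec_b)
            truth.true_scores[idx] = true_score
            truth.is_medication[idx] = True
            pairs.append(SentencePair(idx, sent_a, sent_b, observed))
        else:
            regime = n_filler % cfg.n_regimes
            n_filler += 1
            sent_a, sent_b, score = _filler_pair(regime, rng, cfg.noise_sd)
            truth.true_scores[idx] = score
            truth.regimes[idx] = regime
            pairs.append(SentencePair(idx, sent_a, sent_b, score))
    return Corpus(pairs), truth
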