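"""Prescription entity extraction and entity-difference features.

Clinical prescription sentences are highly templated, e.g.::

    ibuprofen 150 mg tablet 2 tablets by mouth every 7 hours as needed
    furosemide [LASIX] 40 mg tablet 1 tablet by mouth two times a day

A rule-based extractor targets this template and yields a
:class:`MedicationRecord` with five comparable entities: strength amount,
strength unit, dose amount, dose unit, and dosing frequency.  Between the
two sentences of a pair these become an N=5 difference vector Δ —
an exact-match indicator for the nominal entities (units) and the squared
difference for the ratio-scaled ones (amounts, frequency).  Δ is the input
to the tanh adjustment used by the medication graph.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass

import numpy as np

from .corpus_io import SentencePair

logger = logging.getLogger(__name__)

N_DELTA_FEATURES = 5
#: Component order of the Δ vector.
DELTA_NAMES = (
    "strength_amount",
    "strength_unit",
    "dose_amount",
    "dose_unit",
    "frequency",
)

#: Sentinel values used when an otherwise-matching sentence lacks an entity.
MISSING_AMOUNT = 0.0
MISSING_UNIT = "none"

_NUMBER_WORDS = {
    "one-half": 0.5,
    "one half": 0.5,
    "half": 0.5,
    "one": 1.0,
    "two": 2.0,
    "three": 3.0,
    "four": 4.0,
    "five": 5.0,
    "six": 6.0,
    "seven": 7.0,
    "eight": 8.0,
    "nine": 9.0,
    "ten": 10.0,
    "eleven": 11.0,
    "twelve": 12.0,
}

_UNIT_SYNONYMS = {
    "milligram": "mg",
    "milligrams": "mg",
    "microgram": "mcg",
    "micrograms": "mcg",
    "gram": "g",
    "grams": "g",
    "milliliter": "ml",
    "milliliters": "ml",
    "tab": "tablet",
    "tabs": "tablet",
    "cap": "capsule",
    "caps": "capsule",
}

_STRENGTH_UNITS = r"mg|milligrams?|mcg|micrograms?|g|grams?|ml|milliliters?|units?|meq"
_FORMS = r"tablets?|tabs?|capsules?|caps?|pills?"
_NUM = r"\d+(?:\.\d+)?"
_NUM_WORD = "|".join(
    re.escape(w) for w in sorted(_NUMBER_WORDS, key=len, reverse=True)
)

_PRESCRIPTION_RE = re.compile(
    rf"""
    ^\s*
    (?P<agent>[a-z][a-z0-9\-/]*(?:\s+[a-z][a-z0-9\-/]*)*?)      # active agent
    \s*(?:\[[^\]]+\])?                                          # [BRAND]
    \s+(?P<samt>{_NUM})\s*(?P<sunit>{_STRENGTH_UNITS})          # strength
    \s+(?:{_FORMS})                                             # form word
    (?:\s+(?P<damt>{_NUM}|{_NUM_WORD})\s+(?P<dunit>{_FORMS}))?  # dose
    (?:\s+by\s+mouth)?
    (?:\s+(?P<freq>
        every\s+(?:{_NUM}|{_NUM_WORD})\s+hours?
        | (?:{_NUM}|{_NUM_WORD})\s+times?\s+(?:a\s+day|daily|per\s+day)
        | one\s+time\s+daily
        | once\s+(?:daily|a\s+day)
        | every\s+(?:morning|evening|night|day)
        | at\s+bedtime
        | daily
    ))?
    (?:\s+as\s+needed)?
    \s*\.?\s*$
    """,
    re.VERBOSE,
)

_FREQ_EVERY_H = re.compile(rf"every\s+({_NUM}|{_NUM_WORD})\s+hours?")
_FREQ_TIMES = re.compile(rf"({_NUM}|{_NUM_WORD})\s+times?\s+(?:a\s+day|daily|per\s+day)")


@dataclass(frozen=True)
class MedicationRecord:
    """Entities extracted from one prescription sentence."""

    active_agent: str
    strength_amount: float
    strength_unit: str
    dose_amount: float
    dose_unit: str
    frequency: float

    def __post_init__(self) -> None:
        if not self.active_agent:
            raise ValueError("active_agent must be non-empty")
        for name in ("strength_amount", "dose_amount", "frequency"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and >= 0, got {v}")


def normalize_unit(unit: str) -> str:
    """Lowercase a unit string and collapse synonyms (mg/milligram, tab/tablet)."""
    u = unit.strip().lower()
    return _UNIT_SYNONYMS.get(u, u)


def _parse_number(token: str) -> float:
    token = token.strip().lower()
    if token in _NUMBER_WORDS:
        return _NUMBER_WORDS[token]
    return float(token)


def _parse_frequency(text: str) -> float:
    """Map a frequency phrase to a single ratio-scaled number.

    ``every H hours`` yields H; ``N times a day`` yields N; once-daily
    phrasings yield 1.
    """
    m = _FREQ_EVERY_H.search(text)
    if m:
        return _parse_number(m.group(1))
    m = _FREQ_TIMES.search(text)
    if m:
        return _parse_number(m.group(1))
    return 1.0  # once-daily phrasings


def extract_medication(sentence: str) -> MedicationRecord | None:
    """Parse a prescription sentence into a :class:`MedicationRecord`.

    Returns ``None`` when the sentence does not match the prescription
    template.  Bracketed brand names are stripped from the agent; agent and
    units are lowercased.  A matching sentence with a missing dose or
    frequency is filled with sentinel values (amount 0, unit "none") so the
    Δ vector stays defined, and a warning is logged.
    """
    m = _PRESCRIPTION_RE.match(sentence.strip().lower())
    if m is None:
        return None
    agent = " ".join(m.group("agent").split())
    if m.group("damt") is not None:
        dose_amount = _parse_number(m.group("damt"))
        dose_unit = normalize_unit(re.sub(r"s$", "", m.group("dunit")))
    else:
        logger.warning("no dose found in prescription sentence: %r", sentence)
        dose_amount, dose_unit = MISSING_AMOUNT, MISSING_UNIT
    if m.group("freq") is not None:
        frequency = _parse_frequency(m.group("freq"))
    else:
        logger.warning("no frequency found in prescription sentence: %r", sentence)
        frequency = MISSING_AMOUNT
    return MedicationRecord(
        active_agent=agent,
        strength_amount=_parse_number(m.group("samt")),
        strength_unit=normalize_unit(m.group("sunit")),
        dose_amount=dose_amount,
        dose_unit=dose_unit,
        frequency=frequency,
    )


def delta_nominal(a: str, b: str) -> int:
    """Exact-match indicator for nominally scaled entities.

    0 when the two values agree after lowercasing and unit-synonym
    normalization, 1 otherwise.
    """
    if not a or not b:
        raise ValueError("nominal entity values must be non-empty")
    return 0 if normalize_unit(a) == normalize_unit(b) else 1


def delta_ratio(a: float, b: float) -> float:
    """Squared difference for ratio-scaled entities."""
    if not (np.isfinite(a) and np.isfinite(b)):
        raise ValueError("ratio entity values must be finite")
    return float(a - b) ** 2


def build_delta_vector(
    rec_a: MedicationRecord, rec_b: MedicationRecord
) -> np.ndarray:
    """The N=5 entity-difference vector Δ between two prescription records.

    Ordered (strength_amount, strength_unit, dose_amount, dose_unit,
    frequency); symmetric in its arguments.
    """
    return np.array(
        [
            delta_ratio(rec_a.strength_amount, rec_b.strength_amount),
            delta_nominal(rec_a.strength_unit, rec_b.strength_unit),
            delta_ratio(rec_a.dose_amount, rec_b.dose_amount),
            delta_nominal(rec_a.dose_unit, rec_b.dose_unit),
            delta_ratio(rec_a.frequency, rec_b.frequency),
        ],
        dtype=float,
    )


def is_medication_pair(pair: SentencePair) -> bool:
    """True iff both sentences of the pair parse as prescriptions."""
    return (
        extract_medication(pair.sentence_a) is not None
        and extract_medication(pair.sentence_b) is not None
    )
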