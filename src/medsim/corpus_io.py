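"""Reading and writing sentence-pair corpora.

The on-disk format is the tab-separated dialect used by clinical
semantic-textual-similarity shared tasks: one sentence pair per line,
``sentence_a<TAB>sentence_b`` with an optional third field carrying the
gold similarity score on the 0 (unrelated) to 5 (equivalent) scale.
No header, UTF-8, LF line endings.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

SCORE_MIN = 0.0
SCORE_MAX = 5.0


class CorpusFormatError(ValueError):
    """A line does not have the expected number of tab-separated fields."""


class ScoreValidationError(ValueError):
    """A score field is non-numeric or falls outside [0, 5]."""


@dataclass(frozen=True)
class SentencePair:
    """One annotated (or unannotated) clinical sentence pair.

    Parameters
    ----------
    pair_id:
        0-based position of the pair in its corpus file.
    sentence_a, sentence_b:
        The two sentences; non-empty after whitespace trimming.
    score:
        Gold similarity in [0, 5], or ``None`` for unannotated (test) pairs.
    """

    pair_id: int
    sentence_a: str
    sentence_b: str
    score: float | None = None

    def __post_init__(self) -> None:
        if not self.sentence_a.strip() or not self.sentence_b.strip():
            raise ValueError(f"pair {self.pair_id}: empty sentence")
        if self.score is not None and not (SCORE_MIN <= self.score <= SCORE_MAX):
            raise ScoreValidationError(
                f"pair {self.pair_id}: score {self.score} outside "
                f"[{SCORE_MIN}, {SCORE_MAX}]"
            )


@dataclass
class Corpus:
    """An ordered collection of sentence pairs."""

    pairs: list[SentencePair] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.pairs)

    def __iter__(self) -> Iterator[SentencePair]:
        return iter(self.pairs)

    def __getitem__(self, i: int) -> SentencePair:
        return self.pairs[i]

    @property
    def has_scores(self) -> bool:
        """True iff every pair carries a gold score."""
        return bool(self.pairs) and all(p.score is not None for p in self.pairs)

    def scores(self) -> list[float]:
        """Gold scores in pair order; requires a fully annotated corpus."""
        if not self.has_scores:
            raise ValueError("corpus is not fully annotated")
        return [p.score for p in self.pairs]  # type: ignore[misc]

    def subset(self, indices: Sequence[int]) -> "Corpus":
        """A new corpus containing the selected pairs (ids are kept)."""
        return Corpus([self.pairs[i] for i in indices])


def read_sts_tsv(path: str | Path, expect_scores: bool = True) -> Corpus:
    """Read a sentence-pair TSV file.

    Each line must have exactly three tab-separated fields when
    ``expect_scores`` is true, and exactly two otherwise.  Scores are
    validated against the [0, 5] range.  Lines with any other field count
    are rejected (sentences are assumed to contain no tabs).
    """
    path = Path(path)
    n_fields = 3 if expect_scores else 2
    pairs: list[SentencePair] = []
    with path.open(encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh):
            line = raw.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != n_fields:
                raise CorpusFormatError(
                    f"{path}:{lineno + 1}: expected {n_fields} tab-separated "
                    f"fields, found {len(fields)}"
                )
            score: float | None = None
            if expect_scores:
                try:
                    score = float(fields[2])
                except ValueError as exc:
                    raise ScoreValidationError(
                        f"{path}:{lineno + 1}: non-numeric score {fields[2]!r}"
                    ) from exc
            try:
                pairs.append(
                    SentencePair(len(pairs), fields[0], fields[1], score)
                )
            except ValueError as exc:
                raise type(exc)(f"{path}:{lineno + 1}: {exc}") from exc
    return Corpus(pairs)


def write_sts_tsv(corpus: Corpus, path: str | Path) -> None:
    """Write a corpus back to the TSV dialect (scores included if present)."""
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="\n") as fh:
        for p in corpus:
            if p.score is None:
                fh.write(f"{p.sentence_a}\t{p.sentence_b}\n")
            else:
                fh.write(f"{p.sentence_a}\t{p.sentence_b}\t{p.score!r}\n")


def write_predictions(
    corpus: Corpus, scores: Sequence[float], path: str | Path
) -> None:
    """Write one predicted score per line, aligned with pair order.

    Scores are serialized with ``repr`` precision so they survive a
    read/write round trip to well below 1e-9.
    """
    if len(scores) != len(corpus):
        raise ValueError(
            f"{len(scores)} scores for {len(corpus)} pairs"
        )
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="\n") as fh:
        for s in scores:
            fh.write(f"{float(s)!r}\n")


def read_predictions(path: str | Path) -> list[float]:
    """Read a one-score-per-line prediction file."""
    with Path(path).open(encoding="utf-8") as fh:
        return [float(line) for line in fh if line.strip()]
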