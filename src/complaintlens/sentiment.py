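"""Lexicon-based sentiment scoring.

A document's sentiment score is the plain sum of its tokens' lexicon
scores; a token absent from the lexicon contributes exactly 0.  Polarity
follows the sign of the cumulative score: positive (>0), negative (<0),
neutral (=0).  No stemming, negation handling or degree adverbs — lookup
is exact token equality after Unicode NFC normalization.
"""

from __future__ import annotations

import unicodedata
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .errors import InputError


@dataclass
class SentimentLexicon:
    """Token → real-valued score map (Boson-style)."""

    entries: dict[str, float]
    duplicates_overwritten: int = 0

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, token: str) -> bool:
        return unicodedata.normalize("NFC", token) in self.entries

    @classmethod
    def from_pairs(cls, pairs: Mapping[str, float] | Iterable[tuple[str, float]]):
        items = pairs.items() if isinstance(pairs, Mapping) else pairs
        entries: dict[str, float] = {}
        dupes = 0
        for token, score in items:
            key = unicodedata.normalize("NFC", token)
            if key in entries:
                dupes += 1
            entries[key] = float(score)
        return cls(entries=entries, duplicates_overwritten=dupes)


@dataclass
class SentimentResult:
    doc_id: str
    score: float
    polarity: str  # "positive" | "negative" | "neutral"


def load_lexicon(path: str | Path) -> SentimentLexicon:
    """Load a TAB-separated word→score lexicon (UTF-8, '#' comments).

    Later duplicates overwrite earlier ones (counted and warned about);
    a malformed line raises :class:`InputError` with its line number.
    """
    pairs: list[tuple[str, float]] = []
    for lineno, line in enumerate(
        Path(path).read_text(encoding="utf-8").splitlines(), start=1
    ):
        stripped = line.strip()
        if not stripped or stripped.startswith("#"):
            continue
        parts = stripped.split("\t")
        if len(parts) != 2:
            raise InputError(
                f"{path}: malformed lexicon line {lineno}: {line!r} "
                "(expected word<TAB>score)"
            )
        token, raw_score = parts
        try:
            score = float(raw_score)
        except ValueError as exc:
            raise InputError(
                f"{path}: non-numeric score on line {lineno}: {raw_score!r}"
            ) from exc
        pairs.append((token, score))
    lexicon = SentimentLexicon.from_pairs(pairs)
    if not lexicon.entries:
        warnings.warn(f"{path}: empty lexicon", stacklevel=2)
    if lexicon.duplicates_overwritten:
        warnings.warn(
            f"{path}: {lexicon.duplicates_overwritten} duplicate lexicon "
            "entries overwritten",
            stacklevel=2,
        )
    return lexicon


def score_token(token: str, lexicon: SentimentLexicon) -> float:
    """The token's lexicon score, or exactly 0 when it has no entry."""
    return lexicon.entries.get(unicodedata.normalize("NFC", token), 0.0)


def classify_polarity(score: float) -> str:
    if score > 0:
        return "positive"
    if score < 0:
        return "negative"
    return "neutral"


def score_document(
    tokens: Sequence[str], lexicon: SentimentLexicon, doc_id: str = ""
) -> SentimentResult:
    """Cumulative score of every token occurrence; polarity by sign.

    An empty token list scores 0 and is neutral. Every occurrence counts:
    tokens are not deduplicated before scoring.
    """
    total = 0.0
    for token in tokens:
        total += score_token(token, lexicon)
    return SentimentResult(doc_id=doc_id, score=total, polarity=classify_polarity(total))


def polarity_distribution(
    results: Sequence[SentimentResult],
) -> tuple[dict[str, float], dict[str, int]]:
    """Proportions and counts over {positive, negative, neutral}."""
    if not results:
        raise InputError("polarity_distribution: empty result list")
    counts = {"positive": 0, "negative": 0, "neutral": 0}
    for res in results:
        counts[res.polarity] += 1
    n = len(results)
    proportions = {k: v / n for k, v in counts.items()}
    return proportions, counts
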