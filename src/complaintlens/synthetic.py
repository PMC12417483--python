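"""Deterministic synthetic-data generators.

Everything downstream is testable without any external download:
planted-blob point clouds for the clustering search, complaint corpora
with known topic and sentiment structure for the full text pipeline,
and three-level satisfaction records for the indicator computations.

All generators are pure functions of (spec, seed).  One base seed fans
out to per-generator streams through ``numpy`` SeedSequence spawn keys,
so adding a generator never perturbs the draws of an existing one.
Toy lexicon scores are small integers, making document scores exactly
representable and equality-assertable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import ConfigError
from .preprocess import ComplaintRecord, StopList
from .sentiment import SentimentLexicon

_STREAMS = {"blobs": 0, "corpus": 1, "satisfaction": 2}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(_STREAMS[stream],))
    )


# ---------------------------------------------------------------------------
# planted blobs
# ---------------------------------------------------------------------------

@dataclass
class BlobSpec:
    """Isotropic Gaussian blobs around fixed centers.

    Defaults: three unit-separated centers on a line, 15 points each with
    sigma 0.05 — tight, well-separated groups a density-based method must
    recover exactly.
    """

    centers: list[list[float]] = field(
        default_factory=lambda: [[0.0, 0.0], [1.0, 0.0], [2.0, 0.0]]
    )
    points_per_center: int = 15
    sigma: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if len(self.centers) < 1:
            raise ConfigError("BlobSpec: need at least one center")
        if self.sigma <= 0:
            raise ConfigError(f"BlobSpec: sigma must be > 0, got {self.sigma}")
        if self.points_per_center < 1:
            raise ConfigError("BlobSpec: points_per_center must be >= 1")


def make_blobs(spec: BlobSpec) -> tuple[np.ndarray, np.ndarray]:
    """(points, true labels); points i.i.d. Gaussian around each center."""
    rng = _rng(spec.seed, "blobs")
    centers = np.asarray(spec.centers, dtype=float)
    chunks, labels = [], []
    for idx, center in enumerate(centers):
        chunks.append(
            center + rng.normal(scale=spec.sigma, size=(spec.points_per_center,
                                                        centers.shape[1]))
        )
        labels.extend([idx] * spec.points_per_center)
    return np.vstack(chunks), np.array(labels, dtype=int)


# ---------------------------------------------------------------------------
# complaint corpus with planted topics
# ---------------------------------------------------------------------------

@dataclass
class Topic:
    """A planted complaint theme: keyword vocabulary + sentiment word pool."""

    name: str
    keywords: tuple[str, ...]
    sentiment_words: dict[str, int]


def default_topics() -> list[Topic]:
    """Two themes mirroring a before/after complaint mix.

    ``attitude``: service-attitude and environment grievances carrying
    strongly negative sentiment words; ``timeliness``: process-efficiency
    feedback with mildly positive-to-neutral sentiment.  Keyword sets are
    pairwise disjoint so topic recovery has an unambiguous ground truth,
    and every planted word is a fixed point of mechanical compression
    (no internal adjacent repeats), so the cleaned vocabulary stays
    inside the planted vocabulary.
    """
    return [
        Topic(
            name="attitude",
            keywords=(
                "rude", "reception", "environment", "ward",
                "counter", "conduct", "crowd", "noise",
            ),
            sentiment_words={"bad": -3, "awful": -4, "dirty": -2, "angry": -3},
        ),
        Topic(
            name="timeliness",
            keywords=(
                "triage", "schedule", "response", "explain",
                "discharge", "report", "waiting", "delay",
            ),
            sentiment_words={"helpful": 2, "clear": 1, "timely": 2, "kind": 3},
        ),
    ]


DEFAULT_STOPWORDS = ("the", "a", "of", "in", "we", "was", "at", "to")


@dataclass
class CorpusSpec:
    """Synthetic complaint corpus with known topic and sentiment structure."""

    n_docs: int = 60
    topics: list[Topic] = field(default_factory=default_topics)
    proportions: tuple[float, ...] | None = None  # default uniform
    tokens_per_doc: tuple[int, int] = (8, 14)  # topic keywords per doc
    sentiment_per_doc: tuple[int, int] = (2, 4)
    stopwords_per_doc: tuple[int, int] = (2, 5)
    seed: int = 0

    def __post_init__(self):
        if self.n_docs < 1:
            raise ConfigError("CorpusSpec: n_docs must be >= 1")
        seen: set[str] = set()
        for topic in self.topics:
            overlap = seen & set(topic.keywords)
            if overlap:
                raise ConfigError(
                    f"CorpusSpec: topic keyword sets overlap on {sorted(overlap)}"
                )
            seen |= set(topic.keywords)
        if self.proportions is not None:
            if len(self.proportions) != len(self.topics):
                raise ConfigError("CorpusSpec: one proportion per topic required")
            if abs(sum(self.proportions) - 1.0) > 1e-9:
                raise ConfigError("CorpusSpec: proportions must sum to 1")


def make_complaint_corpus(
    spec: CorpusSpec,
) -> tuple[list[ComplaintRecord], SentimentLexicon, StopList, np.ndarray, list[str]]:
    """Generate (records, toy lexicon, toy stoplist, topic labels, polarities).

    Each document mixes keywords sampled from its topic, sentiment words
    with known integer lexicon scores, and shared stop-words.  The true
    polarity is computed in closed form from the sampled sentiment words,
    so downstream sentiment scores can be asserted exactly.
    """
    rng = _rng(spec.seed, "corpus")
    n_topics = len(spec.topics)
    probs = (
        np.asarray(spec.proportions, float)
        if spec.proportions is not None
        else np.full(n_topics, 1.0 / n_topics)
    )
    lexicon_pairs: dict[str, float] = {}
    for topic in spec.topics:
        lexicon_pairs.update({w: float(s) for w, s in topic.sentiment_words.items()})
    lexicon = SentimentLexicon.from_pairs(lexicon_pairs)
    stoplist = StopList(DEFAULT_STOPWORDS)

    records: list[ComplaintRecord] = []
    topic_labels = np.empty(spec.n_docs, dtype=int)
    polarities: list[str] = []
    for i in range(spec.n_docs):
        t = int(rng.choice(n_topics, p=probs))
        topic = spec.topics[t]
        topic_labels[i] = t
        n_kw = int(rng.integers(spec.tokens_per_doc[0], spec.tokens_per_doc[1] + 1))
        n_sent = int(rng.integers(spec.sentiment_per_doc[0],
                                  spec.sentiment_per_doc[1] + 1))
        n_stop = int(rng.integers(spec.stopwords_per_doc[0],
                                  spec.stopwords_per_doc[1] + 1))
        tokens = list(rng.choice(topic.keywords, size=n_kw, replace=True))
        sent_words = list(rng.choice(list(topic.sentiment_words), size=n_sent,
                                     replace=True))
        tokens += sent_words
        tokens += list(rng.choice(DEFAULT_STOPWORDS, size=n_stop, replace=True))
        rng.shuffle(tokens)
        true_score = sum(topic.sentiment_words[w] for w in sent_words)
        polarities.append(
            "positive" if true_score > 0 else "negative" if true_score < 0
            else "neutral"
        )
        day = int(rng.integers(1, 29))
        month = int(rng.integers(1, 13))
        records.append(
            ComplaintRecord(
                record_id=f"doc{i:03d}",
                date=f"2023-{month:02d}-{day:02d}",
                channel="internal" if rng.random() < 0.5 else "external",
                raw_text=" ".join(tokens),
            )
        )
    return records, lexicon, stoplist, topic_labels, polarities


# ---------------------------------------------------------------------------
# satisfaction records
# ---------------------------------------------------------------------------

SATISFACTION_LEVELS = ("satisfied", "generally_satisfied", "dissatisfied")


def make_satisfaction_records(
    n: int, probs: Sequence[float], seed: int = 0
) -> list[str]:
    """n multinomial draws over the three satisfaction levels."""
    probs = np.asarray(probs, dtype=float)
    if probs.shape != (3,) or (probs < 0).any() or abs(probs.sum() - 1.0) > 1e-9:
        raise ConfigError(
            f"make_satisfaction_records: probs must be a 3-vector summing to 1, "
            f"got {probs.tolist()}"
        )
    if n < 1:
        raise ConfigError("make_satisfaction_records: n must be >= 1")
    rng = _rng(seed, "satisfaction")
    draws = rng.choice(3, size=n, p=probs)
    return [SATISFACTION_LEVELS[i] for i in draws]


def tabulate_satisfaction(records: Sequence[str]):
    """Collapse level strings into a :class:`SatisfactionTable`."""
    from .indicators import SatisfactionTable

    counts = {level: 0 for level in SATISFACTION_LEVELS}
    for r in records:
        counts[r] += 1
    return SatisfactionTable(
        satisfied=counts["satisfied"],
        generally_satisfied=counts["generally_satisfied"],
        dissatisfied=counts["dissatisfied"],
    )
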