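"""Per-cluster keyword summaries and period-level negative-sentiment reports.

Keyword salience is within-cluster term frequency × corpus-wide idf, so
corpus boilerplate that appears in every cluster ("hospital", "doctor")
is down-weighted relative to terms that characterize one cluster.  The
period report aggregates the scores of negative-polarity documents
(mean by default; sum and min selectable) — the larger the magnitude of
the aggregate, the deeper the negative emotion in that period.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import ConfigError
from .kann_dbscan import NOISE
from .sentiment import SentimentResult
from .vectorize import idf_vector

AGGREGATES = ("mean", "sum", "min")


@dataclass
class ClusterKeywordSummary:
    cluster_id: int
    keywords: list[tuple[str, float]]  # (term, salience), salience descending
    size: int


@dataclass
class PeriodReport:
    period: str
    negative_score: float | None  # absent (None) when no negative documents
    aggregate: str
    polarity_counts: dict[str, int]
    clusters: list[ClusterKeywordSummary]
    noise_size: int = 0

    def to_dict(self) -> dict:
        return {
            "period": self.period,
            "negative_score": self.negative_score,
            "aggregate": self.aggregate,
            "polarity_counts": self.polarity_counts,
            "noise_size": self.noise_size,
            "clusters": [
                {
                    "cluster_id": c.cluster_id,
                    "size": c.size,
                    "keywords": [
                        {"term": t, "salience": s} for t, s in c.keywords
                    ],
                }
                for c in self.clusters
            ],
        }


def cluster_keywords(
    docs: Sequence[Sequence[str]],
    labels: Sequence[int],
    top_n: int = 5,
) -> list[ClusterKeywordSummary]:
    """Ranked (term, salience) lists per cluster.

    salience(term, c) = tf(term within cluster c) × idf(term over the whole
    corpus).  Ties break lexicographically.  Noise documents are excluded
    from summaries.  An all-noise labeling yields an empty list with a
    warning.
    """
    if len(docs) != len(labels):
        raise ConfigError(
            f"cluster_keywords: {len(docs)} docs but {len(labels)} labels"
        )
    if top_n < 1:
        raise ConfigError(f"top_n must be >= 1, got {top_n}")
    labels = np.asarray(labels, dtype=int)
    cluster_ids = sorted(set(labels.tolist()) - {NOISE})
    if not cluster_ids:
        warnings.warn("cluster_keywords: all documents labeled noise", stacklevel=2)
        return []

    vocabulary = sorted({t for doc in docs for t in doc})
    idf = dict(zip(vocabulary, idf_vector(docs, vocabulary)))

    summaries = []
    for cid in cluster_ids:
        member_docs = [docs[i] for i in np.nonzero(labels == cid)[0]]
        tf: dict[str, int] = {}
        for doc in member_docs:
            for token in doc:
                tf[token] = tf.get(token, 0) + 1
        ranked = sorted(
            ((term, count * idf[term]) for term, count in tf.items()),
            key=lambda item: (-item[1], item[0]),
        )
        summaries.append(
            ClusterKeywordSummary(
                cluster_id=int(cid), keywords=ranked[:top_n], size=len(member_docs)
            )
        )
    return summaries


def negative_report(
    results: Sequence[SentimentResult],
    labels: Sequence[int],
    summaries: list[ClusterKeywordSummary],
    period: str,
    aggregate: str = "mean",
) -> PeriodReport:
    """Period-level negative-sentiment aggregate plus cluster summaries.

    With no negative-polarity documents the negative score is reported as
    absent (``None``) rather than zero, which would misleadingly read as
    "neutral on average".
    """
    if aggregate not in AGGREGATES:
        raise ConfigError(f"unknown aggregate {aggregate!r}; one of {AGGREGATES}")
    if len(results) != len(labels):
        raise ConfigError(
            f"negative_report: {len(results)} results but {len(labels)} labels"
        )
    counts = {"positive": 0, "negative": 0, "neutral": 0}
    negatives: list[float] = []
    for res in results:
        counts[res.polarity] += 1
        if res.polarity == "negative":
            negatives.append(res.score)
    if negatives:
        if aggregate == "mean":
            score = float(np.mean(negatives))
        elif aggregate == "sum":
            score = float(np.sum(negatives))
        else:
            score = float(np.min(negatives))
    else:
        score = None
    noise_size = int(np.sum(np.asarray(labels, dtype=int) == NOISE))
    return PeriodReport(
        period=period,
        negative_score=score,
        aggregate=aggregate,
        polarity_counts=counts,
        clusters=summaries,
        noise_size=noise_size,
    )


def most_negative_cluster(
    results: Sequence[SentimentResult], labels: Sequence[int]
) -> int | None:
    """Cluster id with the lowest mean sentiment score (noise excluded)."""
    labels = np.asarray(labels, dtype=int)
    scores = np.array([r.score for r in results])
    best_id, best_mean = None, np.inf
    for cid in sorted(set(labels.tolist()) - {NOISE}):
        mean = scores[labels == cid].mean()
        if mean < best_mean:
            best_id, best_mean = int(cid), mean
    return best_id
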