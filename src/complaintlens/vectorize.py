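"""Token lists → numeric vectors for clustering.

Weighting is TF-IDF with the smoothed logarithmic idf

    idf(t) = ln((1 + n_docs) / (1 + df(t))) + 1

over raw term counts (``tf`` and ``binary`` weightings are also
available).  Columns are ordered lexicographically by term so the matrix
is reproducible regardless of corpus iteration order.  Standardization
centers each column and scales by the population standard deviation
(constant columns map to zero).  PCA is a plain centered SVD with a
deterministic sign convention: each component's largest-magnitude
loading is made positive.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import ConfigError, InputError

WEIGHTINGS = ("tfidf", "tf", "binary")


@dataclass
class DocTermMatrix:
    doc_ids: list[str]
    vocabulary: list[str]
    weights: np.ndarray  # (n_docs, n_terms)

    @property
    def shape(self) -> tuple[int, int]:
        return self.weights.shape


@dataclass
class PCAResult:
    scores: np.ndarray  # (n_docs, n_components)
    explained_variance_ratio: np.ndarray
    components: np.ndarray  # (n_components, n_terms)


def idf_vector(corpus: Sequence[Sequence[str]], vocabulary: Sequence[str]) -> np.ndarray:
    """Smoothed log idf per vocabulary term (document frequency based)."""
    n_docs = len(corpus)
    doc_sets = [set(doc) for doc in corpus]
    df = np.array([sum(term in s for s in doc_sets) for term in vocabulary], float)
    return np.log((1.0 + n_docs) / (1.0 + df)) + 1.0


def tfidf(
    corpus: Sequence[Sequence[str]],
    doc_ids: Sequence[str] | None = None,
    weighting: str = "tfidf",
) -> DocTermMatrix:
    """Weighted document-term matrix with lexicographic vocabulary order."""
    if weighting not in WEIGHTINGS:
        raise ConfigError(f"unknown weighting {weighting!r}; one of {WEIGHTINGS}")
    if not corpus or all(len(doc) == 0 for doc in corpus):
        raise InputError("tfidf: all documents are empty")
    if doc_ids is None:
        doc_ids = [str(i) for i in range(len(corpus))]
    vocabulary = sorted({t for doc in corpus for t in doc})
    index = {t: j for j, t in enumerate(vocabulary)}
    counts = np.zeros((len(corpus), len(vocabulary)))
    for i, doc in enumerate(corpus):
        for token in doc:
            counts[i, index[token]] += 1.0
    if weighting == "binary":
        weights = (counts > 0).astype(float)
    elif weighting == "tf":
        weights = counts
    else:
        weights = counts * idf_vector(corpus, vocabulary)
    return DocTermMatrix(doc_ids=list(doc_ids), vocabulary=vocabulary, weights=weights)


def standardize(matrix: np.ndarray) -> np.ndarray:
    """Zero-mean / unit-variance columns (population scaling).

    Constant columns become all-zero instead of dividing by zero.
    """
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim != 2 or matrix.shape[0] < 2:
        raise InputError("standardize: need a 2-D matrix with at least 2 rows")
    centered = matrix - matrix.mean(axis=0)
    std = matrix.std(axis=0)  # population (ddof=0)
    scale = np.where(std > 0, std, 1.0)
    out = centered / scale
    out[:, std == 0] = 0.0
    return out


def pca_reduce(matrix: np.ndarray, target: int | float) -> PCAResult:
    """Project onto leading principal components.

    ``target`` is either an explicit component count or a retained-variance
    fraction in (0, 1]; with a fraction the smallest component count whose
    cumulative explained-variance ratio reaches it is used.
    """
    matrix = np.asarray(matrix, dtype=float)
    n_docs, n_terms = matrix.shape
    max_comps = min(n_docs, n_terms)

    centered = matrix - matrix.mean(axis=0)
    u, s, vt = np.linalg.svd(centered, full_matrices=False)
    variances = s**2 / n_docs
    total = variances.sum()
    ratios = variances / total if total > 0 else np.zeros_like(variances)

    if isinstance(target, (int, np.integer)) and not isinstance(target, bool):
        n_comps = int(target)
        if not 1 <= n_comps <= max_comps:
            raise ConfigError(
                f"pca_reduce: component count {n_comps} outside 1..{max_comps}"
            )
    elif isinstance(target, float):
        if not 0 < target <= 1:
            raise ConfigError(
                f"pca_reduce: variance fraction {target} outside (0, 1]"
            )
        cumulative = np.cumsum(ratios)
        reached = np.nonzero(cumulative >= target - 1e-12)[0]
        n_comps = int(reached[0]) + 1 if reached.size else max_comps
    else:
        raise ConfigError(f"pca_reduce: invalid target {target!r}")

    components = vt[:n_comps]
    # sign convention: largest-|loading| entry of each component positive
    flips = np.sign(components[np.arange(n_comps), np.abs(components).argmax(axis=1)])
    flips[flips == 0] = 1.0
    components = components * flips[:, None]
    scores = centered @ components.T
    return PCAResult(
        scores=scores,
        explained_variance_ratio=ratios[:n_comps],
        components=components,
    )


def default_feature_pipeline(
    corpus: Sequence[Sequence[str]],
    doc_ids: Sequence[str] | None = None,
    weighting: str = "tfidf",
    pca_vocab_threshold: int = 100,
) -> tuple[np.ndarray, DocTermMatrix]:
    """tfidf → standardize → (PCA when the vocabulary is large).

    PCA to min(50, n_docs − 1) components kicks in only when the vocabulary
    exceeds ``pca_vocab_threshold`` terms; returns (features, doc-term matrix).
    """
    dtm = tfidf(corpus, doc_ids=doc_ids, weighting=weighting)
    features = standardize(dtm.weights)
    if len(dtm.vocabulary) > pca_vocab_threshold:
        n_comps = min(50, len(corpus) - 1)
        features = pca_reduce(features, n_comps).scores
    return features, dtm
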