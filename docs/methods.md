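# Methods

## Scope and model

`complaintlens` analyzes free-text patient complaints in four linked steps:
text preprocessing, lexicon-based sentiment scoring, adaptive density-based
clustering, and service-quality indicators. The underlying assumptions are
deliberately simple and auditable: sentiment is additive over token
occurrences with exact-match lexicon lookup (no stemming, negation or degree
adverbs), and complaint themes are regions of high density in TF-IDF space
rather than output of a fitted topic model.

## Preprocessing

Records whose free-text content is missing are excluded and counted
(`rows_read = records + dropped` always holds); a record with an
unparseable date is kept with the sentinel `—` in its date field — accepted
date forms are ISO-8601 and `YYYY/MM/DD`, anything else sentinels rather
than errors, because a bad timestamp does not invalidate a complaint.
Unicode NFC normalization is applied before tokenization and stop-word
matching so composed and combining character forms compare equal.

**Mechanical compression** removes machine-pasted repetition: any maximal
adjacent run of a repeated unit of length ≤ `max_unit` (default 5) collapses
to one occurrence, scanning left to right shortest-unit-first and iterating
to a fixed point. The unit bound of 5 covers doubled short words plus their
separator ("bad bad" style paste artifacts) while leaving natural prose
intact; the fixed-point iteration makes the operation idempotent by
construction. Compression is applied to raw text, before segmentation, so
repeats that span token boundaries are caught.

Segmentation is registry-based. `whitespace` is the default and the one the
test suite relies on; `simple-cjk` is a compact built-in greedy
longest-match dictionary segmenter for CJK text, and a `jieba` adapter is
registered automatically when that library is importable.

## Sentiment scoring

Document score = Σ of per-token lexicon scores, with unknown tokens scoring
exactly 0 and polarity strictly by sign (neutral means exactly 0). Tokens
are not deduplicated: every occurrence contributes. Scores are compared
exactly in tests because sums of a fixed lexicon's values are reproducible
floating-point quantities; the synthetic lexicon uses small integers so
document scores are exactly representable.

## Vectorization

The text-to-vector mapping ahead of clustering is this package's own
choice (configurable via `weighting: tfidf|tf|binary`): TF-IDF with
`idf(t) = ln((1+n_docs)/(1+df(t))) + 1` over raw counts, vocabulary ordered
lexicographically for determinism. Standardization divides by the
*population* standard deviation (constant columns map to zero), which makes
a two-point column standardize to exactly ±1. PCA is a centered SVD with a
deterministic sign convention — each component's largest-magnitude loading
is made positive — and engages by default only when the vocabulary exceeds
100 terms, reducing to min(50, n_docs − 1) components.

## KANN-DBSCAN

Parameter conventions that the classical description leaves open are fixed
as follows:

- ε-neighborhoods include the point itself (classical MinPts counting), so
  `pmin_expectation` at ε = 0 is exactly 1 for distinct points.
- `Pmin` stays real-valued: the neighborhood-size expectation is generally
  fractional and the core test is `count ≥ Pmin`; rounding would introduce
  an arbitrary extra rule.
- Border points (non-core within ε of ≥ 1 core point) join the cluster of
  the lowest-index such core point — deterministic and order-stable given a
  canonical input order. Core-point partitions are provably independent of
  point order; only this border tie-break depends on it.
- Cluster ids are renumbered 0..N−1 by smallest member index; noise is −1.
- The ε-candidate index range is 1..n−1: the n-th column of the sorted
  distance profile has no neighbor distinct from the point itself.
- The stability scan stops at the first deviation from the stable count N
  (no restart): the largest k still yielding N before that deviation wins.
  When every k in range yields the same count (e.g. identical points), the
  maximum k of the range is selected.
- `k_range` defaults to 1..min(n−1, 60). A fixed-parameter mode
  (`--fixed-k` / `--fixed-eps`, e.g. k = 20 with ε = 0.5) bypasses the
  search entirely for operational settings where parameters are prescribed.

Distances are euclidean by default (cosine available) and computed exactly
(n×n); no approximate-neighbor index is used at the corpus sizes this
package targets (hundreds to a few thousand complaints).

## Reports and indicators

Keyword salience is within-cluster term frequency × whole-corpus idf, which
suppresses corpus-wide boilerplate that raw frequency would rank first in
every cluster; ties break lexicographically. The period-level negative
score aggregates the scores of negative-polarity documents — mean by
default, sum and min selectable — and is reported as *absent* (not 0) when
no negative documents exist, since 0 would read as "neutral on average".
Because the aggregate of negative scores is itself negative, the report
speaks of the score's *magnitude* when describing emotional intensity.

Overall satisfaction and the rate indicators are computed from raw counts at
full precision, with half-up rounding to 2 decimals only for display. The
2×2 chi-square defaults to the uncorrected closed form with Yates'
correction optional; multivariable regression and t-tests are deliberately
out of scope (routine fits that standard statistics tooling covers; the CSV
outputs are structured to feed such tools).

## Synthetic data

Generators are pure functions of (spec, seed); one base seed fans out to
per-generator streams through SeedSequence spawn keys so adding a generator
never perturbs existing draws.

- **Blobs**: default three unit-separated centers, 15 points each,
  σ = 0.05 — well inside the recoverability regime (σ ≤ 0.1 × separation)
  where the parameter search must return N = 3.
- **Corpus**: default 60 documents over two topics with pairwise-disjoint
  8-word keyword vocabularies, 8–14 topic keywords, 2–4 sentiment words
  (known integer scores, one sign per topic) and 2–5 stop-words per
  document. Every planted word is a fixed point of mechanical compression
  (no internal adjacent repeats), so the cleaned vocabulary provably stays
  inside the planted vocabulary and true polarities survive preprocessing.
- **Satisfaction records**: multinomial draws over the three survey levels.

What the synthetic corpus does *not* emulate: real clinical-complaint
language (Chinese or otherwise), topic overlap, spelling variation, or
correlation between topic and record metadata. Passing tests therefore
demonstrate that the machinery is correct and recovers planted structure in
a favorable regime — not that a particular real corpus will cluster as
cleanly.

## Numerical choices and edge cases

Distance matrices are symmetrized ((D + Dᵀ)/2) with the diagonal forced to
zero to absorb floating-point round-off. Monotonicity checks use a 1e-12
slack. Degenerate inputs are defined, not rejected: identical points form
one cluster with no noise; an all-noise labeling produces an empty keyword
summary with a warning; an empty token list scores 0 / neutral; an empty
stop list is the identity filter.

## Problem sizes

Defaults throughout were chosen to exercise each property at the scale of
its contract: 200 random instances (n ≤ 40) for the DBSCAN/graph-oracle
equivalence, 20 seeds for blob and planted-topic recovery, 100 random
matrices for ε-candidate monotonicity, and 500 random token lists for the
sentiment contract. The whole suite runs in well under a minute on one CPU.

## Known limitations

- Lexicon lookup is exact-match only; morphology, negation ("not good") and
  intensity adverbs change nothing.
- DBSCAN struggles with overlapping clusters and strongly varying density;
  the stability search inherits the heuristic character of k-distance
  analysis and can legitimately report "no stable clustering".
- Mechanical compression collapses *any* adjacent repeat of unit length
  ≤ max_unit, including legitimate doubled words ("very very") — by design,
  at the cost of occasionally shortening emphatic repetition.
- The per-cluster keyword report ranks by tf×idf salience; it does not
  produce model-based topic descriptors.
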