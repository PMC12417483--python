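# complaintlens

Text analytics for hospital patient complaints. Free-text complaint records
are a primary signal of service quality, but they arrive as unstructured
prose: `complaintlens` turns a complaint table into (1) per-record sentiment
scores against a public-style lexicon, (2) density-based complaint clusters
with automatically chosen parameters, (3) per-cluster keyword summaries and a
period-level negative-sentiment report, and (4) standard service-quality
indicators (overall satisfaction, petition/compensation rates, chi-square
group comparisons). It is built for health-services and patient-experience
analysts who need a reproducible pipeline rather than a one-off notebook.

## Method

**Sentiment.** With a lexicon mapping word $x_n$ to score $z_n$, a tokenized
comment scores

$$\mathrm{score} = \sum_n \mathrm{score}_n,\qquad
\mathrm{score}_n = \begin{cases} z_n & x_n \in \text{lexicon} \\ 0 & \text{otherwise}\end{cases}$$

with polarity positive (> 0), negative (< 0) or neutral (= 0).

**Clustering (KANN-DBSCAN).** DBSCAN labels a point *core* when its
ε-neighborhood (self included) holds at least $P_{\min}$ points; clusters are
density-connected components, the rest is noise. Instead of hand-picking
$(\varepsilon, P_{\min})$, the K-average-nearest-neighbor procedure derives
them from the $n\times n$ distance matrix $D$:

1. sort each row of $D$ ascending; column $k$ is the k-th-nearest-neighbor
   distance vector $D_k$;
2. the candidate list is $D_\varepsilon = \{\bar D_k \mid 1 \le k \le n-1\}$,
   where $\bar D_k$ is the mean of column $k$;
3. for each candidate, $P_{\min} = \frac1n\sum_i P_i$ is the expected
   ε-neighborhood size;
4. DBSCAN runs for $k = 1, 2, \dots$; when the cluster count $N$ stays
   constant for three consecutive $k$ the result is stable, and the largest
   $k$ still yielding $N$ (before the first deviation) supplies the final
   $(\varepsilon^\ast, P_{\min}^\ast)$.

Text is vectorized with TF-IDF (smoothed log idf), standardized to zero mean
/ unit population variance, and optionally PCA-reduced before clustering.

**Indicators.** Overall satisfaction = (satisfied + generally satisfied) /
total × 100 % on a three-level survey; group comparisons use the closed-form
2×2 chi-square $X^2 = N(ad-bc)^2 / ((a{+}b)(c{+}d)(a{+}c)(b{+}d))$, with
Yates' correction optional.

## Worked example

Generate a synthetic 60-document corpus with two planted complaint topics
(a negative "service attitude" theme and a milder "timeliness" theme), then
run the whole pipeline from one config:

```sh
complaintlens synth corpus --n-docs 60 --seed 11 --out-dir data
cat > run.yaml <<EOF
input:
  complaints: data/complaints.csv
  lexicon: data/lexicon.tsv
  stopwords: data/stopwords.txt
output_dir: runs
EOF
complaintlens run --config run.yaml
```

which prints:

```
complaintlens stage preprocess: {'rows_read': 60, 'rows_dropped': 0, 'dates_sentineled': 0, 'records_out': 60}
complaintlens stage sentiment: {'docs_scored': 60, 'lexicon_size': 8}
complaintlens stage vectorize: {'n_docs': 60, 'n_features': 24, 'vocabulary': 24}
complaintlens stage cluster: {'n_clusters': 2, 'noise': 0, 'k': 23}
complaintlens stage report: {'clusters_summarized': 2}
complaintlens stage indicators: {'indicators': 3}
run complete → runs/run-0001
```

The parameter search settled on k\* = 23 (ε ≈ 6.11, Pmin ≈ 23.9) and
recovered both planted topics exactly. `runs/run-0001/report.json` then
contains the period report: a mean negative score of −7.91 over the 34
negative-polarity documents, and per-cluster keywords

```
cluster 0 (34 docs): counter, rude, noise, environment, crowd
cluster 1 (26 docs): report, delay, explain, response, triage
```

— cluster 0 is the most-negative cluster and its keywords are exactly the
planted attitude/environment vocabulary, i.e. the pipeline points at the
service dimension driving negative sentiment. Every artifact (tokens,
scores, feature matrix, labels, k-trace, report, indicators) is written with
a content hash into `runs/run-0001/manifest.json`; re-running the same
config reproduces identical hashes.

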