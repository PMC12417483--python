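"""End-to-end orchestration from a single config document.

Stage order follows the analysis flow: preprocess → sentiment →
vectorize → cluster → report → indicators.  Each stage writes its
artifacts into a fresh run directory and registers them, with content
hashes, in a machine-readable manifest; re-running an identical config
on identical inputs reproduces identical label assignments and scores
(and therefore identical artifact hashes — only the timestamp differs).
"""

from __future__ import annotations

import difflib
import hashlib
import json
import logging
import warnings
from dataclasses import dataclass
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .errors import ComplaintLensError, ConfigError
from .indicators import overall_satisfaction
from .kann_dbscan import pairwise_distances, select_parameters, solve_fixed
from .preprocess import (StopList, TableDialect, load_stoplist,
                         preprocess_records, read_complaints)
from .report import cluster_keywords, most_negative_cluster, negative_report
from .sentiment import load_lexicon, polarity_distribution, score_document
from .synthetic import tabulate_satisfaction
from .vectorize import default_feature_pipeline

logger = logging.getLogger("complaintlens")

_DEFAULTS: dict = {
    "input": {"complaints": None, "lexicon": None, "stopwords": None},
    "preprocess": {
        "segmenter": "whitespace",
        "max_unit": 5,
        "id_col": "id",
        "text_col": "text",
        "date_col": "date",
        "channel_col": "channel",
        "satisfaction_col": None,
    },
    "vectorize": {"weighting": "tfidf", "pca_vocab_threshold": 100},
    "clustering": {
        "metric": "euclidean",
        "k_range": None,  # default 1..min(n-1, 60)
        "stability_window": 3,
        "fixed_k": None,
        "fixed_eps": None,
    },
    "report": {"period": "all", "aggregate": "mean", "top_n": 5},
    "output_dir": "runs",
    "seed": 0,
}


@dataclass
class RunConfig:
    raw: dict

    def __getitem__(self, key):
        return self.raw[key]

    def to_dict(self) -> dict:
        return self.raw


def _merge_with_defaults(raw: dict, defaults: dict, prefix: str = "") -> dict:
    merged = {}
    for key, default in defaults.items():
        if key in raw:
            value = raw[key]
            if isinstance(default, dict) and isinstance(value, dict):
                merged[key] = _merge_with_defaults(value, default, f"{prefix}{key}.")
            else:
                merged[key] = value
        else:
            merged[key] = {k: v for k, v in default.items()} if isinstance(
                default, dict) else default
    for key in raw:
        if key not in defaults:
            hint = difflib.get_close_matches(key, defaults.keys(), n=1)
            suggestion = f" (did you mean {hint[0]!r}?)" if hint else ""
            warnings.warn(
                f"unknown config key {prefix}{key!r} ignored{suggestion}",
                stacklevel=2,
            )
    return merged


def validate_config(raw: dict | str | Path) -> RunConfig:
    """Parse, default-fill and validate a config document.

    Accepts a dict or a YAML/JSON file path.  Unknown keys produce
    warnings with a near-miss suggestion; missing required keys and
    out-of-range values raise :class:`ConfigError` naming the key.
    """
    if isinstance(raw, (str, Path)):
        try:
            raw = yaml.safe_load(Path(raw).read_text(encoding="utf-8"))
        except yaml.YAMLError as exc:
            raise ConfigError(f"unparseable config document: {exc}") from exc
    if not isinstance(raw, dict):
        raise ConfigError("config must be a mapping")
    merged = _merge_with_defaults(raw, _DEFAULTS)

    for key in ("complaints", "lexicon"):
        if not merged["input"].get(key):
            raise ConfigError(f"missing required config key input.{key}")
        path = Path(merged["input"][key])
        if not path.exists():
            raise ConfigError(f"input.{key}: path does not exist: {path}")
    sw = merged["input"].get("stopwords")
    if sw and not Path(sw).exists():
        raise ConfigError(f"input.stopwords: path does not exist: {sw}")

    k_range = merged["clustering"]["k_range"]
    if k_range is not None:
        if (len(k_range) != 2 or k_range[0] > k_range[1] or k_range[0] < 1):
            raise ConfigError(
                f"clustering.k_range must be [min, max] with 1 <= min <= max, "
                f"got {k_range}"
            )
        merged["clustering"]["k_range"] = (int(k_range[0]), int(k_range[1]))
    if merged["clustering"]["stability_window"] < 2:
        raise ConfigError("clustering.stability_window must be >= 2")
    if merged["report"]["aggregate"] not in ("mean", "sum", "min"):
        raise ConfigError("report.aggregate must be one of mean|sum|min")
    return RunConfig(raw=merged)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _new_run_dir(base: Path) -> Path:
    base.mkdir(parents=True, exist_ok=True)
    existing = [
        int(p.name.split("-")[1])
        for p in base.glob("run-*")
        if p.name.split("-")[1].isdigit()
    ]
    run_dir = base / f"run-{(max(existing) + 1) if existing else 1:04d}"
    run_dir.mkdir()
    return run_dir


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute all stages; returns the manifest (also written to disk)."""
    run_dir = _new_run_dir(Path(cfg["output_dir"]))
    manifest: dict = {
        "config": cfg.to_dict(),
        "package_versions": {
            "complaintlens": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "timestamp": datetime.now(timezone.utc).isoformat(),
        "run_dir": str(run_dir),
        "stages": {},
    }

    def register(stage: str, outputs: dict[str, Path], counts: dict):
        manifest["stages"][stage] = {
            "outputs": {name: _sha256(p) for name, p in outputs.items()},
            "counts": counts,
        }
        logger.info("stage %s: %s", stage, counts)

    def run_stage(stage, fn):
        try:
            return fn()
        except ComplaintLensError as exc:
            raise type(exc)(f"[stage {stage}] {exc}") from exc
        except Exception as exc:
            raise ComplaintLensError(f"[stage {stage}] {exc}") from exc

    # -- preprocess ---------------------------------------------------------
    def _preprocess():
        pre = cfg["preprocess"]
        dialect = TableDialect(
            id_col=pre["id_col"], text_col=pre["text_col"],
            date_col=pre["date_col"], channel_col=pre["channel_col"],
        )
        records, summary = read_complaints(cfg["input"]["complaints"], dialect)
        stoplist = (
            load_stoplist(cfg["input"]["stopwords"])
            if cfg["input"]["stopwords"] else StopList()
        )
        preprocess_records(records, stoplist, segmenter=pre["segmenter"],
                           max_unit=pre["max_unit"])
        out = run_dir / "tokens.jsonl"
        with out.open("w", encoding="utf-8") as fh:
            for rec in records:
                fh.write(json.dumps(
                    {"record_id": rec.record_id, "date": rec.date,
                     "channel": rec.channel, "tokens": rec.tokens},
                    ensure_ascii=False) + "\n")
        register("preprocess", {"tokens.jsonl": out}, {
            "rows_read": summary.rows_read,
            "rows_dropped": summary.rows_dropped,
            "dates_sentineled": summary.dates_sentineled,
            "records_out": len(records),
        })
        return records

    records = run_stage("preprocess", _preprocess)

    # -- sentiment ----------------------------------------------------------
    def _sentiment():
        lexicon = load_lexicon(cfg["input"]["lexicon"])
        results = [score_document(r.tokens, lexicon, doc_id=r.record_id)
                   for r in records]
        out = run_dir / "scores.csv"
        pd.DataFrame(
            {"record_id": [r.doc_id for r in results],
             "score": [r.score for r in results],
             "polarity": [r.polarity for r in results]}
        ).to_csv(out, index=False)
        register("sentiment", {"scores.csv": out},
                 {"docs_scored": len(results), "lexicon_size": len(lexicon)})
        return results

    results = run_stage("sentiment", _sentiment)

    # -- vectorize ----------------------------------------------------------
    def _vectorize():
        vec = cfg["vectorize"]
        features, dtm = default_feature_pipeline(
            [r.tokens for r in records],
            doc_ids=[r.record_id for r in records],
            weighting=vec["weighting"],
            pca_vocab_threshold=vec["pca_vocab_threshold"],
        )
        out = run_dir / "matrix.csv"
        frame = pd.DataFrame(features)
        frame.insert(0, "record_id", [r.record_id for r in records])
        frame.to_csv(out, index=False)
        register("vectorize", {"matrix.csv": out},
                 {"n_docs": features.shape[0], "n_features": features.shape[1],
                  "vocabulary": len(dtm.vocabulary)})
        return features

    features = run_stage("vectorize", _vectorize)

    # -- cluster ------------------------------------------------------------
    def _cluster():
        clu = cfg["clustering"]
        d = pairwise_distances(features, metric=clu["metric"])
        if clu["fixed_k"] is not None or clu["fixed_eps"] is not None:
            solution = solve_fixed(d, k=clu["fixed_k"], eps=clu["fixed_eps"])
        else:
            solution = select_parameters(
                d, k_range=clu["k_range"],
                stability_window=clu["stability_window"],
            )
        labels_out = run_dir / "labels.csv"
        pd.DataFrame({"record_id": [r.record_id for r in records],
                      "cluster": solution.labels}).to_csv(labels_out, index=False)
        trace_out = run_dir / "trace.csv"
        pd.DataFrame([{"k": t.k, "eps": t.eps, "pmin": t.pmin,
                       "n_clusters": t.n_clusters}
                      for t in solution.trace]).to_csv(trace_out, index=False)
        params_out = run_dir / "params.json"
        params_out.write_text(json.dumps(
            {"k": solution.k, "eps": solution.eps, "pmin": solution.pmin,
             "n_clusters": solution.n_clusters}, indent=2))
        register("cluster",
                 {"labels.csv": labels_out, "trace.csv": trace_out,
                  "params.json": params_out},
                 {"n_clusters": solution.n_clusters,
                  "noise": int((solution.labels == -1).sum()),
                  "k": solution.k})
        return solution

    solution = run_stage("cluster", _cluster)

    # -- report -------------------------------------------------------------
    def _report():
        rep = cfg["report"]
        docs = [r.tokens for r in records]
        summaries = cluster_keywords(docs, solution.labels, top_n=rep["top_n"])
        period = negative_report(results, solution.labels, summaries,
                                 period=rep["period"], aggregate=rep["aggregate"])
        report_out = run_dir / "report.json"
        payload = period.to_dict()
        payload["most_negative_cluster"] = most_negative_cluster(
            results, solution.labels)
        report_out.write_text(
            json.dumps(payload, indent=2, ensure_ascii=False))
        kw_out = run_dir / "keywords.csv"
        rows = [
            {"cluster": s.cluster_id, "rank": rank + 1, "term": term,
             "salience": sal}
            for s in summaries for rank, (term, sal) in enumerate(s.keywords)
        ]
        pd.DataFrame(rows, columns=["cluster", "rank", "term", "salience"]
                     ).to_csv(kw_out, index=False)
        register("report", {"report.json": report_out, "keywords.csv": kw_out},
                 {"clusters_summarized": len(summaries)})
        return period

    run_stage("report", _report)

    # -- indicators ---------------------------------------------------------
    def _indicators():
        proportions, counts = polarity_distribution(results)
        rows = [{"indicator": f"polarity_{k}", "value": v}
                for k, v in proportions.items()]
        sat_col = cfg["preprocess"]["satisfaction_col"]
        if sat_col:
            levels = [str(r.extra.get(sat_col, "")).strip()
                      for r in records if r.extra.get(sat_col)]
            if levels:
                table = tabulate_satisfaction(levels)
                combined, percent = overall_satisfaction(table)
                rows.append({"indicator": "overall_satisfaction_combined",
                             "value": combined})
                rows.append({"indicator": "overall_satisfaction_percent",
                             "value": percent})
        out = run_dir / "indicators.csv"
        pd.DataFrame(rows).to_csv(out, index=False)
        register("indicators", {"indicators.csv": out},
                 {"indicators": len(rows)})

    run_stage("indicators", _indicators)

    manifest_path = run_dir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, ensure_ascii=False))
    return manifest
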