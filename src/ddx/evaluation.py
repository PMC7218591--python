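"""Accuracy-analysis battery for differential-diagnosis predictions.

Compares one or more prediction sources (the model, simulated or real
raters) against gold-standard vignettes, overall and per specificity
stratum:

* **top-3 accuracy** — fraction of vignettes whose gold primary diagnosis
  appears anywhere in the predicted differential;
* **per-disease precision / recall** on the primary diagnosis, with
  frequency-weighted aggregates (weights are each disease's gold-primary
  frequency);
* **Jaccard similarity** on the unordered diagnosis sets of the two
  differentials (rank- and surety-blind);
* **cosine similarity** on surety-weighted vectors over the disease
  universe (confidence-aware);
* **upper-tailed Welch t tests** on per-vignette scores, model versus the
  pooled non-model sources.

Per-stratum statistics use the stratum's vignettes only; "overall" is the
full set, not an average of strata.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ddx.errors import CoverageError
from ddx.inference import Differential
from ddx.vignettes import STRATA, VignetteSet

#: Policies for per-disease precision values that are undefined (0/0: the
#: disease occurs in gold but was never predicted as primary).
UNDEFINED_POLICIES = ("zero", "exclude")


@dataclass(frozen=True)
class PredictionRecord:
    """One source's differential for one vignette."""

    vignette_id: str
    source: str
    differential: Differential


@dataclass(frozen=True)
class MetricReport:
    """All metrics for one (source, stratum) cell; ``stratum`` may be ``overall``."""

    source: str
    stratum: str
    n_vignettes: int
    top3_accuracy: float
    precision_aggregate: float
    recall_aggregate: float
    jaccard_mean: float
    cosine_mean: float
    per_disease: pd.DataFrame = field(repr=False, compare=False)


@dataclass(frozen=True)
class ComparisonResult:
    """Upper-tailed Welch t test of source_a's per-vignette scores over source_b's."""

    metric: str
    source_a: str
    source_b: str
    statistic: float
    p_value: float
    n_a: int
    n_b: int
    degenerate: bool = False


# ---------------------------------------------------------------------------
# prediction bookkeeping
# ---------------------------------------------------------------------------


def _index_predictions(
    predictions: Sequence[PredictionRecord], gold: VignetteSet
) -> dict[str, PredictionRecord]:
    gold_ids = set(v.id for v in gold)
    by_id: dict[str, PredictionRecord] = {}
    for p in predictions:
        if p.vignette_id not in gold_ids:
            raise CoverageError(f"prediction for unknown vignette id {p.vignette_id!r}")
        if p.vignette_id in by_id:
            raise CoverageError(f"duplicate prediction for vignette {p.vignette_id!r}")
        by_id[p.vignette_id] = p
    return by_id


# ---------------------------------------------------------------------------
# primary-diagnosis metrics
# ---------------------------------------------------------------------------


def top_k_accuracy(
    predictions: Sequence[PredictionRecord], gold: VignetteSet, k: int = 3
) -> float:
    """Fraction of predicted vignettes whose gold primary is in the top ``k`` items."""
    if k < 1:
        raise ValueError("k must be >= 1")
    by_id = _index_predictions(predictions, gold)
    if not by_id:
        raise ValueError("no predictions to score")
    gold_by_id = gold.by_id()
    hits = 0
    for vid, pred in by_id.items():
        top = pred.differential.disease_ids[:k]
        if gold_by_id[vid].gold.primary in top:
            hits += 1
    return hits / len(by_id)


def per_disease_precision_recall(
    predictions: Sequence[PredictionRecord], gold: VignetteSet
) -> pd.DataFrame:
    """Confusion counts on the primary diagnosis, one row per disease.

    TP: predicted primary = gold primary = d.  FP: predicted primary d, gold
    primary differs.  FN: gold primary d, predicted primary differs.  A
    disease that is never a gold primary and never a predicted primary is
    excluded (both ratios vacuous).  Undefined ratios (0/0) are NaN in the
    table; aggregation decides how to weight them.
    """
    by_id = _index_predictions(predictions, gold)
    gold_by_id = gold.by_id()
    pairs = [
        (gold_by_id[vid].gold.primary, pred.differential.primary)
        for vid, pred in by_id.items()
    ]
    diseases = sorted({g for g, _ in pairs} | {p for _, p in pairs})
    rows = []
    for d in diseases:
        tp = sum(1 for g, p in pairs if g == d and p == d)
        fp = sum(1 for g, p in pairs if g != d and p == d)
        fn = sum(1 for g, p in pairs if g == d and p != d)
        gold_count = tp + fn
        predicted_count = tp + fp
        rows.append(
            {
                "disease_id": d,
                "precision": tp / predicted_count if predicted_count else math.nan,
                "recall": tp / gold_count if gold_count else math.nan,
                "gold_count": gold_count,
                "predicted_count": predicted_count,
                "tp": tp,
            }
        )
    return pd.DataFrame(
        rows, columns=["disease_id", "precision", "recall", "gold_count", "predicted_count", "tp"]
    )


def _aggregate(table: pd.DataFrame, column: str, undefined_policy: str) -> float:
    if undefined_policy not in UNDEFINED_POLICIES:
        raise ValueError(f"undefined_policy must be one of {UNDEFINED_POLICIES}")
    weighted = table[table["gold_count"] > 0]
    if weighted.empty:
        raise ValueError("empty gold set: no diseases carry weight")
    values = weighted[column].to_numpy(dtype=float)
    weights = weighted["gold_count"].to_numpy(dtype=float)
    defined = ~np.isnan(values)
    if undefined_policy == "zero":
        values = np.where(defined, values, 0.0)
    else:  # exclude-and-renormalize
        values, weights = values[defined], weights[defined]
        if len(values) == 0:
            raise ValueError(f"all {column} values undefined; nothing to aggregate")
    return float(np.average(values, weights=weights))


def aggregate_precision(
    table: pd.DataFrame, undefined_policy: str = "zero"
) -> float:
    """Gold-frequency-weighted mean precision over diseases.

    Weights are each disease's gold-primary count.  With the default
    ``zero`` policy an undefined precision (disease never predicted as
    primary) contributes 0 at full weight — conservative, penalizes
    never-predicting; ``exclude`` drops undefined rows and renormalizes.
    """
    return _aggregate(table, "precision", undefined_policy)


def aggregate_recall(table: pd.DataFrame, undefined_policy: str = "zero") -> float:
    """Gold-frequency-weighted mean recall over diseases (cf. aggregate_precision)."""
    return _aggregate(table, "recall", undefined_policy)


# ---------------------------------------------------------------------------
# set / vector similarity of whole differentials
# ---------------------------------------------------------------------------


def jaccard_similarity(pred: Differential, gold: Differential) -> float:
    """Intersection-over-union of the two unordered diagnosis sets."""
    a, b = set(pred.disease_ids), set(gold.disease_ids)
    if not a or not b:
        raise ValueError("differentials must be non-empty")
    return len(a & b) / len(a | b)


def cosine_similarity(
    pred: Differential, gold: Differential, disease_universe: Sequence[str]
) -> float:
    """Cosine of the surety-weighted vectors over the disease universe.

    Coordinates are the percentage sureties (zero for diseases outside the
    differential); bounded in [0, 1] because coordinates are non-negative.
    """
    universe = list(disease_universe)
    missing = (set(pred.disease_ids) | set(gold.disease_ids)) - set(universe)
    if missing:
        raise ValueError(f"differential diseases missing from universe: {sorted(missing)}")
    u = np.zeros(len(universe))
    v = np.zeros(len(universe))
    idx = {d: i for i, d in enumerate(universe)}
    for d, s in pred.items:
        u[idx[d]] = s
    for d, s in gold.items:
        v[idx[d]] = s
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        raise ValueError("zero surety vector")
    return float(np.dot(u, v) / (nu * nv))


def jaccard_mean(predictions: Sequence[PredictionRecord], gold: VignetteSet) -> float:
    """Study-level mean of per-vignette Jaccard similarity to the gold differential."""
    by_id = _index_predictions(predictions, gold)
    gold_by_id = gold.by_id()
    return float(
        np.mean([jaccard_similarity(p.differential, gold_by_id[vid].gold) for vid, p in by_id.items()])
    )


def cosine_mean(
    predictions: Sequence[PredictionRecord],
    gold: VignetteSet,
    disease_universe: Sequence[str],
) -> float:
    """Study-level mean of per-vignette cosine similarity to the gold differential."""
    by_id = _index_predictions(predictions, gold)
    gold_by_id = gold.by_id()
    return float(
        np.mean(
            [
                cosine_similarity(p.differential, gold_by_id[vid].gold, disease_universe)
                for vid, p in by_id.items()
            ]
        )
    )


# ---------------------------------------------------------------------------
# significance testing
# ---------------------------------------------------------------------------


def upper_tailed_t_test(
    scores_a: Sequence[float],
    scores_b: Sequence[float],
    metric: str = "",
    source_a: str = "a",
    source_b: str = "b",
) -> ComparisonResult:
    """Welch two-sample t test of mean(a) > mean(b), upper-tail p value.

    Uses the unequal-variance (Welch) statistic with Welch-Satterthwaite
    degrees of freedom.  Degenerate inputs — both variances zero — return
    p = 0.5 for equal means (symmetric null convention) or a saturated
    0/1 otherwise, flagged via ``degenerate``.
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample needs at least 2 observations")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0.0 and vb == 0.0:
        diff = a.mean() - b.mean()
        if diff == 0.0:
            t, p = 0.0, 0.5
        else:
            t = math.inf if diff > 0 else -math.inf
            p = 0.0 if diff > 0 else 1.0
        return ComparisonResult(metric, source_a, source_b, t, p, len(a), len(b), degenerate=True)
    res = stats.ttest_ind(a, b, equal_var=False, alternative="greater")
    return ComparisonResult(
        metric, source_a, source_b, float(res.statistic), float(res.pvalue), len(a), len(b)
    )


# ---------------------------------------------------------------------------
# full study evaluation
# ---------------------------------------------------------------------------


def _per_vignette_scores(
    predictions: Sequence[PredictionRecord],
    gold: VignetteSet,
    disease_universe: Sequence[str],
    k: int,
) -> pd.DataFrame:
    by_id = _index_predictions(predictions, gold)
    rows = []
    for v in gold:  # gold order, so the battery is ordering-invariant by construction
        if v.id not in by_id:
            continue
        pred = by_id[v.id]
        rows.append(
            {
                "vignette_id": v.id,
                "stratum": v.stratum,
                "top3_hit": float(v.gold.primary in pred.differential.disease_ids[:k]),
                "jaccard": jaccard_similarity(pred.differential, v.gold),
                "cosine": cosine_similarity(pred.differential, v.gold, disease_universe),
            }
        )
    return pd.DataFrame(rows)


def _report_for(
    source: str,
    stratum: str,
    predictions: Sequence[PredictionRecord],
    gold: VignetteSet,
    scores: pd.DataFrame,
    k: int,
    undefined_policy: str,
) -> MetricReport:
    table = per_disease_precision_recall(predictions, gold)
    return MetricReport(
        source=source,
        stratum=stratum,
        n_vignettes=len(gold),
        top3_accuracy=top_k_accuracy(predictions, gold, k=k),
        precision_aggregate=aggregate_precision(table, undefined_policy),
        recall_aggregate=aggregate_recall(table, undefined_policy),
        jaccard_mean=float(scores["jaccard"].mean()),
        cosine_mean=float(scores["cosine"].mean()),
        per_disease=table,
    )


def evaluate_study(
    gold: VignetteSet,
    predictions_by_source: Mapping[str, Sequence[PredictionRecord]],
    disease_universe: Sequence[str] | None = None,
    model_source: str = "model",
    k: int = 3,
    undefined_policy: str = "zero",
) -> tuple[list[MetricReport], list[ComparisonResult]]:
    """Full stratified comparison of every source against the gold standard.

    Every source must cover every vignette (gaps are collected per source
    and raised as one :class:`CoverageError`).  Returns a
    :class:`MetricReport` per source per stratum plus ``overall``, and — when
    any non-model source exists — an upper-tailed Welch t test per
    per-vignette metric (top-3 hit indicator, Jaccard, cosine) of the model
    against the pooled non-model sources.

    ``disease_universe`` defaults to every disease mentioned in any gold or
    predicted differential.
    """
    gold_ids = {v.id for v in gold}
    missing_by_source = {}
    for source, preds in predictions_by_source.items():
        missing = sorted(gold_ids - {p.vignette_id for p in preds})
        if missing:
            missing_by_source[source] = missing
    if missing_by_source:
        parts = "; ".join(f"{s}: {m}" for s, m in sorted(missing_by_source.items()))
        raise CoverageError(f"prediction coverage gaps ({parts})", missing_by_source)

    if disease_universe is None:
        universe: set[str] = set()
        for v in gold:
            universe.update(v.gold.disease_ids)
        for preds in predictions_by_source.values():
            for p in preds:
                universe.update(p.differential.disease_ids)
        disease_universe = sorted(universe)

    strata_sets = {"overall": gold}
    from ddx.vignettes import stratify

    for stratum, vs in stratify(gold).items():
        if len(vs):
            strata_sets[stratum] = vs

    reports: list[MetricReport] = []
    scores_by_source: dict[str, pd.DataFrame] = {}
    for source in sorted(predictions_by_source):
        preds = list(predictions_by_source[source])
        scores = _per_vignette_scores(preds, gold, disease_universe, k)
        scores_by_source[source] = scores
        by_id = {p.vignette_id: p for p in preds}
        for stratum, vs in strata_sets.items():
            sub_preds = [by_id[v.id] for v in vs]
            sub_scores = scores[scores["vignette_id"].isin({v.id for v in vs})]
            reports.append(
                _report_for(source, stratum, sub_preds, vs, sub_scores, k, undefined_policy)
            )

    comparisons: list[ComparisonResult] = []
    rater_sources = [s for s in sorted(predictions_by_source) if s != model_source]
    if model_source in predictions_by_source and rater_sources:
        pooled = pd.concat([scores_by_source[s] for s in rater_sources], ignore_index=True)
        model_scores = scores_by_source[model_source]
        for metric, col in (
            ("top3_accuracy", "top3_hit"),
            ("jaccard", "jaccard"),
            ("cosine", "cosine"),
        ):
            comparisons.append(
                upper_tailed_t_test(
                    model_scores[col].to_numpy(),
                    pooled[col].to_numpy(),
                    metric=metric,
                    source_a=model_source,
                    source_b="pooled-raters",
                )
            )
    return reports, comparisons


# ---------------------------------------------------------------------------
# prediction / report IO
# ---------------------------------------------------------------------------


def read_predictions(path: str | os.PathLike) -> list[PredictionRecord]:
    """Read PredictionRecord JSON lines."""
    out = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                doc = json.loads(line)
                out.append(
                    PredictionRecord(
                        vignette_id=doc["vignette_id"],
                        source=doc["source"],
                        differential=Differential.from_json_dict(doc["differential"]),
                    )
                )
            except (json.JSONDecodeError, KeyError, ValueError) as exc:
                raise ValueError(f"{path}:{lineno}: invalid prediction record: {exc}") from exc
    return out


def write_predictions(records: Iterable[PredictionRecord], path: str | os.PathLike) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        for rec in records:
            doc = {
                "vignette_id": rec.vignette_id,
                "source": rec.source,
                "differential": rec.differential.to_json_dict(),
            }
            fh.write(json.dumps(doc, separators=(", ", ": ")))
            fh.write("\n")


_METRIC_COLUMNS = (
    "top3_accuracy",
    "precision_aggregate",
    "recall_aggregate",
    "jaccard_mean",
    "cosine_mean",
)


def report_to_json_dict(
    reports: Sequence[MetricReport], comparisons: Sequence[ComparisonResult]
) -> dict:
    return {
        "reports": [
            {
                "source": r.source,
                "stratum": r.stratum,
                "n_vignettes": r.n_vignettes,
                **{m: getattr(r, m) for m in _METRIC_COLUMNS},
                "per_disease": r.per_disease.where(r.per_disease.notna(), None).to_dict(
                    orient="records"
                ),
            }
            for r in reports
        ],
        "comparisons": [
            {
                "metric": c.metric,
                "source_a": c.source_a,
                "source_b": c.source_b,
                "statistic": c.statistic,
                "p_value": c.p_value,
                "n_a": c.n_a,
                "n_b": c.n_b,
                "degenerate": c.degenerate,
            }
            for c in comparisons
        ],
    }


def write_report_json(
    reports: Sequence[MetricReport],
    comparisons: Sequence[ComparisonResult],
    path: str | os.PathLike,
) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(report_to_json_dict(reports, comparisons), fh, indent=2)
        fh.write("\n")


def write_report_tsv(
    reports: Sequence[MetricReport],
    comparisons: Sequence[ComparisonResult],
    path: str | os.PathLike,
) -> None:
    """Human-readable long-format table: one row per (source, stratum, metric)."""
    rows = []
    for r in reports:
        for m in _METRIC_COLUMNS:
            rows.append(
                {"source": r.source, "stratum": r.stratum, "metric": m, "value": getattr(r, m)}
            )
    for c in comparisons:
        rows.append(
            {
                "source": f"{c.source_a} vs {c.source_b}",
                "stratum": "overall",
                "metric": f"t_test[{c.metric}].p_value",
                "value": c.p_value,
            }
        )
    df = pd.DataFrame(rows, columns=["source", "stratum", "metric", "value"])
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False, float_format="%.6f")
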