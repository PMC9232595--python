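"""Evaluation designs: test-set regression, virtual screening, multi-threshold
crystal-set scoring, per-peptide consistency, and the position-ablation run.

Reported correlations are absolute values (the protocol scores rank quality,
not sign); signed values are retained alongside. Aggregation across alleles
is an unweighted mean over the alleles where a metric is defined.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .affinity import STANDARD_THRESHOLDS_NM, label_at_threshold
from .featurize import FeatureDataset
from .metrics import auprc, auroc, normalize_scores, pearson, spearman
from .models import AlleleModel, SplitSpec, stratified_split, train_all

logger = logging.getLogger(__name__)

METRIC_NAMES = ("pearson_r", "spearman_rho", "auroc", "auprc")


@dataclass
class MetricReport:
    """Per-allele metric table plus its unweighted cross-allele mean."""

    per_allele: dict[str, dict[str, float]]
    signed: dict[str, dict[str, float]] = field(default_factory=dict)

    @property
    def aggregate(self) -> dict[str, float]:
        out = {}
        for name in METRIC_NAMES:
            vals = [m[name] for m in self.per_allele.values()
                    if name in m and np.isfinite(m[name])]
            out[name] = float(np.mean(vals)) if vals else float("nan")
        return out

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.per_allele).T
        df.loc["aggregate"] = pd.Series(self.aggregate)
        return df


def predict_dataset(
    models: dict[str, AlleleModel], data: FeatureDataset, reduce_long: bool = False
) -> np.ndarray:
    """Score every record with its allele's model.

    ``reduce_long`` opts 10-position records into the documented 10-mer
    reduction (drop position 6) before scoring.
    """
    scores = np.full(len(data), np.nan)
    for allele in data.unique_alleles():
        if allele not in models:
            raise KeyError(f"no model for allele {allele}")
        idx = data.allele_indices(allele)
        scores[idx] = models[allele].predict(data.subset(idx), reduce_long=reduce_long)
    return scores


def evaluate_models(
    models: dict[str, AlleleModel],
    test: FeatureDataset,
    binder_threshold_nM: float = 500.0,
    train_ids: set[str] | None = None,
) -> MetricReport:
    """Per-allele regression/classification metrics on a held-out set.

    When ``train_ids`` is given, any complex id shared with the test set is an
    error (leakage guard). Metrics undefined for an allele (constant targets,
    single label class) are reported as NaN and excluded from the aggregate.
    """
    if train_ids is not None:
        overlap = train_ids & set(test.ids)
        if overlap:
            raise ValueError(f"test overlaps training: {sorted(overlap)[:5]}")
    per_allele: dict[str, dict[str, float]] = {}
    signed: dict[str, dict[str, float]] = {}
    for allele in test.unique_alleles():
        idx = test.allele_indices(allele)
        sub = test.subset(idx)
        pred = models[allele].predict(sub) if allele in models else None
        if pred is None:
            raise KeyError(f"no model for allele {allele}")
        r = pearson(pred, sub.scaled)
        rho = spearman(pred, sub.scaled)
        entry = {"pearson_r": abs(r), "spearman_rho": abs(rho)}
        labels = label_at_threshold(sub.ic50_nM, binder_threshold_nM)
        try:
            entry["auroc"] = auroc(pred, labels)
            entry["auprc"] = auprc(pred, labels)
        except ValueError:
            entry["auroc"] = entry["auprc"] = float("nan")
        per_allele[allele] = entry
        signed[allele] = {"pearson_r": r, "spearman_rho": rho}
    return MetricReport(per_allele=per_allele, signed=signed)


@dataclass
class ScreeningResult:
    """Virtual-screening outcome: per-entry scores and ranking metrics."""

    entries: pd.DataFrame                    # complex_id, allele, score, is_binder
    per_allele: dict[str, dict[str, float]]
    pooled: dict[str, float]


def screening_eval(
    models: dict[str, AlleleModel], benchmark: FeatureDataset
) -> ScreeningResult:
    """Rank a binder+decoy benchmark with the per-allele models.

    Pooled AUROC/AUPRC are computed over all entries; per-allele metrics skip
    (with a warning) alleles lacking a positive or a negative.
    """
    if benchmark.is_binder is None:
        raise ValueError("benchmark must carry binder/decoy labels")
    scores = predict_dataset(models, benchmark)
    labels = benchmark.is_binder.astype(int)
    entries = pd.DataFrame({
        "complex_id": benchmark.ids,
        "allele": benchmark.alleles,
        "score": scores,
        "is_binder": labels,
    })
    per_allele: dict[str, dict[str, float]] = {}
    for allele in benchmark.unique_alleles():
        idx = benchmark.allele_indices(allele)
        if labels[idx].min() == labels[idx].max():
            warnings.warn(f"allele {allele}: single class, skipped", stacklevel=2)
            continue
        per_allele[allele] = {
            "auroc": auroc(scores[idx], labels[idx]),
            "auprc": auprc(scores[idx], labels[idx]),
        }
    pooled = {"auroc": auroc(scores, labels), "auprc": auprc(scores, labels)}
    # Cross-allele unweighted means, alongside the pooled values.
    for name in ("auroc", "auprc"):
        vals = [m[name] for m in per_allele.values()]
        pooled[f"mean_{name}"] = float(np.mean(vals)) if vals else float("nan")
    return ScreeningResult(entries=entries, per_allele=per_allele, pooled=pooled)


def threshold_eval(
    scores, ic50s, thresholds=STANDARD_THRESHOLDS_NM
) -> dict[float, dict[str, float]]:
    """AUROC/AUPRC at each binder-definition threshold (nM).

    A threshold under which all entries fall in one class reports NaN cells.
    """
    scores = np.asarray(scores, dtype=float)
    ic50s = np.asarray(ic50s, dtype=float)
    if np.any(~np.isfinite(ic50s)):
        raise ValueError("IC50 required for every entry")
    out: dict[float, dict[str, float]] = {}
    for thr in thresholds:
        labels = label_at_threshold(ic50s, thr)
        try:
            out[thr] = {"auroc": auroc(scores, labels), "auprc": auprc(scores, labels)}
        except ValueError:
            out[thr] = {"auroc": float("nan"), "auprc": float("nan")}
    return out


def consistency_ranges(scores, peptides) -> pd.DataFrame:
    """Per-peptide (min, max, range) of scores across alternative structures.

    A smaller range means the scorer is more consistent across different
    structures of the same complex.
    """
    df = pd.DataFrame({"peptide": list(peptides), "score": np.asarray(scores, float)})
    g = df.groupby("peptide", sort=False)["score"]
    out = g.agg(["min", "max"])
    out["range"] = out["max"] - out["min"]
    return out


def baseline_report(
    test: FeatureDataset, binder_threshold_nM: float = 500.0
) -> MetricReport:
    """Metrics of the untrained baseline: the weighted total-energy score.

    Totals are lower-is-stronger, so scores are inverted via min-max
    normalization per allele before computing the same four metrics the
    trained models report.
    """
    per_allele: dict[str, dict[str, float]] = {}
    signed: dict[str, dict[str, float]] = {}
    for allele in test.unique_alleles():
        sub = test.subset(test.allele_indices(allele))
        scores = normalize_scores(sub.baseline_scores(), lower_is_stronger=True)
        r, rho = pearson(scores, sub.scaled), spearman(scores, sub.scaled)
        entry = {"pearson_r": abs(r), "spearman_rho": abs(rho)}
        labels = label_at_threshold(sub.ic50_nM, binder_threshold_nM)
        try:
            entry["auroc"] = auroc(scores, labels)
            entry["auprc"] = auprc(scores, labels)
        except ValueError:
            entry["auroc"] = entry["auprc"] = float("nan")
        per_allele[allele] = entry
        signed[allele] = {"pearson_r": r, "spearman_rho": rho}
    return MetricReport(per_allele=per_allele, signed=signed)


def protocol_comparison(
    data: FeatureDataset,
    split: SplitSpec = SplitSpec(),
    hyperparameters: dict | None = None,
    regressor_kind: str = "random_forest",
    seed: int = 0,
) -> dict[str, MetricReport]:
    """Head-to-head comparison of the three scoring routes on one split.

    Trains per-allele models under the per-position and the standard
    (aggregated) featurization on an identical train/test split and scores
    the untrained total-energy baseline on the same test set. Returns
    ``{"per_position": ..., "standard": ..., "baseline": ...}`` reports; any
    gap between the first two isolates the effect of keeping positions
    separate.
    """
    train, test = stratified_split(data, split)
    train_ids = set(train.ids)
    out: dict[str, MetricReport] = {}
    for feat in ("per_position", "standard"):
        models = train_all(
            train, featurization=feat, regressor_kind=regressor_kind,
            hyperparameters=hyperparameters, seed=seed,
        )
        out[feat] = evaluate_models(
            models, test, binder_threshold_nM=split.binder_threshold_nM,
            train_ids=train_ids,
        )
    out["baseline"] = baseline_report(test, split.binder_threshold_nM)
    return out


def ablation_run(
    data: FeatureDataset,
    subsets=("all", "anchor", "middle"),
    split: SplitSpec = SplitSpec(),
    hyperparameters: dict | None = None,
    seed: int = 0,
) -> dict[str, MetricReport]:
    """Train and evaluate per-position models under each position subset.

    The train/test split and all seeds are shared across subsets, so reports
    differ only by which peptide positions the models may see.
    """
    train, test = stratified_split(data, split)
    train_ids = set(train.ids)
    reports: dict[str, MetricReport] = {}
    for name in subsets:
        models = train_all(
            train, featurization="per_position", positions=name,
            hyperparameters=hyperparameters, seed=seed,
        )
        reports[name] = evaluate_models(
            models, test, binder_threshold_nM=split.binder_threshold_nM,
            train_ids=train_ids,
        )
    return reports
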