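"""Regression and classification metrics, plus score normalization.

Correlations come from scipy, AUROC/AUPRC from scikit-learn; the wrappers
pin down the edge cases the evaluation designs rely on (constant inputs are
reported as missing, not zero; AUROC is the Mann-Whitney probability with
ties counted half; AUPRC is step-wise average precision, not a trapezoidal
interpolation).
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import stats
from sklearn.metrics import average_precision_score, roc_auc_score


def _pair(x, y):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("length mismatch")
    if x.size < 3:
        raise ValueError("need at least 3 points")
    return x, y


def pearson(x, y) -> float:
    """Product-moment correlation; NaN (missing) for constant input."""
    x, y = _pair(x, y)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan")
    return float(stats.pearsonr(x, y).statistic)


def spearman(x, y) -> float:
    """Rank correlation with average ranks for ties; NaN for constant input."""
    x, y = _pair(x, y)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan")
    return float(stats.spearmanr(x, y).statistic)


def auroc(scores, labels) -> float:
    """Mann-Whitney AUROC: P(score+ > score-) + 0.5 P(tie)."""
    labels = np.asarray(labels, dtype=int)
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes required")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


def auprc(scores, labels) -> float:
    """Average precision over descending score thresholds (ties = one step)."""
    labels = np.asarray(labels, dtype=int)
    if labels.sum() == 0:
        raise ValueError("at least one positive required")
    return float(average_precision_score(labels, np.asarray(scores, dtype=float)))


def normalize_scores(scores, lower_is_stronger: bool) -> np.ndarray:
    """Min-max scale to [0, 1], inverted so 1 is always the strongest binder.

    Raw structural energies are lower-is-stronger; model outputs are already
    higher-is-stronger. Constant input maps to all 0.5 with a warning.
    """
    s = np.asarray(scores, dtype=float)
    span = np.ptp(s)
    if span == 0:
        warnings.warn("constant scores: normalizing to 0.5", stacklevel=2)
        return np.full_like(s, 0.5)
    out = (s - s.min()) / span
    return 1.0 - out if lower_is_stronger else out


def max_normalize_scores(scores, lower_is_stronger: bool) -> np.ndarray:
    """Plain x/max variant (kept as an option; min-max is the default)."""
    s = np.asarray(scores, dtype=float)
    m = np.abs(s).max()
    if m == 0:
        warnings.warn("all-zero scores: normalizing to 0.5", stacklevel=2)
        return np.full_like(s, 0.5)
    out = s / m
    return 1.0 - out if lower_is_stronger else out
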