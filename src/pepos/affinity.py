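"""Affinity scaling and threshold labels.

Experimental binding affinities arrive as IC50 in nM (lower = stronger). The
regression target is the conventional log-scaled value

    s = 1 - log(IC50) / log(50000),  clamped to [0, 1],

so 1 nM maps to 1, 50 uM (the usual non-binder ceiling) maps to 0, and the
transform is strictly decreasing in between. The log base cancels in the
ratio. Classification labels are derived at the standard thresholds: 50 nM
(strong binders), 500 nM (strong + medium), 25 000 nM (any binder).
"""

from __future__ import annotations

import warnings

import numpy as np

IC50_CEILING_NM = 50_000.0

#: Canonical thresholds (nM) for strong / strong+medium / any-binder labels.
STANDARD_THRESHOLDS_NM = (50.0, 500.0, 25_000.0)

#: Closed IC50 ranges (nM) of the qualitative binder classes.
CLASS_RANGES_NM = {
    "strong": (0.0, 5.0),
    "medium": (50.0, 500.0),
    "weak": (500.0, 25_000.0),
}


def scale_affinity(ic50_nM):
    """Map IC50 (nM) to the [0, 1] regression target (vectorised).

    Raises for non-positive input; values below 1 nM or above 50 000 nM clamp
    to 1 and 0 respectively (clamping applied after the transform).
    """
    x = np.asarray(ic50_nM, dtype=float)
    if np.any(x <= 0):
        raise ValueError("IC50 must be positive (nM)")
    s = np.clip(1.0 - np.log(x) / np.log(IC50_CEILING_NM), 0.0, 1.0)
    return float(s) if np.isscalar(ic50_nM) or x.ndim == 0 else s


def unscale_affinity(scaled):
    """Inverse transform: scaled target back to IC50 in nM."""
    s = np.clip(np.asarray(scaled, dtype=float), 0.0, 1.0)
    x = IC50_CEILING_NM ** (1.0 - s)
    return float(x) if np.isscalar(scaled) or s.ndim == 0 else x


def label_at_threshold(ic50_nM, threshold_nM: float):
    """Binary binder label: positive iff IC50 <= threshold (boundary inclusive)."""
    if threshold_nM not in STANDARD_THRESHOLDS_NM:
        warnings.warn(
            f"non-standard threshold {threshold_nM} nM "
            f"(standard: {STANDARD_THRESHOLDS_NM})",
            stacklevel=2,
        )
    x = np.asarray(ic50_nM, dtype=float)
    if np.any(x <= 0):
        raise ValueError("IC50 must be positive (nM)")
    lab = x <= threshold_nM
    return bool(lab) if np.isscalar(ic50_nM) or x.ndim == 0 else lab


def binder_class(ic50_nM: float) -> str:
    """Qualitative class from IC50: strong / medium / weak / nonbinder.

    Gaps between the closed class ranges fall to the next weaker class.
    """
    if ic50_nM <= 0:
        raise ValueError("IC50 must be positive (nM)")
    if ic50_nM <= CLASS_RANGES_NM["strong"][1]:
        return "strong"
    if ic50_nM <= CLASS_RANGES_NM["medium"][1]:
        return "medium"
    if ic50_nM <= CLASS_RANGES_NM["weak"][1]:
        return "weak"
    return "nonbinder"
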