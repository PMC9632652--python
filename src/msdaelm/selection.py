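"""Minimum-redundancy maximum-relevance (mRMR) feature selection.

Greedy forward selection: the first pick maximizes mutual information (MI)
with the label; each later pick maximizes, in the difference (MID) variant,

    MI(f; y) − mean_{s in selected} MI(f; s)

or, in the quotient (MIQ) variant, the ratio of the two terms.  MI is
estimated on equal-frequency discretized features (10 bins by default),
which is the standard recipe for continuous deep features.  Ties are broken
by lowest column index, making the selection deterministic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from sklearn.metrics import mutual_info_score

from .data import LabeledFeatureSet
from .errors import ConfigurationError, InputError

__all__ = ["SelectionResult", "mrmr_select"]


@dataclass
class SelectionResult:
    """Ordered selected indices with the per-step criterion values."""

    selected_indices: list[int]
    scores: list[float]
    fraction: float

    def apply(self, fs: LabeledFeatureSet) -> LabeledFeatureSet:
        """Reduced copy of a feature set (columns in selection order)."""
        idx = self.selected_indices
        return LabeledFeatureSet(
            fs.features[:, idx],
            fs.labels,
            domain_id=fs.domain_id,
            feature_names=[fs.feature_names[i] for i in idx],
        )


def discretize_equal_frequency(x: np.ndarray, n_bins: int = 10) -> np.ndarray:
    """Equal-frequency binning of one feature column.

    Constant columns collapse to a single bin (MI 0 against anything).
    """
    edges = np.unique(np.quantile(x, np.linspace(0, 1, n_bins + 1)[1:-1]))
    return np.searchsorted(edges, x, side="right")


def mrmr_select(
    features: LabeledFeatureSet,
    fraction: float = 0.10,
    variant: str = "MID",
    n_bins: int = 10,
) -> SelectionResult:
    """Select the top ``ceil(fraction × n_features)`` features by greedy mRMR.

    Returns the selection order and the criterion value at each step (the
    first score is the raw relevance of the top feature).
    """
    if features.labels is None:
        raise InputError("mrmr_select requires labels")
    if not 0.0 < fraction <= 1.0:
        raise ConfigurationError(f"fraction must be in (0, 1], got {fraction}")
    if variant not in ("MID", "MIQ"):
        raise ConfigurationError(f"unknown mRMR variant {variant!r}")

    X, y = features.features, features.labels
    p = X.shape[1]
    n_select = math.ceil(fraction * p)
    binned = [discretize_equal_frequency(X[:, j], n_bins) for j in range(p)]
    relevance = np.array([mutual_info_score(y, b) for b in binned])

    selected: list[int] = []
    scores: list[float] = []
    # running sum of MI(f_j; f_s) over already-selected s, per candidate j
    red_sum = np.zeros(p)
    remaining = np.ones(p, dtype=bool)
    for step in range(n_select):
        if step == 0:
            crit = relevance.copy()
        else:
            mean_red = red_sum / step
            if variant == "MID":
                crit = relevance - mean_red
            else:
                crit = relevance / np.maximum(mean_red, 1e-12)
        crit = np.where(remaining, crit, -np.inf)
        best = int(np.argmax(crit))  # argmax takes the lowest index on ties
        selected.append(best)
        scores.append(float(crit[best]))
        remaining[best] = False
        if step + 1 < n_select:
            for j in np.flatnonzero(remaining):
                red_sum[j] += mutual_info_score(binned[best], binned[j])
    return SelectionResult(selected, scores, fraction)
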