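"""Binary-classification metrics, ROC/AUC, and KDE distribution comparison.

Metric definitions (positive class = class correctly counted in TP):

    Sen = TP/(TP+FN)   Spe = TN/(TN+FP)   Acc = (TP+TN)/N
    Pre = TP/(TP+FP)   F1  = 2·Pre·Sen/(Pre+Sen)

Zero-denominator ratios are reported as 0 with ``undefined_metrics``
flagging which ones, rather than erroring (small batches routinely produce
empty cells).  AUC is the trapezoidal area under the ROC curve, equivalent
to the tie-corrected Mann–Whitney U statistic normalized by n₁·n₀.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import gaussian_kde
from sklearn.metrics import roc_curve

from .data import LabeledFeatureSet
from .errors import InputError

__all__ = ["EvaluationReport", "confusion_metrics", "roc_auc", "kde_compare",
           "group_average_scores"]


@dataclass
class EvaluationReport:
    tp: int = 0
    tn: int = 0
    fp: int = 0
    fn: int = 0
    sen: float = 0.0
    spe: float = 0.0
    acc: float = 0.0
    pre: float = 0.0
    f1: float = 0.0
    auc: float = float("nan")
    roc_points: list[tuple[float, float]] = field(default_factory=list)
    undefined_metrics: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "tp": self.tp, "tn": self.tn, "fp": self.fp, "fn": self.fn,
            "sen": self.sen, "spe": self.spe, "acc": self.acc,
            "pre": self.pre, "f1": self.f1, "auc": self.auc,
            "roc_points": [list(p) for p in self.roc_points],
            "undefined_metrics": list(self.undefined_metrics),
        }


def _ratio(num: float, den: float, name: str, flags: list[str]) -> float:
    if den == 0:
        flags.append(name)
        return 0.0
    return num / den


def confusion_metrics(
    true_labels, predicted_labels, positive_class: int = 1
) -> EvaluationReport:
    """Confusion counts and the five derived metrics for binary labels."""
    y = np.asarray(true_labels)
    p = np.asarray(predicted_labels)
    if y.shape != p.shape:
        raise InputError("label vectors must have equal length")
    labels = set(np.unique(y)) | set(np.unique(p))
    if not labels <= {0, 1} or len(set(np.unique(y))) > 2:
        raise InputError(f"binary labels in {{0,1}} required, got {sorted(labels)}")
    pos = y == positive_class
    ppos = p == positive_class
    tp = int(np.sum(pos & ppos))
    fn = int(np.sum(pos & ~ppos))
    fp = int(np.sum(~pos & ppos))
    tn = int(np.sum(~pos & ~ppos))
    flags: list[str] = []
    sen = _ratio(tp, tp + fn, "sen", flags)
    spe = _ratio(tn, tn + fp, "spe", flags)
    acc = _ratio(tp + tn, tp + tn + fp + fn, "acc", flags)
    pre = _ratio(tp, tp + fp, "pre", flags)
    f1 = _ratio(2 * pre * sen, pre + sen, "f1", flags)
    return EvaluationReport(tp=tp, tn=tn, fp=fp, fn=fn, sen=sen, spe=spe,
                            acc=acc, pre=pre, f1=f1, undefined_metrics=flags)


def roc_auc(true_labels, scores, positive_class: int = 1):
    """ROC points and trapezoidal AUC (tie handling = rank average).

    The score convention is "larger score → more positive"; evaluating with
    the opposite positive class and unchanged scores yields 1 − AUC.
    Returns ``(auc, roc_points)`` with points as (FPR, TPR) pairs.
    """
    y = np.asarray(true_labels)
    s = np.asarray(scores, dtype=float)
    if y.shape != s.shape:
        raise InputError("labels and scores must have equal length")
    if not np.all(np.isfinite(s)):
        raise InputError("scores must be finite")
    ybin = (y == positive_class).astype(int)
    if ybin.min() == ybin.max():
        raise InputError("both classes must be present to compute a ROC curve")
    fpr, tpr, _ = roc_curve(ybin, s)
    auc = float(np.trapezoid(tpr, fpr))
    return auc, list(zip(fpr.tolist(), tpr.tolist()))


def group_average_scores(scores, groups, true_labels):
    """Average per-image scores within a grouping key (e.g. patient).

    Returns ``(group_scores, group_labels)``; each group must carry one
    label.
    """
    scores = np.asarray(scores, dtype=float)
    groups = np.asarray(groups)
    y = np.asarray(true_labels)
    out_s, out_y = [], []
    for g in np.unique(groups):
        m = groups == g
        lab = np.unique(y[m])
        if len(lab) != 1:
            raise InputError(f"group {g!r} mixes labels {lab.tolist()}")
        out_s.append(float(scores[m].mean()))
        out_y.append(int(lab[0]))
    return np.array(out_s), np.array(out_y)


def kde_compare(
    features_a: LabeledFeatureSet | np.ndarray,
    features_b: LabeledFeatureSet | np.ndarray,
    projection: str | int | None = None,
    grid_size: int = 512,
):
    """Compare two feature distributions along a 1-D projection by KDE.

    ``projection`` selects a named feature (or column index); the default
    projects both sets on the first principal direction of the pooled data.
    Gaussian KDE with Silverman bandwidth on a shared grid; the scalar
    summary is the L1 distance ∫|f_a − f_b| (0 for identical samples, →2
    for disjoint supports).

    Returns ``(grid, density_a, density_b, l1_distance)``.
    """
    Xa = features_a.features if isinstance(features_a, LabeledFeatureSet) else np.atleast_2d(features_a)
    Xb = features_b.features if isinstance(features_b, LabeledFeatureSet) else np.atleast_2d(features_b)
    if Xa.shape[0] < 5 or Xb.shape[0] < 5:
        raise InputError("kde_compare requires at least 5 samples per set")
    if Xa.shape[1] != Xb.shape[1]:
        raise InputError("feature dimensions differ")

    if projection is None:
        pooled = np.vstack([Xa, Xb])
        pooled = pooled - pooled.mean(axis=0)
        _, _, vt = np.linalg.svd(pooled, full_matrices=False)
        direction = vt[0]
        a, b = Xa @ direction, Xb @ direction
    else:
        if isinstance(projection, str):
            if not isinstance(features_a, LabeledFeatureSet):
                raise InputError("named projection needs LabeledFeatureSet input")
            projection = features_a.feature_names.index(projection)
        a, b = Xa[:, projection], Xb[:, projection]

    # degenerate (zero-variance) projections: KDE undefined, compare as spikes
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        same = float(a[0]) == float(b[0])
        grid = np.array([a[0]])
        return grid, np.array([np.inf]), np.array([np.inf]), 0.0 if same else 2.0

    kde_a = gaussian_kde(a, bw_method="silverman")
    kde_b = gaussian_kde(b, bw_method="silverman")
    lo = min(a.min(), b.min())
    hi = max(a.max(), b.max())
    pad = 0.25 * (hi - lo)
    grid = np.linspace(lo - pad, hi + pad, grid_size)
    da = kde_a(grid)
    db = kde_b(grid)
    l1 = float(np.trapezoid(np.abs(da - db), grid))
    return grid, da, db, l1
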