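"""Voxel-wise detection metrics on the percent scale.

All seven metrics (specificity, accuracy, recall, precision, Dice,
Youden index, AUC) are reported multiplied by 100 to match the customary
percent presentation; the Youden index is recall + specificity - 100 on
that scale, and the single-threshold AUC is
100 * (1 - (FPR + FNR) / 2) = (specificity + recall) / 2.

Metrics with a zero denominator are explicitly undefined (``None``),
never silently 0 or 100: at voxel scale the classes are extremely
imbalanced and degenerate counts are routine.
"""

from __future__ import annotations

from dataclasses import dataclass, fields

import numpy as np
import pandas as pd

from corthick.volume_io import BinaryMask

METRIC_NAMES = (
    "specificity", "accuracy", "recall", "precision", "dice", "youden", "auc",
)


@dataclass(frozen=True)
class ConfusionCounts:
    """Voxel confusion counts of a predicted vs true lesion mask."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        for f in fields(self):
            if getattr(self, f.name) < 0:
                raise ValueError(f"{f.name} must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class MetricsReport:
    """The seven detection metrics, percent scale; None where undefined."""

    specificity: float | None
    accuracy: float | None
    recall: float | None
    precision: float | None
    dice: float | None
    youden: float | None
    auc: float | None

    def as_dict(self) -> dict[str, float | None]:
        return {name: getattr(self, name) for name in METRIC_NAMES}

    def rounded(self, ndigits: int = 2) -> dict[str, float | None]:
        return {
            k: (None if v is None else round(v, ndigits))
            for k, v in self.as_dict().items()
        }


def confusion_from_masks(
    pred: BinaryMask,
    truth: BinaryMask,
    eval_domain: BinaryMask | None = None,
) -> ConfusionCounts:
    """Tally TP/FP/FN/TN over an evaluation domain (default: whole grid).

    The choice of domain (whole image, brain mask, GM mask) drives
    specificity and accuracy under class imbalance, so it is an explicit
    parameter.
    """
    if pred.shape != truth.shape:
        raise ValueError("prediction and truth grids differ")
    if eval_domain is None:
        dom = np.ones(pred.shape, dtype=bool)
    else:
        if eval_domain.shape != pred.shape:
            raise ValueError("eval_domain grid differs")
        dom = eval_domain.mask
        if not dom.any():
            raise ValueError("eval_domain is empty")
    p = pred.mask[dom]
    t = truth.mask[dom]
    return ConfusionCounts(
        tp=int(np.count_nonzero(p & t)),
        fp=int(np.count_nonzero(p & ~t)),
        fn=int(np.count_nonzero(~p & t)),
        tn=int(np.count_nonzero(~p & ~t)),
    )


def _ratio_pct(num: int, den: int) -> float | None:
    return None if den == 0 else 100.0 * num / den


def dice_from_pr(precision_pct: float, recall_pct: float) -> float | None:
    """Dice = 2 PR / (P + R): the harmonic mean of precision and recall,
    evaluated directly on the percent scale."""
    s = precision_pct + recall_pct
    if s == 0:
        return None
    return 2.0 * precision_pct * recall_pct / s


def youden_from(recall_pct: float, specificity_pct: float) -> float:
    """Youden index = recall + specificity - 1, on the percent scale
    (hence the -100)."""
    return recall_pct + specificity_pct - 100.0


def metrics_from_counts(c: ConfusionCounts) -> MetricsReport:
    """All seven metrics from confusion counts; zero-denominator metrics
    come back as None.

    AUC uses the single-threshold form 1 - (FPR + FNR)/2, which equals
    (specificity + recall)/2 on the percent scale.
    """
    specificity = _ratio_pct(c.tn, c.tn + c.fp)
    accuracy = _ratio_pct(c.tp + c.tn, c.total)
    recall = _ratio_pct(c.tp, c.tp + c.fn)
    precision = _ratio_pct(c.tp, c.tp + c.fp)
    dice = None
    if precision is not None and recall is not None:
        dice = dice_from_pr(precision, recall)
    youden = None
    if recall is not None and specificity is not None:
        youden = youden_from(recall, specificity)
    auc = None
    if (c.fp + c.tn) > 0 and (c.fn + c.tp) > 0:
        auc = 100.0 * (1.0 - 0.5 * (c.fp / (c.fp + c.tn) + c.fn / (c.fn + c.tp)))
    return MetricsReport(
        specificity=specificity,
        accuracy=accuracy,
        recall=recall,
        precision=precision,
        dice=dice,
        youden=youden,
        auc=auc,
    )


def cohort_summary(reports: list[MetricsReport]) -> pd.DataFrame:
    """Per-metric mean and n-1 sample SD over a cohort of reports.

    Undefined metrics are excluded metric-by-metric; the returned frame has
    one row per metric with columns ``mean``, ``sd`` and ``n``.
    """
    if len(reports) < 2:
        raise ValueError("need at least 2 reports to summarize")
    rows = []
    for name in METRIC_NAMES:
        vals = np.array(
            [getattr(r, name) for r in reports if getattr(r, name) is not None],
            dtype=float,
        )
        if vals.size == 0:
            rows.append({"metric": name, "mean": np.nan, "sd": np.nan, "n": 0})
        else:
            sd = float(vals.std(ddof=1)) if vals.size > 1 else 0.0
            rows.append(
                {"metric": name, "mean": float(vals.mean()), "sd": sd, "n": vals.size}
            )
    return pd.DataFrame(rows).set_index("metric")
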