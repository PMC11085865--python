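"""Diagnostic evaluation: confusion counts, the five ratio metrics,
ROC/AUC, and gender/age subgroup reporting.

CAD is the positive class throughout.  The five metrics are

    accuracy    = (TP + TN) / N
    sensitivity = TP / (TP + FN)
    specificity = TN / (TN + FP)
    precision   = TP / (TP + FP)
    NPV         = TN / (TN + FN)

A zero denominator yields ``None`` (an explicit undefined marker), never
an exception or a silent 0, so empty subgroup rows stay visibly empty.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import roc_curve

__all__ = [
    "ConfusionCounts", "MetricReport", "SubgroupSpec", "confusion", "metrics",
    "roc_auc", "subgroup_report", "AGE_BINS", "age_bin",
]

POSITIVE = "CAD"

AGE_BINS = ("<=40", "(40,50]", "(50,60]", "(60,70]", ">70")
_AGE_EDGES = (40, 50, 60, 70)


def age_bin(age: int) -> str:
    """Age bin label; bins are closed on the right (age 40 -> '<=40')."""
    for label, edge in zip(AGE_BINS, _AGE_EDGES):
        if age <= edge:
            return label
    return AGE_BINS[-1]


@dataclass(frozen=True)
class ConfusionCounts:
    """TP/TN/FP/FN with CAD as the positive class."""

    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def n(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass(frozen=True)
class MetricReport:
    """The five diagnostic ratios; ``None`` marks an undefined metric."""

    accuracy: float | None
    sensitivity: float | None
    specificity: float | None
    precision: float | None
    npv: float | None

    def as_percent(self) -> dict[str, float | None]:
        return {
            name: (None if value is None else 100.0 * value)
            for name, value in self.__dict__.items()
        }


def confusion(predicted: Sequence[str], actual: Sequence[str]) -> ConfusionCounts:
    """Count TP/TN/FP/FN from label sequences ('CAD' / 'non-CAD')."""
    if len(predicted) != len(actual):
        raise ValueError(
            f"length mismatch: {len(predicted)} predictions vs {len(actual)} labels"
        )
    if len(actual) == 0:
        raise ValueError("cannot build a confusion matrix from zero samples")
    tp = tn = fp = fn = 0
    for p, a in zip(predicted, actual):
        if a == POSITIVE:
            if p == POSITIVE:
                tp += 1
            else:
                fn += 1
        else:
            if p == POSITIVE:
                fp += 1
            else:
                tn += 1
    return ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn)


def _ratio(num: int, den: int) -> float | None:
    return None if den == 0 else num / den


def metrics(c: ConfusionCounts) -> MetricReport:
    """The five diagnostic metrics from integer confusion counts."""
    if c.n < 1:
        raise ValueError("metrics require at least one sample")
    return MetricReport(
        accuracy=_ratio(c.tp + c.tn, c.n),
        sensitivity=_ratio(c.tp, c.tp + c.fn),
        specificity=_ratio(c.tn, c.tn + c.fp),
        precision=_ratio(c.tp, c.tp + c.fp),
        npv=_ratio(c.tn, c.tn + c.fn),
    )


def roc_auc(scores: Sequence[float], labels: Sequence[str]) -> tuple[np.ndarray, float]:
    """ROC curve points and AUC from p(CAD) scores.

    The curve sweeps the threshold over the distinct scores; the AUC is
    the trapezoidal integral, which equals the tie-corrected
    Mann-Whitney concordant-pair statistic.  Single-class inputs have no
    defined AUC and raise ``ValueError``.
    """
    y = np.asarray([1 if lab == POSITIVE else 0 for lab in labels])
    scores = np.asarray(scores, dtype=float)
    if y.min() == y.max():
        raise ValueError("AUC is undefined when only one class is present")
    fpr, tpr, _ = roc_curve(y, scores)
    auc = float(np.trapezoid(tpr, fpr))
    return np.column_stack([fpr, tpr]), auc


@dataclass(frozen=True)
class SubgroupSpec:
    """Stratification spec: gender groups and right-closed age bins."""

    genders: tuple[str, ...] = ("male", "female")
    age_bins: tuple[str, ...] = AGE_BINS


def subgroup_report(
    predicted: Sequence[str],
    actual: Sequence[str],
    metadata: pd.DataFrame,
    spec: SubgroupSpec = SubgroupSpec(),
) -> pd.DataFrame:
    """Per-gender and per-age-bin metric table.

    *metadata* must cover every sample (columns ``id``, ``gender``,
    ``age``), aligned row-by-row with the predictions.  Groups with zero
    samples are marked empty.
    """
    if len(metadata) != len(predicted):
        raise ValueError(
            f"metadata covers {len(metadata)} samples but there are "
            f"{len(predicted)} predictions"
        )
    for col in ("gender", "age"):
        if col in metadata.columns and metadata[col].isna().any():
            bad = metadata.loc[metadata[col].isna(), "id"].tolist()
            raise ValueError(f"missing {col} for sample(s): {bad}")
    predicted = list(predicted)
    actual = list(actual)
    rows = []
    groups: list[tuple[str, str, np.ndarray]] = []
    gender_values = metadata["gender"].to_numpy()
    bins = np.array([age_bin(a) for a in metadata["age"]])
    for gender in spec.genders:
        groups.append(("gender", gender, gender_values == gender))
    for label in spec.age_bins:
        groups.append(("age", label, bins == label))
    for kind, label, mask in groups:
        idx = np.flatnonzero(mask)
        row: dict[str, object] = {"group_type": kind, "group": label, "n": len(idx)}
        if len(idx) == 0:
            row.update({m: None for m in
                        ("accuracy", "sensitivity", "specificity", "precision", "npv")})
        else:
            rep = metrics(confusion([predicted[i] for i in idx],
                                    [actual[i] for i in idx]))
            row.update(rep.__dict__)
        rows.append(row)
    return pd.DataFrame(rows)
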