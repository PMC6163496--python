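"""Validity, efficiency and confusion-matrix calculus for conformal predictions.

A prediction is *correct* when its label set contains the true class, so
*both* predictions are always correct and *empty* predictions never are.
Per-class validity is

    validity(c) = (#correct single-label + #both among true-c compounds) / #true-c

and the predictor is valid at significance epsilon when 1 - validity <= epsilon.
Efficiency is the fraction of compounds receiving exactly one label; the
remainder split into the *both* and *empty* fractions.  Confusion-derived
metrics (sensitivity, specificity, balanced accuracy, Cohen's kappa, Matthews
correlation) are computed over single-label predictions only, with M as the
positive class; a zero denominator yields NaN, never zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .conformal import PredictionRecord
from .dataset import CLASS_LABELS, NEGATIVE_LABEL, POSITIVE_LABEL

__all__ = [
    "ConfusionCounts",
    "UndefinedMetricError",
    "validity",
    "efficiency",
    "both_empty_fractions",
    "confusion",
    "classification_metrics",
    "build_sweep_report",
]


class UndefinedMetricError(ValueError):
    """A metric's denominator is empty (e.g. no compounds of the class)."""


@dataclass(frozen=True)
class ConfusionCounts:
    """2x2 counts over single-label predictions only (M = positive)."""

    TP: int
    FP: int
    TN: int
    FN: int

    def __post_init__(self) -> None:
        if min(self.TP, self.FP, self.TN, self.FN) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.TN + self.FN


def _require_true_labels(records: Sequence[PredictionRecord]) -> None:
    if any(r.true_label is None for r in records):
        raise UndefinedMetricError("records must carry true labels")


def validity(
    records: Sequence[PredictionRecord], cls: str, significance: float
) -> float:
    """Fraction of true-class-``cls`` compounds whose label set contains ``cls``.

    Single-label correct predictions and *both* predictions count as correct;
    wrong single labels and *empty* sets count as errors.
    """
    _require_true_labels(records)
    members = [r for r in records if r.true_label == cls]
    if not members:
        raise UndefinedMetricError(f"no compounds of class {cls!r}")
    hits = sum(1 for r in members if cls in r.label_set(significance))
    return hits / len(members)


def efficiency(records: Sequence[PredictionRecord], significance: float) -> float:
    """Fraction of compounds assigned exactly one class label."""
    if not records:
        raise UndefinedMetricError("no records")
    single = sum(1 for r in records if len(r.label_set(significance)) == 1)
    return single / len(records)


def both_empty_fractions(
    records: Sequence[PredictionRecord], significance: float
) -> tuple[float, float]:
    """(fraction *both*, fraction *empty*); sums with efficiency to 1."""
    if not records:
        raise UndefinedMetricError("no records")
    sizes = [len(r.label_set(significance)) for r in records]
    return sizes.count(2) / len(sizes), sizes.count(0) / len(sizes)


def confusion(
    records: Sequence[PredictionRecord], significance: float
) -> ConfusionCounts:
    """Tally TP/FP/TN/FN over single-label predictions; *both*/*empty* excluded."""
    _require_true_labels(records)
    tp = fp = tn = fn = 0
    for r in records:
        labels = r.label_set(significance)
        if len(labels) != 1:
            continue
        (predicted,) = labels
        if predicted == POSITIVE_LABEL:
            if r.true_label == POSITIVE_LABEL:
                tp += 1
            else:
                fp += 1
        else:
            if r.true_label == NEGATIVE_LABEL:
                tn += 1
            else:
                fn += 1
    if tp + fp + tn + fn == 0:
        raise UndefinedMetricError("no single-label predictions at this level")
    return ConfusionCounts(TP=tp, FP=fp, TN=tn, FN=fn)


def _ratio(num: float, den: float) -> float:
    return num / den if den else math.nan


def classification_metrics(counts: ConfusionCounts) -> dict[str, float]:
    """Sensitivity, specificity, BA, kappa, MCC and the FN:FP ratio.

    kappa = (po - pe) / (1 - pe) with po the observed accuracy and pe the
    chance agreement [(TP+FN)(TP+FP) + (TN+FP)(TN+FN)] / total^2.  Undefined
    values (zero denominators) are returned as NaN.
    """
    tp, fp, tn, fn = counts.TP, counts.FP, counts.TN, counts.FN
    total = counts.total
    sensitivity = _ratio(tp, tp + fn)
    specificity = _ratio(tn, tn + fp)
    ba = (
        (sensitivity + specificity) / 2.0
        if not (math.isnan(sensitivity) or math.isnan(specificity))
        else math.nan
    )
    po = _ratio(tp + tn, total)
    pe = _ratio((tp + fn) * (tp + fp) + (tn + fp) * (tn + fn), total**2)
    kappa = (
        _ratio(po - pe, 1.0 - pe) if not (math.isnan(po) or math.isnan(pe)) else math.nan
    )
    mcc_den = math.sqrt(
        float(tp + fp) * float(tp + fn) * float(tn + fp) * float(tn + fn)
    )
    mcc = _ratio(tp * tn - fp * fn, mcc_den)
    return {
        "sensitivity": sensitivity,
        "specificity": specificity,
        "balanced_accuracy": ba,
        "kappa": kappa,
        "mcc": mcc,
        "fn_fp_ratio": _ratio(fn, fp),
    }


_METRIC_COLUMNS = [
    "validity_M",
    "validity_NM",
    "efficiency",
    "fraction_both",
    "fraction_empty",
    "sensitivity",
    "specificity",
    "balanced_accuracy",
    "kappa",
    "mcc",
    "TP",
    "FP",
    "TN",
    "FN",
]


def _repetition_row(records, significance: float) -> dict[str, float]:
    row: dict[str, float] = {}
    for cls in CLASS_LABELS:
        try:
            row[f"validity_{cls}"] = validity(records, cls, significance)
        except UndefinedMetricError:
            row[f"validity_{cls}"] = math.nan
    row["efficiency"] = efficiency(records, significance)
    row["fraction_both"], row["fraction_empty"] = both_empty_fractions(
        records, significance
    )
    try:
        counts = confusion(records, significance)
        row.update(
            {
                k: v
                for k, v in classification_metrics(counts).items()
                if k != "fn_fp_ratio"
            }
        )
        row.update(TP=counts.TP, FP=counts.FP, TN=counts.TN, FN=counts.FN)
    except UndefinedMetricError:
        for key in ("sensitivity", "specificity", "balanced_accuracy", "kappa", "mcc",
                    "TP", "FP", "TN", "FN"):
            row[key] = math.nan
    return row


def build_sweep_report(
    repetition_results: Iterable,
    significance_grid: Sequence[float],
    kinds: Sequence[str] = ("internal", "external"),
) -> pd.DataFrame:
    """Significance-level sweep over repetitions, one row per (set kind, level).

    Validity, efficiency, both/empty fractions and the confusion-derived
    metrics are computed per repetition and averaged (NaN-skipping);
    confusion counts are reported as means, and the FN:FP ratio is computed
    from those mean counts.
    """
    results = list(repetition_results)
    if not results:
        raise ValueError("need at least one repetition")
    grid = list(significance_grid)
    if not grid:
        raise ValueError("significance grid must be non-empty")
    if any(not 0.0 <= eps <= 1.0 for eps in grid):
        raise ValueError("significance levels must lie in [0, 1]")

    rows = []
    for kind in kinds:
        for eps in grid:
            per_rep = pd.DataFrame(
                [
                    _repetition_row(getattr(res, f"{kind}_records"), eps)
                    for res in results
                ]
            )
            mean = per_rep.mean()  # skips NaN per column
            row = {"set": kind, "significance": eps}
            row.update({c: float(mean[c]) for c in _METRIC_COLUMNS})
            row["fn_fp_ratio"] = _ratio(row["FN"], row["FP"])
            rows.append(row)
    return pd.DataFrame(rows, columns=["set", "significance", *_METRIC_COLUMNS, "fn_fp_ratio"])
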