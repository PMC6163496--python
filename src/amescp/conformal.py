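"""Mondrian inductive conformal prediction from random-forest class probabilities.

The conformity score of a compound for a hypothesized class is simply the
fraction of forest trees voting for that class.  Calibration is *Mondrian*
(class-conditional): the class-M score list is built only from calibration
compounds whose true label is M, and likewise for NM, which is what gives the
predictor per-class validity.  A test compound's p-value for class c is the
fraction of the (calibration + 1)-element list lying strictly below its score:

    p_c = #{s in calibration_c : s < score_c} / (n_c + 1)

and the prediction set at significance level epsilon is {c : p_c >= epsilon},
which may contain one class, both classes, or be empty.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.ensemble import RandomForestClassifier

from .dataset import (
    CLASS_LABELS,
    NEGATIVE_LABEL,
    POSITIVE_LABEL,
    DatasetValidationError,
    LabeledFingerprintDataset,
)

__all__ = [
    "CalibrationError",
    "ConformityModel",
    "MondrianCalibration",
    "PredictionRecord",
    "fit_conformity_model",
    "build_calibration",
    "conformal_p_value",
    "assign_label_set",
    "predict",
    "records_to_frame",
]

DEFAULT_N_TREES = 100


class CalibrationError(ValueError):
    """Calibration data missing or degenerate."""


@dataclass(frozen=True)
class ConformityModel:
    """A fitted probabilistic classifier used as the conformity measure.

    The default underlying model is a 100-tree random forest; its per-class
    predicted probability (tree-vote fraction) is used directly as the
    conformity score, larger meaning more conforming.
    """

    underlying_classifier: RandomForestClassifier
    feature_dimension: int

    def class_probabilities(self, features: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Return ``(prob_M, prob_NM)`` arrays for a feature matrix."""
        X = np.asarray(features)
        if X.ndim != 2 or X.shape[1] != self.feature_dimension:
            raise DatasetValidationError(
                f"feature dimension mismatch: model expects {self.feature_dimension}, "
                f"got {X.shape[1] if X.ndim == 2 else X.shape}"
            )
        proba = self.underlying_classifier.predict_proba(X)
        classes = list(self.underlying_classifier.classes_)
        p_m = proba[:, classes.index(POSITIVE_LABEL)]
        p_nm = proba[:, classes.index(NEGATIVE_LABEL)]
        return p_m, p_nm


@dataclass(frozen=True)
class MondrianCalibration:
    """Per-class sorted conformity scores of the calibration compounds."""

    scores_M: np.ndarray
    scores_NM: np.ndarray

    def __post_init__(self) -> None:
        for name in ("scores_M", "scores_NM"):
            s = np.asarray(getattr(self, name), dtype=float)
            if s.size == 0:
                raise CalibrationError(f"{name} is empty")
            if np.any((s < 0.0) | (s > 1.0)):
                raise CalibrationError(f"{name} contains values outside [0, 1]")
            object.__setattr__(self, name, np.sort(s))

    def scores_for(self, label: str) -> np.ndarray:
        return self.scores_M if label == POSITIVE_LABEL else self.scores_NM


@dataclass(frozen=True)
class PredictionRecord:
    """Conformal p-values of one compound, with label sets derivable at any level.

    ``label_set`` needs no re-prediction: the pair (p_M, p_NM) determines the
    prediction set at every significance level, and the sets are nested --
    raising epsilon can only shrink them.
    """

    compound_id: str
    p_M: float
    p_NM: float
    true_label: str | None = None

    def __post_init__(self) -> None:
        for name in ("p_M", "p_NM"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")

    def label_set(self, significance: float) -> frozenset[str]:
        return assign_label_set(self.p_M, self.p_NM, significance)


def fit_conformity_model(
    proper_training: LabeledFingerprintDataset,
    n_trees: int = DEFAULT_N_TREES,
    seed: int = 0,
) -> ConformityModel:
    """Fit the underlying random forest on the proper training set."""
    proper_training.require_both_classes("proper training set")
    clf = RandomForestClassifier(n_estimators=n_trees, random_state=int(seed))
    clf.fit(proper_training.features, proper_training.labels)
    return ConformityModel(underlying_classifier=clf, feature_dimension=proper_training.n_features)


def build_calibration(
    model: ConformityModel,
    calibration_set: LabeledFingerprintDataset,
) -> MondrianCalibration:
    """Collect per-class conformity scores of the calibration compounds.

    ``scores_M`` holds the model's class-M probability for every true-M
    calibration compound (sorted ascending); ``scores_NM`` analogously.
    """
    counts = calibration_set.class_counts()
    if min(counts.values()) < 1:
        raise CalibrationError(
            f"calibration set must contain both classes, got {counts}"
        )
    p_m, p_nm = model.class_probabilities(calibration_set.features)
    is_m = calibration_set.labels == POSITIVE_LABEL
    return MondrianCalibration(scores_M=p_m[is_m], scores_NM=p_nm[~is_m])


def conformal_p_value(new_score: float, calibration_scores: np.ndarray) -> float:
    """Rank-based conformal p-value of a score against a sorted calibration list.

    The new compound joins the list (denominator n+1) and the p-value is the
    fraction of entries strictly below it; ties do not count as lower.
    """
    scores = np.asarray(calibration_scores, dtype=float)
    if scores.size == 0:
        raise CalibrationError("calibration score list is empty")
    n_lower = int(np.searchsorted(scores, new_score, side="left"))
    return n_lower / (scores.size + 1)


def assign_label_set(p_M: float, p_NM: float, significance: float) -> frozenset[str]:
    """Prediction set {c : p_c >= epsilon}; the boundary is inclusive."""
    for name, v in (("p_M", p_M), ("p_NM", p_NM), ("significance", significance)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name}={v} outside [0, 1]")
    out = set()
    if p_M >= significance:
        out.add(POSITIVE_LABEL)
    if p_NM >= significance:
        out.add(NEGATIVE_LABEL)
    return frozenset(out)


def predict(
    model: ConformityModel,
    calibration: MondrianCalibration,
    test_set: LabeledFingerprintDataset,
) -> list[PredictionRecord]:
    """One PredictionRecord per test compound, carrying its true label."""
    p_m, p_nm = model.class_probabilities(test_set.features)
    n_m = calibration.scores_M.size + 1
    n_nm = calibration.scores_NM.size + 1
    pv_m = np.searchsorted(calibration.scores_M, p_m, side="left") / n_m
    pv_nm = np.searchsorted(calibration.scores_NM, p_nm, side="left") / n_nm
    return [
        PredictionRecord(
            compound_id=str(cid),
            p_M=float(a),
            p_NM=float(b),
            true_label=str(lab),
        )
        for cid, a, b, lab in zip(test_set.compound_ids, pv_m, pv_nm, test_set.labels)
    ]


def records_to_frame(records, significance_levels=()):
    """Tabulate records as a DataFrame; one label-set column per requested level."""
    import pandas as pd

    data = {
        "compound_id": [r.compound_id for r in records],
        "true_label": [r.true_label for r in records],
        "p_M": [r.p_M for r in records],
        "p_NM": [r.p_NM for r in records],
    }
    for eps in significance_levels:
        data[f"set_at_{eps:g}"] = [
            "|".join(sorted(r.label_set(eps))) or "empty" for r in records
        ]
    return pd.DataFrame(data)
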