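"""Labeled fingerprint datasets, CSV I/O and the random-splitting primitives.

The universal input of the pipeline is a compounds x binary-features matrix
with a two-valued activity label: ``M`` (mutagenic, the positive class) or
``NM`` (nonmutagenic).  All downstream stages -- conformal calibration,
cross-conformal validation, the evaluation calculus -- consume this type.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "LabeledFingerprintDataset",
    "SplitPlan",
    "DatasetFormatError",
    "DatasetValidationError",
    "POSITIVE_LABEL",
    "NEGATIVE_LABEL",
    "read_dataset",
    "write_dataset",
    "split_external",
    "partition_folds",
]

POSITIVE_LABEL = "M"
NEGATIVE_LABEL = "NM"
CLASS_LABELS = (POSITIVE_LABEL, NEGATIVE_LABEL)

# Accepted label vocabularies, normalized internally to M / NM.
_LABEL_ALIASES = {
    "m": POSITIVE_LABEL,
    "1": POSITIVE_LABEL,
    "active": POSITIVE_LABEL,
    "nm": NEGATIVE_LABEL,
    "0": NEGATIVE_LABEL,
    "inactive": NEGATIVE_LABEL,
}


class DatasetFormatError(ValueError):
    """A file or matrix does not conform to the expected format."""


class DatasetValidationError(ValueError):
    """Structurally valid input violating a dataset invariant."""


def normalize_label(token: object) -> str:
    key = str(token).strip().lower()
    try:
        return _LABEL_ALIASES[key]
    except KeyError:
        raise DatasetValidationError(
            f"unknown class label {token!r}; accepted tokens (case-insensitive): "
            f"{sorted(_LABEL_ALIASES)}"
        ) from None


@dataclass(frozen=True)
class LabeledFingerprintDataset:
    """Compounds x binary-fingerprint matrix with M/NM activity labels.

    Parameters
    ----------
    compound_ids
        Unique text identifiers, one per row.
    features
        ``(n_compounds, n_features)`` matrix of 0/1 indicators.
    labels
        Per-compound class, each ``"M"`` or ``"NM"``.
    feature_names
        Optional column names; generated as ``bit_0000`` ... when omitted.
    """

    compound_ids: np.ndarray
    features: np.ndarray
    labels: np.ndarray
    feature_names: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        ids = np.asarray(self.compound_ids, dtype=object)
        X = np.asarray(self.features)
        y = np.asarray(self.labels, dtype=object)
        if X.ndim != 2:
            raise DatasetFormatError("features must be a 2-D matrix")
        if not (len(ids) == X.shape[0] == len(y)):
            raise DatasetValidationError("compound_ids, features and labels must align")
        bad = ~np.isin(X, (0, 1))
        if bad.any():
            r, c = np.argwhere(bad)[0]
            raise DatasetFormatError(
                f"non-binary feature value {X[r, c]!r} at row {r}, column {c}"
            )
        if len(np.unique(ids)) != len(ids):
            raise DatasetValidationError("compound_ids must be unique")
        unknown = set(y) - set(CLASS_LABELS)
        if unknown:
            raise DatasetValidationError(
                f"labels must be in {CLASS_LABELS}, got {sorted(map(str, unknown))}"
            )
        names = tuple(self.feature_names) or tuple(
            f"bit_{j:04d}" for j in range(X.shape[1])
        )
        if len(names) != X.shape[1]:
            raise DatasetValidationError("feature_names must match feature count")
        object.__setattr__(self, "compound_ids", ids)
        object.__setattr__(self, "features", X.astype(np.uint8))
        object.__setattr__(self, "labels", y.astype(str))
        object.__setattr__(self, "feature_names", names)

    @property
    def n_compounds(self) -> int:
        return self.features.shape[0]

    @property
    def n_features(self) -> int:
        return self.features.shape[1]

    def class_counts(self) -> dict[str, int]:
        return {c: int(np.sum(self.labels == c)) for c in CLASS_LABELS}

    def subset(self, indices: Sequence[int]) -> "LabeledFingerprintDataset":
        idx = np.asarray(indices, dtype=int)
        return replace(
            self,
            compound_ids=self.compound_ids[idx],
            features=self.features[idx],
            labels=self.labels[idx],
        )

    def require_both_classes(self, context: str = "dataset") -> None:
        counts = self.class_counts()
        if min(counts.values()) < 1 or self.n_compounds < 2:
            raise DatasetValidationError(
                f"{context} must contain at least one compound of each class "
                f"(got {counts})"
            )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, LabeledFingerprintDataset):
            return NotImplemented
        return (
            np.array_equal(self.compound_ids, other.compound_ids)
            and np.array_equal(self.features, other.features)
            and np.array_equal(self.labels, other.labels)
            and self.feature_names == other.feature_names
        )


@dataclass(frozen=True)
class SplitPlan:
    """Parameters of the repeated cross-conformal validation protocol.

    Defaults mirror the study design: a 70/30 train/external-test split
    repeated 50 times, each training set rotated through 5 folds so every
    training compound serves once in a ~20% calibration block, and a 20%
    internal test set drawn from each proper training set.
    """

    test_fraction: float = 0.30
    n_repetitions: int = 50
    n_folds: int = 5
    calibration_fraction: float = 0.20
    internal_test_fraction: float = 0.20
    base_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("test_fraction", "calibration_fraction", "internal_test_fraction"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must lie in (0, 1), got {v}")
        if self.n_repetitions < 1:
            raise ValueError("n_repetitions must be positive")
        if self.n_folds < 2:
            raise ValueError("n_folds must be at least 2")


def read_dataset(path: str | Path) -> LabeledFingerprintDataset:
    """Read a labeled fingerprint CSV (first column id, ``label`` column, 0/1 bits).

    Label tokens ``M``/``NM``, ``1``/``0`` and ``active``/``inactive`` are
    accepted case-insensitively and normalized to M/NM.
    """
    frame = pd.read_csv(path, dtype=str)
    if frame.shape[1] < 3:
        raise DatasetFormatError(
            "expected at least an id column, a 'label' column and one feature column"
        )
    id_col = frame.columns[0]
    label_cols = [c for c in frame.columns if c.lower() == "label"]
    if not label_cols:
        raise DatasetFormatError("no 'label' column found")
    label_col = label_cols[0]
    feature_cols = [c for c in frame.columns if c not in (id_col, label_col)]
    if frame.isna().any().any():
        raise DatasetFormatError("missing entries are not allowed")

    raw = frame[feature_cols].to_numpy(dtype=object)
    X = np.empty(raw.shape, dtype=np.uint8)
    for j, col in enumerate(feature_cols):
        for i, value in enumerate(raw[:, j]):
            token = str(value).strip()
            if token not in ("0", "1"):
                raise DatasetFormatError(
                    f"non-binary feature value {value!r} at row {i}, column {col!r}"
                )
            X[i, j] = int(token)
    labels = np.array([normalize_label(t) for t in frame[label_col]], dtype=object)
    return LabeledFingerprintDataset(
        compound_ids=frame[id_col].to_numpy(dtype=object),
        features=X,
        labels=labels,
        feature_names=tuple(feature_cols),
    )


def write_dataset(dataset: LabeledFingerprintDataset, path: str | Path) -> None:
    """Write the standard CSV form (id, label, one column per bit)."""
    frame = pd.DataFrame(dataset.features, columns=list(dataset.feature_names))
    frame.insert(0, "label", dataset.labels)
    frame.insert(0, "compound_id", dataset.compound_ids)
    frame.to_csv(path, index=False)


def _resolve_rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def split_external(
    dataset: LabeledFingerprintDataset,
    test_fraction: float,
    seed,
    stratify: bool = False,
) -> tuple[LabeledFingerprintDataset, LabeledFingerprintDataset]:
    """Randomly split into training and external-test subsets.

    The test set receives ``floor(N * test_fraction)`` compounds (936 at 0.30
    gives the canonical 656/280 partition); assignment is simple random by
    default, optionally stratified per class.  Deterministic for a fixed seed.
    """
    if not 0.0 < test_fraction < 1.0:
        raise ValueError(f"test_fraction must lie in (0, 1), got {test_fraction}")
    n = dataset.n_compounds
    n_test = int(np.floor(n * test_fraction))
    if n_test < 1:
        raise ValueError("test_fraction too small: empty test set")
    rng = _resolve_rng(seed)
    if stratify:
        test_idx: list[int] = []
        for c in CLASS_LABELS:
            members = np.flatnonzero(dataset.labels == c)
            k = int(np.floor(len(members) * test_fraction))
            test_idx.extend(rng.permutation(members)[:k].tolist())
        test = np.sort(np.asarray(test_idx, dtype=int))
    else:
        perm = rng.permutation(n)
        test = np.sort(perm[:n_test])
    mask = np.zeros(n, dtype=bool)
    mask[test] = True
    train = np.flatnonzero(~mask)
    return dataset.subset(train), dataset.subset(test)


def partition_folds(
    training: LabeledFingerprintDataset,
    n_folds: int,
    seed,
) -> list[tuple[LabeledFingerprintDataset, LabeledFingerprintDataset]]:
    """Partition a training set into ``n_folds`` (proper-training, calibration) pairs.

    The training compounds are shuffled once and cut into near-equal disjoint
    blocks; fold *k* uses block *k* as the calibration set (~20% for 5 folds)
    and the union of the others as the proper training set, so every compound
    calibrates exactly once across folds.
    """
    if n_folds < 2:
        raise ValueError("n_folds must be at least 2")
    counts = training.class_counts()
    lacking = {c: k for c, k in counts.items() if k < n_folds}
    if lacking:
        raise DatasetValidationError(
            f"each class needs at least n_folds={n_folds} members so every "
            f"calibration block can contain it; got {counts}"
        )
    rng = _resolve_rng(seed)
    perm = rng.permutation(training.n_compounds)
    blocks = np.array_split(perm, n_folds)
    folds = []
    for k in range(n_folds):
        calib = np.sort(blocks[k])
        proper = np.sort(np.concatenate([blocks[j] for j in range(n_folds) if j != k]))
        folds.append((training.subset(proper), training.subset(calib)))
    return folds
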