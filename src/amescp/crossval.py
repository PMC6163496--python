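"""Repeated cross-conformal validation protocol.

Each repetition draws a fresh 70/30 training/external-test split, cuts the
training set into five folds, and rotates the calibration role through the
folds: fold k fits the forest on the other four blocks, calibrates on block k
and scores the external test set.  The five per-fold p-values of each external
compound are then aggregated (median by default) into a single cross-conformal
p-value per class.  Each fold additionally draws an 80/20 internal
train/test split of its proper training set, fits a second forest on the
internal-train part, calibrates it on the same fold calibration block, and
records the internal-test p-values; internal records are pooled over folds.

Seed policy: repetition r derives an independent, order-insensitive seed
stream from ``(base_seed, r)`` via numpy's SeedSequence, with separate child
seeds for the external split, the fold partition, and each fold's model and
internal split, so any repetition is reproducible in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .conformal import (
    DEFAULT_N_TREES,
    PredictionRecord,
    build_calibration,
    fit_conformity_model,
    predict,
)
from .dataset import LabeledFingerprintDataset, SplitPlan, partition_folds, split_external

__all__ = [
    "RepetitionResult",
    "ProtocolError",
    "run_fold",
    "aggregate_fold_p_values",
    "run_experiment",
]


class ProtocolError(ValueError):
    """Violation of the cross-conformal protocol (e.g. missing fold values)."""


@dataclass(frozen=True)
class RepetitionResult:
    """One repetition's aggregated external records and pooled internal records."""

    repetition_index: int
    external_records: list[PredictionRecord]
    internal_records: list[PredictionRecord]


def _child_seed(seq: np.random.SeedSequence) -> int:
    # sklearn wants a plain int; keep it under 2**31
    return int(seq.generate_state(1)[0] % (2**31))


def run_fold(
    proper_training: LabeledFingerprintDataset,
    calibration_block: LabeledFingerprintDataset,
    external_test: LabeledFingerprintDataset,
    internal_test_fraction: float,
    model_seed: int,
    internal_split_seed,
    internal_model_seed: int,
    n_trees: int = DEFAULT_N_TREES,
) -> tuple[list[PredictionRecord], list[PredictionRecord]]:
    """Run one fold: external p-values plus the fold's internal-test records.

    Fits the forest on the proper training set, builds the Mondrian
    calibration from the fold's calibration block and scores the external
    test set.  Then splits the proper training 80/20, fits a second forest on
    the internal-train part, calibrates it on the *same* calibration block,
    and scores the internal test set.
    """
    model = fit_conformity_model(proper_training, n_trees=n_trees, seed=model_seed)
    calibration = build_calibration(model, calibration_block)
    external_records = predict(model, calibration, external_test)

    internal_train, internal_test = split_external(
        proper_training, internal_test_fraction, internal_split_seed
    )
    internal_model = fit_conformity_model(
        internal_train, n_trees=n_trees, seed=internal_model_seed
    )
    internal_calibration = build_calibration(internal_model, calibration_block)
    internal_records = predict(internal_model, internal_calibration, internal_test)
    return external_records, internal_records


def aggregate_fold_p_values(per_fold_p: np.ndarray, method: str = "median") -> np.ndarray:
    """Combine per-fold p-values (axis 0 = folds) into one value per entry.

    ``median`` (default) or ``mean``; the result always lies within the
    per-fold min/max and hence in [0, 1].
    """
    arr = np.asarray(per_fold_p, dtype=float)
    if arr.size == 0 or np.isnan(arr).any():
        raise ProtocolError("missing fold p-values")
    if method == "median":
        return np.median(arr, axis=0)
    if method == "mean":
        return np.mean(arr, axis=0)
    raise ValueError(f"unknown aggregation method {method!r}")


def run_experiment(
    dataset: LabeledFingerprintDataset,
    split_plan: SplitPlan,
    n_trees: int = DEFAULT_N_TREES,
    aggregation: str = "median",
) -> list[RepetitionResult]:
    """Run the full repeated cross-conformal protocol.

    For each repetition: external split -> fold partition -> one ``run_fold``
    per fold -> aggregate the folds' external p-values per compound and class.
    Internal records are pooled across folds.  Label sets at any significance
    level are computable afterwards from the stored p-values.
    """
    dataset.require_both_classes()
    results: list[RepetitionResult] = []
    for r in range(split_plan.n_repetitions):
        try:
            results.append(
                _run_repetition(dataset, split_plan, r, n_trees, aggregation)
            )
        except Exception as exc:
            raise ProtocolError(f"repetition {r} failed: {exc}") from exc
    return results


def _run_repetition(
    dataset: LabeledFingerprintDataset,
    plan: SplitPlan,
    repetition: int,
    n_trees: int,
    aggregation: str,
) -> RepetitionResult:
    root = np.random.SeedSequence(entropy=plan.base_seed, spawn_key=(repetition,))
    split_seq, fold_seq, *fold_seqs = root.spawn(2 + plan.n_folds)

    training, external_test = split_external(dataset, plan.test_fraction, split_seq)
    folds = partition_folds(training, plan.n_folds, fold_seq)

    per_fold_p_m: list[np.ndarray] = []
    per_fold_p_nm: list[np.ndarray] = []
    internal_records: list[PredictionRecord] = []
    for (proper, calib), seq in zip(folds, fold_seqs):
        model_seq, internal_split_seq, internal_model_seq = seq.spawn(3)
        ext, internal = run_fold(
            proper,
            calib,
            external_test,
            plan.internal_test_fraction,
            model_seed=_child_seed(model_seq),
            internal_split_seed=internal_split_seq,
            internal_model_seed=_child_seed(internal_model_seq),
            n_trees=n_trees,
        )
        per_fold_p_m.append(np.array([rec.p_M for rec in ext]))
        per_fold_p_nm.append(np.array([rec.p_NM for rec in ext]))
        internal_records.extend(internal)

    agg_m = aggregate_fold_p_values(np.vstack(per_fold_p_m), aggregation)
    agg_nm = aggregate_fold_p_values(np.vstack(per_fold_p_nm), aggregation)
    external_records = [
        PredictionRecord(
            compound_id=str(cid), p_M=float(a), p_NM=float(b), true_label=str(lab)
        )
        for cid, a, b, lab in zip(
            external_test.compound_ids, agg_m, agg_nm, external_test.labels
        )
    ]
    return RepetitionResult(
        repetition_index=repetition,
        external_records=external_records,
        internal_records=internal_records,
    )
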