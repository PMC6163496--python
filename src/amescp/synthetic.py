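"""Exchangeable synthetic fingerprint datasets emulating the study's shape.

The real 936-compound primary-aromatic-amine dataset and its substructure
fingerprints are proprietary, so the pipeline is exercised on generated data
with the same statistical skeleton: ~936 compounds at a ~2.06:1
mutagenic:nonmutagenic ratio, sparse binary features of which a handful are
class-informative ("activating" bits enriched among mutagens, "deactivating"
bits enriched among nonmutagens) and the rest are background noise.  Rows are
i.i.d. given the label, hence exchangeable -- the assumption under which the
conformal validity guarantee holds, and the reason this module exists.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .conformal import PredictionRecord
from .dataset import CLASS_LABELS, NEGATIVE_LABEL, POSITIVE_LABEL, LabeledFingerprintDataset

__all__ = ["SyntheticConfig", "FixtureError", "generate", "generate_record_fixture"]


class FixtureError(ValueError):
    """A requested fixture outcome cannot be realized."""


@dataclass(frozen=True)
class SyntheticConfig:
    """Generator parameters; defaults emulate the study dataset's shape.

    936 compounds, 630 mutagenic (ratio 2.06:1); 200 binary features of which
    20 are activating (Bernoulli ``p_on_enriched`` in class M, background
    rate otherwise) and 10 deactivating (symmetric for NM), the remaining 170
    background in both classes.
    """

    n_compounds: int = 936
    n_mutagenic: int = 630
    n_features: int = 200
    n_activating: int = 20
    n_deactivating: int = 10
    p_on_enriched: float = 0.30
    p_on_background: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.n_mutagenic < self.n_compounds:
            raise ValueError("need 0 < n_mutagenic < n_compounds")
        if self.n_activating + self.n_deactivating > self.n_features:
            raise ValueError("informative bits exceed feature count")
        if min(self.n_activating, self.n_deactivating) < 0:
            raise ValueError("bit counts must be non-negative")
        if not 0.0 <= self.p_on_background <= self.p_on_enriched <= 1.0:
            raise ValueError("need 0 <= p_on_background <= p_on_enriched <= 1")


def generate(config: SyntheticConfig) -> LabeledFingerprintDataset:
    """Draw a labeled dataset; bit-identical for a fixed seed.

    Each row is sampled independently given its label, so rows are
    exchangeable within class; row order is shuffled so the labels carry no
    positional information.
    """
    rng = np.random.default_rng(config.seed)
    n, d = config.n_compounds, config.n_features
    n_act, n_deact = config.n_activating, config.n_deactivating

    labels = np.array(
        [POSITIVE_LABEL] * config.n_mutagenic
        + [NEGATIVE_LABEL] * (n - config.n_mutagenic),
        dtype=object,
    )
    rates = np.full((n, d), config.p_on_background)
    is_m = labels == POSITIVE_LABEL
    rates[np.ix_(is_m, np.arange(n_act))] = config.p_on_enriched
    rates[np.ix_(~is_m, np.arange(n_act, n_act + n_deact))] = config.p_on_enriched
    X = (rng.random((n, d)) < rates).astype(np.uint8)

    order = rng.permutation(n)
    names = (
        [f"act_{j:03d}" for j in range(n_act)]
        + [f"deact_{j:03d}" for j in range(n_deact)]
        + [f"noise_{j:03d}" for j in range(d - n_act - n_deact)]
    )
    return LabeledFingerprintDataset(
        compound_ids=np.array([f"CMP-{i:06d}" for i in range(n)], dtype=object),
        features=X[order],
        labels=labels[order],
        feature_names=tuple(names),
    )


def generate_record_fixture(
    outcomes: list[tuple[str, frozenset | set]],
    significance: float = 0.20,
) -> list[PredictionRecord]:
    """Synthetic prediction records realizing requested (true label, label set) pairs.

    P-values are chosen consistently with the stated significance level:
    included classes get p midway between the level and 1, excluded classes
    get half the level.  A set excluding a class cannot be realized at level
    0 (every p-value is >= 0); that inconsistency raises ``FixtureError``.
    """
    records = []
    for i, (true_label, label_set) in enumerate(outcomes):
        wanted = frozenset(label_set)
        if true_label not in CLASS_LABELS or not wanted <= frozenset(CLASS_LABELS):
            raise FixtureError(f"invalid outcome spec {true_label!r}, {set(wanted)!r}")
        if significance == 0.0 and wanted != frozenset(CLASS_LABELS):
            raise FixtureError("cannot exclude a class at significance 0")
        p_in = significance + 0.5 * (1.0 - significance)
        p_out = 0.5 * significance
        records.append(
            PredictionRecord(
                compound_id=f"FIX-{i:04d}",
                p_M=p_in if POSITIVE_LABEL in wanted else p_out,
                p_NM=p_in if NEGATIVE_LABEL in wanted else p_out,
                true_label=true_label,
            )
        )
    return records
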