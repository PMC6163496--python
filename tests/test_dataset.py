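import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from amescp import (
    DatasetFormatError,
    DatasetValidationError,
    LabeledFingerprintDataset,
    SplitPlan,
    partition_folds,
    read_dataset,
    split_external,
    write_dataset,
)


def _write(tmp_path, text):
    path = tmp_path / "data.csv"
    path.write_text(text)
    return path


class TestReadDataset:
    def test_direct_parse(self, tmp_path):
        path = _write(tmp_path, "id,label,f1,f2\na,M,1,0\nb,NM,0,0\nc,M,1,1\n")
        ds = read_dataset(path)
        assert ds.n_compounds == 3 and ds.n_features == 2
        assert list(ds.labels) == ["M", "NM", "M"]
        assert list(ds.compound_ids) == ["a", "b", "c"]

    @pytest.mark.parametrize(
        "tokens", [("M", "NM"), ("m", "nm"), ("1", "0"), ("Active", "inactive")]
    )
    def test_label_vocabularies_normalized(self, tmp_path, tokens):
        pos, neg = tokens
        path = _write(tmp_path, f"id,label,f1,f2\na,{pos},1,0\nb,{neg},0,1\n")
        assert list(read_dataset(path).labels) == ["M", "NM"]

    def test_non_binary_value_names_row_and_column(self, tmp_path):
        path = _write(tmp_path, "id,label,f1,f2\na,M,1,0\nb,NM,2,1\n")
        with pytest.raises(DatasetFormatError, match="row 1.*'f1'"):
            read_dataset(path)

    def test_duplicate_id_rejected(self, tmp_path):
        path = _write(tmp_path, "id,label,f1,f2\na,M,1,0\na,NM,0,1\n")
        with pytest.raises(DatasetValidationError, match="unique"):
            read_dataset(path)

    def test_unknown_label_lists_accepted_tokens(self, tmp_path):
        path = _write(tmp_path, "id,label,f1,f2\na,maybe,1,0\n")
        with pytest.raises(DatasetValidationError, match="active"):
            read_dataset(path)

    def test_round_trip_identity(self, tmp_path, tiny_dataset):
        path = tmp_path / "rt.csv"
        write_dataset(tiny_dataset, path)
        assert read_dataset(path) == tiny_dataset


class TestDatasetInvariants:
    def test_non_binary_matrix_rejected(self):
        with pytest.raises(DatasetFormatError):
            LabeledFingerprintDataset(
                compound_ids=np.array(["a", "b"], dtype=object),
                features=np.array([[1, 2], [0, 1]]),
                labels=np.array(["M", "NM"], dtype=object),
            )

    def test_single_class_fails_fit_precondition(self, tiny_dataset):
        ds = tiny_dataset.subset([0, 1, 2])
        with pytest.raises(DatasetValidationError):
            ds.require_both_classes()


class TestSplitPlan:
    def test_defaults_mirror_protocol(self):
        plan = SplitPlan()
        assert (plan.test_fraction, plan.n_repetitions, plan.n_folds) == (0.30, 50, 5)
        assert (plan.calibration_fraction, plan.internal_test_fraction) == (0.20, 0.20)

    @pytest.mark.parametrize("kwargs", [{"test_fraction": 0.0}, {"test_fraction": 1.0},
                                        {"n_folds": 1}, {"n_repetitions": 0}])
    def test_invalid_parameters(self, kwargs):
        with pytest.raises(ValueError):
            SplitPlan(**kwargs)


class TestSplitExternal:
    def test_canonical_936_split(self):
        rng = np.random.default_rng(0)
        ds = LabeledFingerprintDataset(
            compound_ids=np.array([f"c{i}" for i in range(936)], dtype=object),
            features=rng.integers(0, 2, size=(936, 3)),
            labels=np.array(["M"] * 630 + ["NM"] * 306, dtype=object),
        )
        training, test = split_external(ds, 0.30, seed=5)
        assert (training.n_compounds, test.n_compounds) == (656, 280)

    def test_floor_rule_small(self, tiny_dataset):
        big = tiny_dataset
        ds = LabeledFingerprintDataset(
            compound_ids=np.array([f"x{i}" for i in range(10)], dtype=object),
            features=np.tile(big.features[:1], (10, 1)),
            labels=np.array(["M"] * 5 + ["NM"] * 5, dtype=object),
        )
        training, test = split_external(ds, 0.30, seed=1)
        assert (training.n_compounds, test.n_compounds) == (7, 3)

    def test_deterministic_and_disjoint(self, small_synthetic):
        a_train, a_test = split_external(small_synthetic, 0.3, seed=9)
        b_train, b_test = split_external(small_synthetic, 0.3, seed=9)
        assert a_train == b_train and a_test == b_test
        combined = sorted(list(a_train.compound_ids) + list(a_test.compound_ids))
        assert combined == sorted(small_synthetic.compound_ids)

    def test_fraction_out_of_range(self, small_synthetic):
        with pytest.raises(ValueError):
            split_external(small_synthetic, 1.5, seed=0)

    def test_stratified_preserves_class_fractions(self, small_synthetic):
        _, test = split_external(small_synthetic, 0.3, seed=2, stratify=True)
        counts = test.class_counts()
        assert counts["M"] == 30 and counts["NM"] == 15  # floor(100*.3), floor(50*.3)


class TestPartitionFolds:
    def test_656_into_5_near_equal(self):
        rng = np.random.default_rng(3)
        ds = LabeledFingerprintDataset(
            compound_ids=np.array([f"c{i}" for i in range(656)], dtype=object),
            features=rng.integers(0, 2, size=(656, 3)),
            labels=np.array(["M"] * 440 + ["NM"] * 216, dtype=object),
        )
        folds = partition_folds(ds, 5, seed=8)
        calib_sizes = sorted(c.n_compounds for _, c in folds)
        assert set(calib_sizes) <= {131, 132} and sum(calib_sizes) == 656
        assert all(p.n_compounds in (524, 525) for p, _ in folds)

    def test_exact_division(self):
        ds = LabeledFingerprintDataset(
            compound_ids=np.array([f"c{i}" for i in range(10)], dtype=object),
            features=np.eye(10, 4, dtype=int) % 2,
            labels=np.array(["M", "NM"] * 5, dtype=object),
        )
        folds = partition_folds(ds, 5, seed=0)
        assert all(c.n_compounds == 2 for _, c in folds)

    def test_calibration_blocks_partition_training(self, small_synthetic):
        folds = partition_folds(small_synthetic, 5, seed=4)
        pooled = sorted(
            cid for _, calib in folds for cid in calib.compound_ids
        )
        assert pooled == sorted(small_synthetic.compound_ids)
        for proper, calib in folds:
            assert not set(proper.compound_ids) & set(calib.compound_ids)
            assert proper.n_compounds + calib.n_compounds == small_synthetic.n_compounds

    def test_scarce_class_rejected(self, tiny_dataset):
        with pytest.raises(DatasetValidationError):
            partition_folds(tiny_dataset, 5, seed=0)


@settings(derandomize=True, max_examples=30)
@given(
    n=st.integers(min_value=4, max_value=60),
    frac=st.floats(min_value=0.1, max_value=0.9),
    seed=st.integers(min_value=0, max_value=2**31 - 1),
)
def test_split_is_disjoint_exhaustive_and_floor_sized(n, frac, seed):
    """Any split is a partition with test size floor(N * fraction)."""
    if int(np.floor(n * frac)) < 1:
        return
    ds = LabeledFingerprintDataset(
        compound_ids=np.array([f"c{i}" for i in range(n)], dtype=object),
        features=np.zeros((n, 2), dtype=np.uint8),
        labels=np.array(["M", "NM"] * (n // 2) + ["M"] * (n % 2), dtype=object),
    )
    training, test = split_external(ds, frac, seed)
    assert test.n_compounds == int(np.floor(n * frac))
    ids = set(training.compound_ids) | set(test.compound_ids)
    assert len(ids) == n and not set(training.compound_ids) & set(test.compound_ids)
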