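"""Dataset I/O, normalisation and partitioning contracts."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ergan import dataio
from ergan import fixtures as fx


class TestRoundTrip:
    def test_csv_round_trip_is_bit_exact(self, tiny_dataset, tmp_path):
        p = dataio.write_dataset(tiny_dataset, tmp_path / "ds.csv")
        back = dataio.read_dataset(p)
        assert np.array_equal(back.X, tiny_dataset.X)
        assert back.meta[dataio.META_COLUMNS].equals(
            tiny_dataset.meta[dataio.META_COLUMNS]
        )
        assert back.grid == tiny_dataset.grid

    def test_partition_and_normalization_survive_round_trip(self, tiny_dataset, tmp_path):
        split = dataio.split_train_test(tiny_dataset, 0.25, seed=0)
        tr = dataio.normalize(split.train)
        p = dataio.write_dataset(tr, tmp_path / "train.csv")
        back = dataio.read_dataset(p)
        assert back.partition == "train"
        assert back.normalization == tr.normalization

    def test_wrong_signal_column_count_rejected(self, tiny_dataset, tmp_path):
        p = dataio.write_dataset(tiny_dataset, tmp_path / "ds.csv")
        df = pd.read_csv(p)
        df.drop(columns=["s234"]).to_csv(tmp_path / "short.csv", index=False)
        with pytest.raises(dataio.DatasetFormatError, match="234"):
            dataio.read_dataset(tmp_path / "short.csv", grid=tiny_dataset.grid)

    def test_non_binary_label_rejected_with_row(self, tiny_dataset, tmp_path):
        p = dataio.write_dataset(tiny_dataset, tmp_path / "ds.csv")
        df = pd.read_csv(p)
        df.loc[3, "group"] = 2
        df.to_csv(p, index=False)
        with pytest.raises(dataio.DatasetFormatError, match="row 3"):
            dataio.read_dataset(p)

    def test_empty_file_rejected(self, tmp_path):
        (tmp_path / "empty.csv").write_text("")
        with pytest.raises(dataio.DatasetFormatError):
            dataio.read_dataset(tmp_path / "empty.csv")


class TestNormalization:
    def test_minmax_maps_extremes_to_unit_interval(self, tiny_dataset):
        n = dataio.normalize(tiny_dataset, "minmax")
        assert n.X.min() == pytest.approx(-1.0)
        assert n.X.max() == pytest.approx(1.0)

    @pytest.mark.parametrize("mode", ["minmax", "zscore"])
    def test_inverse_round_trip(self, tiny_dataset, mode):
        n = dataio.normalize(tiny_dataset, mode)
        back = dataio.denormalize(n)
        assert np.abs(back.X - tiny_dataset.X).max() < 1e-9
        assert back.normalization is None

    def test_constant_dataset_rejected(self, grid):
        meta = pd.DataFrame(
            {"id": ["a", "b"], "subject": "s", "eye": "L", "group": [0, 1],
             "strength": 1.0, "replicate": 1, "synthetic": False}
        )
        const = dataio.LabeledDataset(X=np.zeros((2, 235)), meta=meta, grid=grid)
        with pytest.raises(ValueError, match="zero-variance"):
            dataio.normalize(const, "zscore")
        with pytest.raises(ValueError, match="min-max"):
            dataio.normalize(const, "minmax")

    def test_train_constants_applied_to_test(self, tiny_dataset):
        split = dataio.split_train_test(tiny_dataset, 0.25, seed=0)
        tr = dataio.normalize(split.train)
        te = dataio.normalize(split.test, using=tr.normalization)
        assert te.normalization == tr.normalization
        # test extremes need not hit +-1 exactly
        assert te.X.min() >= -1.5 and te.X.max() <= 1.5


class TestSplit:
    def test_even_split_counts(self):
        pop = fx.PopulationConfig(counts={1.204: (100, 100)}, seed=0)
        ds = fx.generate_dataset(pop)
        res = dataio.split_train_test(ds, 0.25, seed=1)
        assert len(res.test) == 50
        assert res.test.class_counts() == {0: 25, 1: 25}
        assert res.train.partition == "train" and res.test.partition == "test"

    @settings(max_examples=20, derandomize=True, deadline=None)
    @given(st.integers(5, 60), st.integers(5, 60), st.integers(0, 1000))
    def test_per_group_share_within_one_record(self, n0, n1, seed):
        pop = fx.PopulationConfig(counts={1.204: (n0, n1)}, seed=seed)
        ds = fx.generate_dataset(pop)
        res = dataio.split_train_test(ds, 0.25, seed=seed)
        for g, n in ((0, n0), (1, n1)):
            got = int(np.sum(res.test.y == g))
            assert abs(got - 0.25 * n) <= 1.0

    def test_no_overlap_and_exhaustive(self, tiny_dataset):
        res = dataio.split_train_test(tiny_dataset, 0.25, seed=2)
        ids_tr = set(res.train.meta["id"])
        ids_te = set(res.test.meta["id"])
        assert not ids_tr & ids_te
        assert ids_tr | ids_te == set(tiny_dataset.meta["id"])

    def test_subject_grouping_keeps_subjects_on_one_side(self, tiny_dataset):
        res = dataio.split_train_test(tiny_dataset, 0.25, seed=2, group_by_subject=True)
        assert not set(res.train.meta["subject"]) & set(res.test.meta["subject"])

    def test_degenerate_group_rejected(self, grid):
        meta = pd.DataFrame(
            {"id": ["a", "b", "c"], "subject": "s", "eye": "L",
             "group": [0, 0, 1], "strength": 1.0, "replicate": 1, "synthetic": False}
        )
        ds = dataio.LabeledDataset(X=np.random.default_rng(0).normal(size=(3, 235)),
                                   meta=meta, grid=grid)
        with pytest.raises(ValueError, match="cannot stratify"):
            dataio.split_train_test(ds, 0.25, seed=0)

    def test_manifest_lists_both_sides(self, tiny_dataset, tmp_path):
        res = dataio.split_train_test(tiny_dataset, 0.25, seed=2)
        p = res.write_manifest(tmp_path / "split.json")
        import json

        doc = json.loads(p.read_text())
        assert len(doc["train_ids"]) == len(res.train)
        assert doc["stratified_by"] == "group"


class TestKFold:
    def test_five_folds_of_twenty(self):
        pop = fx.PopulationConfig(counts={1.204: (50, 50)}, seed=0)
        ds = fx.generate_dataset(pop)
        folds = dataio.kfold_indices(ds, k=5, seed=0)
        assert len(folds) == 5
        assert all(len(val) == 20 for _, val in folds)

    def test_validation_folds_partition_the_dataset(self, tiny_dataset):
        folds = dataio.kfold_indices(tiny_dataset, k=5, seed=1)
        all_val = np.concatenate([val for _, val in folds])
        assert sorted(all_val) == list(range(len(tiny_dataset)))
        for fit, val in folds:
            assert not set(fit) & set(val)

    def test_folds_are_stratified(self, tiny_dataset):
        ratio = tiny_dataset.y.mean()
        for _, val in dataio.kfold_indices(tiny_dataset, k=5, seed=1):
            got = tiny_dataset.y[val].sum()
            assert abs(got - ratio * len(val)) <= 1.0

    def test_k_below_two_rejected(self, tiny_dataset):
        with pytest.raises(ValueError):
            dataio.kfold_indices(tiny_dataset, k=1)
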