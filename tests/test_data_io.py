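import numpy as np
import pandas as pd
import pytest

import otulearn as ol
from otulearn.data_io import read_table, write_table


class TestReadWrite:
    def test_round_trip_preserves_values_exactly(self, tiny_table, tmp_path):
        target = ol.TargetVector(np.array([1.5, 2.0, -0.5, 3.25, 0.0]))
        path = tmp_path / "t.csv"
        write_table(tiny_table, path, target=target)
        table2, target2 = read_table(path)
        assert table2.sample_ids == tiny_table.sample_ids
        assert table2.taxon_ids == tiny_table.taxon_ids
        assert table2.group_ids == tiny_table.group_ids
        np.testing.assert_array_equal(table2.counts, tiny_table.counts)
        np.testing.assert_array_equal(target2.values, target.values)

    def test_empty_table_errors(self, tmp_path):
        path = tmp_path / "empty.csv"
        path.write_text("sample_id,t1,t2\n")
        with pytest.raises(ValueError, match="empty"):
            read_table(path)

    def test_duplicate_sample_ids_named_in_error(self, tmp_path):
        path = tmp_path / "dup.csv"
        path.write_text("sample_id,t1\na,1\na,2\n")
        with pytest.raises(ValueError, match="a"):
            read_table(path)

    def test_non_numeric_column_errors(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("sample_id,t1,t2\na,1,x\nb,2,y\n")
        with pytest.raises(ValueError, match="t2"):
            read_table(path)

    def test_groups_derived_from_sample_id_prefix(self, tmp_path):
        path = tmp_path / "g.csv"
        path.write_text("sample_id,t1\nsoil1_r1,1\nsoil1_r2,2\nsoil2_r1,3\n")
        table, _ = read_table(path)
        assert table.group_ids == ["soil1", "soil1", "soil2"]


class TestRarefy:
    def test_rows_sum_to_depth(self, small_dataset):
        table, _, _ = small_dataset
        # generator rows already sum to 1023; rarefy down to 200
        rare = ol.rarefy(table, depth=200, seed=0)
        assert np.all(rare.counts.sum(axis=1) == 200)
        assert rare.n_samples == table.n_samples

    def test_shallow_sample_dropped_with_warning(self, tiny_table):
        # every tiny_table row has exactly 10 reads: depth 9 keeps all
        rare = ol.rarefy(tiny_table, depth=9, seed=1)
        assert rare.n_samples == 5
        shallow = ol.OtuTable(
            sample_ids=["a", "b"], taxon_ids=["t1"],
            counts=np.array([[500], [1100]]),
        )
        with pytest.warns(UserWarning, match="a"):
            out = ol.rarefy(shallow, depth=1023, seed=0)
        assert out.sample_ids == ["b"]

    def test_reproducible_for_fixed_seed(self, small_dataset):
        table, _, _ = small_dataset
        a = ol.rarefy(table, depth=300, seed=7)
        b = ol.rarefy(table, depth=300, seed=7)
        np.testing.assert_array_equal(a.counts, b.counts)

    def test_rejects_bad_inputs(self, tiny_table):
        with pytest.raises(ValueError):
            ol.rarefy(tiny_table, depth=0, seed=0)
        std = ol.OtuTable(
            sample_ids=["a"], taxon_ids=["t"], counts=np.array([[0.3]]),
            standardized=True,
        )
        with pytest.raises(ValueError, match="standardized"):
            ol.rarefy(std, depth=5, seed=0)

    def test_mean_rarefied_count_matches_hypergeometric_expectation(self):
        # taxon with proportion p in a sample: E[count] = p * depth
        counts = np.array([[300, 700]])
        table = ol.OtuTable(
            sample_ids=["s"], taxon_ids=["t1", "t2"], counts=counts
        )
        depth = 100
        draws = np.array(
            [ol.rarefy(table, depth, seed=s).counts[0, 0] for s in range(1000)]
        )
        expected = 0.3 * depth
        # variance of multivariate hypergeometric marginal
        n_tot = 1000
        var = depth * 0.3 * 0.7 * (n_tot - depth) / (n_tot - 1)
        se = np.sqrt(var / len(draws))
        assert abs(draws.mean() - expected) < 3 * se


class TestGroupSplit:
    def test_partition_is_disjoint_and_complete(self, small_dataset):
        table, target, _ = small_dataset
        (tr, tr_y), (te, te_y) = ol.group_split(table, target, 0.165, seed=0)
        assert set(tr.sample_ids) | set(te.sample_ids) == set(table.sample_ids)
        assert not set(tr.sample_ids) & set(te.sample_ids)
        assert not set(tr.group_ids) & set(te.group_ids)
        assert len(tr_y) == tr.n_samples and len(te_y) == te.n_samples

    def test_group_disjointness_across_seeds(self, small_dataset):
        table, target, _ = small_dataset
        for seed in range(20):
            (tr, _), (te, _) = ol.group_split(table, target, 0.165, seed=seed)
            assert not set(tr.group_ids) & set(te.group_ids)

    def test_achieved_sizes_near_requested_fraction(self, small_dataset):
        # replicate groups of 3: achieved test size within one group of target
        table, target, _ = small_dataset
        target_n = 0.165 * table.n_samples
        for seed in range(50):
            _, (te, _) = ol.group_split(table, target, 0.165, seed=seed)
            assert abs(te.n_samples - target_n) <= 3

    def test_reproducible_for_fixed_seed(self, small_dataset):
        table, target, _ = small_dataset
        a = ol.group_split(table, target, 0.3, seed=9)
        b = ol.group_split(table, target, 0.3, seed=9)
        assert a[0][0].sample_ids == b[0][0].sample_ids

    def test_single_group_errors(self):
        table = ol.OtuTable(
            sample_ids=["a", "b"], taxon_ids=["t"],
            counts=np.array([[1], [2]]), group_ids=["g", "g"],
        )
        with pytest.raises(ValueError, match="single"):
            ol.group_split(table, ol.TargetVector([1.0, 2.0]), 0.5, seed=0)


class TestStandardize:
    def test_train_columns_zero_mean_unit_variance(self, small_split):
        X = small_split["train"].counts
        nonconst = small_split["stats"].sd > 0
        np.testing.assert_allclose(X[:, nonconst].mean(axis=0), 0, atol=1e-10)
        np.testing.assert_allclose(
            X[:, nonconst].std(axis=0), 1, atol=1e-10
        )

    def test_constant_column_maps_to_zeros(self):
        table = ol.OtuTable(
            sample_ids=["a", "b", "c"], taxon_ids=["t1", "t2"],
            counts=np.array([[2, 1], [2, 5], [2, 9]]),
        )
        (scaled,), stats = ol.standardize(table)
        np.testing.assert_array_equal(scaled.counts[:, 0], 0)
        assert stats.sd[0] == 0

    def test_test_data_scaled_with_training_stats_only(self):
        # train col {0,2}: mean 1, population sd 1 -> test value 3 maps to 2.0
        train = ol.OtuTable(
            sample_ids=["a", "b"], taxon_ids=["t"], counts=np.array([[0], [2]])
        )
        test = ol.OtuTable(
            sample_ids=["c"], taxon_ids=["t"], counts=np.array([[3]])
        )
        (tr_s, te_s), stats = ol.standardize(train, [test])
        assert te_s.counts[0, 0] == pytest.approx(2.0)

    def test_outlier_in_test_does_not_change_training_stats(self, small_split):
        tr = small_split["train_raw"]
        te = small_split["test_raw"]
        wild = ol.OtuTable(
            sample_ids=te.sample_ids, taxon_ids=te.taxon_ids,
            counts=te.counts * 1000, group_ids=te.group_ids,
        )
        _, stats_plain = ol.standardize(tr, [te])
        _, stats_wild = ol.standardize(tr, [wild])
        np.testing.assert_array_equal(stats_plain.mean, stats_wild.mean)
        np.testing.assert_array_equal(stats_plain.sd, stats_wild.sd)

    def test_taxon_mismatch_errors(self, tiny_table):
        other = ol.OtuTable(
            sample_ids=["x"], taxon_ids=["zz", "tB", "tC", "tD"],
            counts=np.array([[1, 1, 1, 1]]),
        )
        with pytest.raises(ValueError, match="taxon"):
            ol.standardize(tiny_table, [other])

    def test_inverse_transform_round_trips(self, small_split):
        stats = small_split["stats"]
        raw = np.asarray(small_split["test_raw"].counts, dtype=float)
        back = stats.inverse(stats.transform(raw))
        nonconst = stats.sd > 0
        np.testing.assert_allclose(
            back[:, nonconst], raw[:, nonconst], atol=1e-12
        )


class TestOtuTableInvariants:
    def test_duplicate_sample_ids_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            ol.OtuTable(
                sample_ids=["a", "a"], taxon_ids=["t"],
                counts=np.array([[1], [2]]),
            )

    def test_negative_counts_rejected_unless_standardized(self):
        with pytest.raises(ValueError, match="negative"):
            ol.OtuTable(
                sample_ids=["a"], taxon_ids=["t"], counts=np.array([[-1]])
            )
        ol.OtuTable(
            sample_ids=["a"], taxon_ids=["t"], counts=np.array([[-1.0]]),
            standardized=True,
        )

    def test_dimension_mismatches_rejected(self):
        with pytest.raises(ValueError):
            ol.OtuTable(
                sample_ids=["a"], taxon_ids=["t1", "t2"],
                counts=np.array([[1]]),
            )
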