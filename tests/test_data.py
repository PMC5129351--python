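"""Table I/O, correlation screening, and the random splitter."""

import numpy as np
import pandas as pd
import pytest

from gepqsar import (
    CorrelationMatrix,
    DescriptorTable,
    TableFormatError,
    collinearity_filter,
    correlation_matrix,
    prefilter,
    random_split,
    read_table,
    reference_correlations,
    write_table,
)


def _pearson_oracle(x, y):
    # direct definition, no numpy corrcoef
    mx, my = sum(x) / len(x), sum(y) / len(y)
    num = sum((a - mx) * (b - my) for a, b in zip(x, y))
    dx = sum((a - mx) ** 2 for a in x) ** 0.5
    dy = sum((b - my) ** 2 for b in y) ** 0.5
    return num / (dx * dy)


class TestIO:
    def test_read_well_formed(self, tmp_path):
        p = tmp_path / "t.csv"
        p.write_text("compound,x1,x2,label\nc1,1.5,2.0,1\nc2,0.1,-3.0,0\nc3,2.2,0.0,1\n")
        t = read_table(p)
        assert t.n == 3 and t.descriptors == ["x1", "x2"]
        assert list(t.y) == [1, 0, 1]

    def test_nonbinary_label_names_row(self, tmp_path):
        p = tmp_path / "t.csv"
        p.write_text("compound,x1,label\nc1,1.0,0\nc2,2.0,2\n")
        with pytest.raises(TableFormatError, match="row 1"):
            read_table(p)

    def test_nonnumeric_cell_names_location(self, tmp_path):
        p = tmp_path / "t.csv"
        p.write_text("compound,x1,label\nc1,1.0,0\nc2,oops,1\n")
        with pytest.raises(TableFormatError, match="row 1.*x1"):
            read_table(p)

    def test_empty_file_rejected(self, tmp_path):
        p = tmp_path / "t.csv"
        p.write_text("")
        with pytest.raises(TableFormatError):
            read_table(p)

    def test_round_trip_93x8(self, tmp_path, rng):
        X = pd.DataFrame(rng.normal(size=(93, 8)),
                         columns=[f"d{i}" for i in range(8)])
        t = DescriptorTable(np.arange(1, 94), X, rng.integers(0, 2, 93))
        for ext in (".csv", ".tsv"):
            p = tmp_path / f"t{ext}"
            write_table(t, p, header_comments=["seed=1"])
            back = read_table(p)
            assert back.descriptors == t.descriptors
            assert np.array_equal(back.y, t.y)
            assert np.array_equal(back.X.to_numpy(), t.X.to_numpy())

    def test_unlabeled_table_round_trip(self, tmp_path, rng):
        t = DescriptorTable([1, 2, 3], pd.DataFrame({"x1": [1.0, 2.0, 3.0]}))
        p = tmp_path / "u.csv"
        write_table(t, p)
        assert read_table(p).y is None


class TestCorrelation:
    def test_self_correlation_is_one(self, rng):
        x = rng.normal(size=20)
        t = DescriptorTable(np.arange(20), pd.DataFrame({"a": x, "b": rng.normal(size=20)}))
        m = correlation_matrix(t)
        assert np.allclose(np.diag(m.values), 1.0)

    def test_exact_anticorrelation(self):
        x = np.array([1.0, 2.0, 5.0, -3.0])
        t = DescriptorTable(np.arange(4), pd.DataFrame({"a": x, "b": -x}))
        m = correlation_matrix(t)
        assert m.values[0, 1] == pytest.approx(-1.0)

    def test_matches_direct_formula_oracle(self):
        a = [1.0, 2.0, 4.0, 7.0, 11.0]
        b = [2.0, 1.0, 5.0, 4.0, 8.0]
        t = DescriptorTable(np.arange(5), pd.DataFrame({"a": a, "b": b}))
        m = correlation_matrix(t)
        assert m.values[0, 1] == pytest.approx(_pearson_oracle(a, b), abs=1e-12)

    def test_constant_column_named_in_error(self):
        t = DescriptorTable(np.arange(4), pd.DataFrame({"a": [1.0, 2, 3, 4],
                                                        "flat": [5.0] * 4}))
        with pytest.raises(ValueError, match="flat"):
            correlation_matrix(t)

    def test_symmetry_and_unit_diag_enforced(self):
        with pytest.raises(ValueError):
            CorrelationMatrix(np.array([[1.0, 0.5], [0.4, 1.0]]))
        with pytest.raises(ValueError):
            CorrelationMatrix(np.array([[0.9, 0.0], [0.0, 1.0]]))


class TestCollinearityFilter:
    def test_published_matrix_retains_all_eight(self):
        m = reference_correlations()
        assert m.max_offdiag() == pytest.approx(0.730)
        assert collinearity_filter(m, 0.8) == m.names
        assert len(m.names) == 8

    def test_identity_matrix_all_retained(self):
        m = CorrelationMatrix(np.eye(4))
        assert collinearity_filter(m) == m.names

    def test_offending_pair_drops_more_collinear_member(self):
        # r(1,2) = 0.9; column 2 is also correlated 0.5 with column 3,
        # column 1 only 0.1 -> column 2 is dropped
        vals = np.array([[1.0, 0.9, 0.1],
                         [0.9, 1.0, 0.5],
                         [0.1, 0.5, 1.0]])
        m = CorrelationMatrix(vals, ["c1", "c2", "c3"])
        assert collinearity_filter(m, 0.8) == ["c1", "c3"]

    def test_tie_drops_later_column(self):
        vals = np.array([[1.0, 0.9], [0.9, 1.0]])
        m = CorrelationMatrix(vals, ["c1", "c2"])
        assert collinearity_filter(m, 0.8) == ["c1"]

    def test_output_always_below_threshold(self, rng):
        for _ in range(20):
            A = rng.normal(size=(30, 6))
            A[:, 3] = A[:, 0] + rng.normal(scale=0.1, size=30)   # plant collinearity
            t = DescriptorTable(np.arange(30), pd.DataFrame(A, columns=list("abcdef")))
            m = correlation_matrix(t)
            kept = collinearity_filter(m, 0.8)
            idx = [m.names.index(k) for k in kept]
            sub = np.abs(m.values[np.ix_(idx, idx)] - np.eye(len(idx)))
            assert sub.max() < 0.8


class TestPrefilter:
    def test_constant_column_dropped(self):
        t = DescriptorTable(np.arange(4), pd.DataFrame({"a": [1.0, 2, 3, 4],
                                                        "flat": [5.0] * 4}))
        assert prefilter(t).descriptors == ["a"]

    def test_varying_full_columns_unchanged(self, rng):
        t = DescriptorTable(np.arange(10), pd.DataFrame(rng.normal(size=(10, 3)),
                                                        columns=["a", "b", "c"]))
        assert prefilter(t).descriptors == ["a", "b", "c"]

    def test_low_coverage_column_dropped(self):
        col = [1.0, 2.0, np.nan, np.nan]
        t = DescriptorTable(np.arange(4), pd.DataFrame({"a": [1.0, 2, 3, 4], "sparse": col}))
        assert prefilter(t, min_coverage=0.9).descriptors == ["a"]


class TestRandomSplit:
    def test_study_partition_sizes(self):
        train, test = random_split(128, 35, seed=4)
        assert len(train) == 93 and len(test) == 35
        assert len(np.intersect1d(train, test)) == 0
        assert np.array_equal(np.union1d(train, test), np.arange(1, 129))

    def test_same_seed_same_partition(self):
        assert np.array_equal(random_split(128, 35, 9)[1], random_split(128, 35, 9)[1])
        assert not np.array_equal(random_split(128, 35, 9)[1], random_split(128, 35, 10)[1])

    @pytest.mark.parametrize("n_total,n_test", [(128, 0), (128, 128), (1, 1), (10, 15)])
    def test_bad_sizes_rejected(self, n_total, n_test):
        with pytest.raises(ValueError):
            random_split(n_total, n_test, 0)

    def test_encodings_are_one_based(self):
        train, test = random_split(10, 3, seed=0)
        allv = np.concatenate([train, test])
        assert allv.min() >= 1 and allv.max() <= 10
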