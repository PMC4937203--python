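"""Data cube construction, I/O round trips, subsetting and filtering."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from kronstat import (
    TransposableDataset,
    filter_rows_by_total,
    load_long_table,
    load_wide_matrices,
    subset,
    write_dataset,
)
from .conftest import make_dataset


def write_long(path, lines):
    path.write_text("subject_id\trow_id\tcol_id\tvalue\n" + "".join(l + "\n" for l in lines))


TINY = [
    f"{s}\t{g}\t{t}\t{v}"
    for s, g, t, v in [
        ("s1", "gA", "t1", 1.0), ("s1", "gA", "t2", 2.0),
        ("s1", "gB", "t1", 3.0), ("s1", "gB", "t2", 4.0),
        ("s2", "gA", "t1", 5.0), ("s2", "gA", "t2", 6.0),
        ("s2", "gB", "t1", 7.0), ("s2", "gB", "t2", 8.0),
    ]
]


class TestConstruction:
    def test_rejects_nonfinite_and_bad_labels(self):
        with pytest.raises(ValueError, match="finite"):
            make_dataset(values=np.full((2, 2, 2), np.nan))
        with pytest.raises(ValueError, match="duplicate"):
            TransposableDataset(np.zeros((1, 2, 1)), ["s"], ["g", "g"], ["t"])
        with pytest.raises(ValueError, match="empty-string"):
            TransposableDataset(np.zeros((1, 1, 1)), [""], ["g"], ["t"])

    def test_shape_label_mismatch(self):
        with pytest.raises(ValueError, match="do not match"):
            TransposableDataset(np.zeros((2, 2, 2)), ["s1"], ["g1", "g2"], ["t1", "t2"])


class TestLongFormat:
    def test_tiny_file(self, tmp_path):
        f = tmp_path / "d.tsv"
        write_long(f, TINY)
        ds = load_long_table(f)
        assert (ds.n_subjects, ds.n_rows, ds.n_cols) == (2, 2, 2)
        assert ds.subject_ids == ["s1", "s2"]
        np.testing.assert_allclose(ds.values[1], [[5, 6], [7, 8]])

    def test_missing_triple_reports_key(self, tmp_path):
        f = tmp_path / "d.tsv"
        write_long(f, TINY[:-1])
        with pytest.raises(ValueError, match=r"incomplete cube.*s2.*gB.*t2"):
            load_long_table(f)

    def test_duplicate_triple(self, tmp_path):
        f = tmp_path / "d.tsv"
        write_long(f, TINY + [TINY[0]])
        with pytest.raises(ValueError, match="duplicate triple"):
            load_long_table(f)

    def test_non_numeric_value(self, tmp_path):
        f = tmp_path / "d.tsv"
        write_long(f, TINY[:-1] + ["s2\tgB\tt2\toops"])
        with pytest.raises(ValueError, match="non-numeric"):
            load_long_table(f)

    def test_line_count(self, tmp_path):
        ds = make_dataset(n=3, r=4, c=2)
        f = tmp_path / "out.tsv"
        write_dataset(ds, f, format="long")
        assert len(f.read_text().splitlines()) == 3 * 4 * 2 + 1


class TestWideFormat:
    def test_permuted_columns_reordered(self, tmp_path):
        ds = make_dataset(n=2, r=3, c=3)
        import pandas as pd

        a = pd.DataFrame(ds.values[0], index=ds.row_ids, columns=ds.col_ids)
        # same labelled data for subject 1, stored with permuted axes
        b = pd.DataFrame(
            ds.values[1][::-1, ::-1], index=ds.row_ids[::-1], columns=ds.col_ids[::-1]
        )
        a.to_csv(tmp_path / "a.tsv", sep="\t")
        b.to_csv(tmp_path / "b.tsv", sep="\t")
        (tmp_path / "manifest.tsv").write_text("s0\ta.tsv\ns1\tb.tsv\n")
        got = load_wide_matrices(tmp_path / "manifest.tsv")
        np.testing.assert_allclose(got.values, ds.values)
        assert got.row_ids == ds.row_ids and got.col_ids == ds.col_ids

    def test_label_mismatch_names_subject(self, tmp_path):
        ds = make_dataset(n=2, r=3, c=2)
        write_dataset(ds, tmp_path, format="wide")
        # corrupt second subject's file: drop a row
        f = tmp_path / "s1.tsv"
        f.write_text("".join(f.read_text().splitlines(keepends=True)[:-1]))
        with pytest.raises(ValueError, match="s1"):
            load_wide_matrices(tmp_path / "manifest.tsv")


@pytest.mark.parametrize("fmt", ["long", "wide"])
def test_round_trip(tmp_path, fmt):
    ds = make_dataset(n=3, r=5, c=4, seed=42)
    target = tmp_path / ("d.tsv" if fmt == "long" else "wide")
    write_dataset(ds, target, format=fmt)
    back = load_long_table(target) if fmt == "long" else load_wide_matrices(target / "manifest.tsv")
    np.testing.assert_allclose(back.values, ds.values, rtol=1e-12, atol=0)
    assert back.subject_ids == ds.subject_ids
    assert back.row_ids == ds.row_ids and back.col_ids == ds.col_ids


class TestSubset:
    def test_column_pair(self):
        ds = make_dataset(c=9 - 6)  # c=3
        got = subset(ds, cols=["t2", "t0"])
        assert got.col_ids == ["t2", "t0"]
        np.testing.assert_allclose(got.values, ds.values[:, :, [2, 0]])

    def test_row_reversal(self):
        ds = make_dataset()
        got = subset(ds, rows=ds.row_ids[::-1])
        np.testing.assert_allclose(got.values, ds.values[:, ::-1, :])

    def test_errors(self):
        ds = make_dataset()
        with pytest.raises(ValueError, match="unknown"):
            subset(ds, cols=["nope"])
        with pytest.raises(ValueError, match="empty"):
            subset(ds, rows=[])

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.data())
    def test_composition(self, data):
        ds = make_dataset(n=2, r=6, c=3, seed=7)
        a = data.draw(st.lists(st.sampled_from(ds.row_ids), min_size=2, max_size=6, unique=True))
        b = data.draw(st.lists(st.sampled_from(a), min_size=1, unique=True))
        lhs = subset(subset(ds, rows=a), rows=b)
        rhs = subset(ds, rows=b)
        np.testing.assert_array_equal(lhs.values, rhs.values)
        assert lhs.row_ids == rhs.row_ids


class TestFilter:
    def test_threshold_example(self):
        # single subject, row sums 0.05 and 0.2 against the standard 0.1 cutoff
        ds = make_dataset(values=np.array([[[0.02, 0.03], [0.15, 0.05]]]))
        kept, dropped = filter_rows_by_total(ds, 0.1)
        assert dropped == ["g0"] and kept.row_ids == ["g1"]

    def test_zero_threshold_keeps_nonnegative(self):
        ds = make_dataset(values=np.abs(np.random.default_rng(1).standard_normal((3, 4, 2))))
        kept, dropped = filter_rows_by_total(ds, 0.0)
        assert dropped == [] and kept.n_rows == 4

    def test_all_dropped_errors(self):
        ds = make_dataset(values=np.zeros((2, 3, 2)))
        with pytest.raises(ValueError, match="all rows dropped"):
            filter_rows_by_total(ds, 1.0)

    @pytest.mark.parametrize("reduction", ["mean_over_subjects", "per_subject_any"])
    def test_matches_bruteforce_recount(self, reduction, rng):
        ds = make_dataset(values=rng.gamma(1.0, 1.0, (4, 20, 3)))
        kept, dropped = filter_rows_by_total(ds, 2.5, reduction)
        survivors = []
        for a, rid in enumerate(ds.row_ids):  # independent loop oracle
            sums = [ds.values[i, a, :].sum() for i in range(ds.n_subjects)]
            if reduction == "mean_over_subjects":
                drop = sum(sums) / len(sums) < 2.5
            else:
                drop = any(s < 2.5 for s in sums)
            if not drop:
                survivors.append(rid)
        assert kept.row_ids == survivors
        assert dropped == [x for x in ds.row_ids if x not in survivors]
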