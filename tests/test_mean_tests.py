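"""Mean estimation, projection algebra, conservation tests and BH."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from kronstat import (
    ColumnGrouping,
    SimulationConfig,
    bh_adjust,
    estimate_mean,
    make_projection,
    mean_conservation_test,
    mean_variance_term_oracle,
    pairwise_conservation_tests,
    sample_dataset,
)
from .conftest import make_dataset


class TestEstimateMean:
    def test_identical_subjects(self):
        a = np.random.default_rng(0).standard_normal((1, 4, 3))
        ds = make_dataset(values=np.repeat(a, 5, axis=0))
        np.testing.assert_allclose(estimate_mean(ds).matrix, a[0])

    def test_opposite_pair_cancels(self):
        a = np.random.default_rng(1).standard_normal((4, 3))
        ds = make_dataset(values=np.stack([a, -a]))
        np.testing.assert_allclose(estimate_mean(ds).matrix, 0.0, atol=1e-15)

    def test_root_n_concentration(self):
        """||Xbar - M|| shrinks roughly like 1/sqrt(N)."""
        m = np.ones((20, 3))
        errs = {}
        for n in (5, 80):
            cfg = SimulationConfig(m, np.eye(20), np.eye(3), n, seed=2)
            errs[n] = np.linalg.norm(estimate_mean(sample_dataset(cfg)).matrix - m)
        assert errs[80] < errs[5]


class TestProjection:
    def test_single_pair_block(self):
        p = make_projection(ColumnGrouping([["a", "b"]]))
        np.testing.assert_allclose(p, [[0.5, -0.5], [-0.5, 0.5]])

    def test_all_singletons_give_zero(self):
        p = make_projection(ColumnGrouping([["a"], ["b"], ["c"]]))
        np.testing.assert_allclose(p, 0.0)

    def test_idempotent_with_expected_rank(self):
        g = ColumnGrouping([["a", "b", "c"], ["d", "e"], ["f"]])
        p = make_projection(g)
        np.testing.assert_allclose(p @ p, p, atol=1e-12)
        assert np.linalg.matrix_rank(p) == (3 - 1) + (2 - 1) + (1 - 1)

    def test_grouping_validation(self):
        with pytest.raises(ValueError, match="empty group"):
            ColumnGrouping([["a"], []])
        with pytest.raises(ValueError, match="more than one group"):
            ColumnGrouping([["a", "b"], ["b"]])


class TestConservationTest:
    def test_vacuous_grouping_rejected(self, small_ds):
        with pytest.raises(ValueError, match="vacuous"):
            mean_conservation_test(small_ds, ColumnGrouping([[c] for c in small_ds.col_ids]))

    def test_needs_four_subjects(self):
        ds = make_dataset(n=3)
        with pytest.raises(ValueError, match="N >= 4"):
            mean_conservation_test(ds, ColumnGrouping([list(ds.col_ids)]))

    def test_statistic_unbiased_for_projected_mean_norm(self):
        """Monte-Carlo mean of T near tr(M P M') for a mean that violates H0."""
        r, c, n = 30, 3, 8
        m = np.zeros((r, c))
        m[:6, 0] = 1.5
        g = ColumnGrouping([["t1", "t2", "t3"]])  # simulator labels are 1-based
        p = make_projection(g)
        target = np.trace(m @ p @ m.T)
        stats = []
        for rep in range(300):
            cfg = SimulationConfig(m, np.eye(r), np.eye(c), n, seed=rep)
            stats.append(mean_conservation_test(sample_dataset(cfg), g).statistic)
        se = np.std(stats, ddof=1) / np.sqrt(len(stats))
        assert abs(np.mean(stats) - target) < 3 * se

    def test_variance_term_matches_enumeration_oracle(self):
        ds = make_dataset(n=6, r=8, c=4, seed=11)
        g = ColumnGrouping([["t0", "t2"], ["t1", "t3"]])
        res = mean_conservation_test(ds, g)
        assert res.details["theta"] == pytest.approx(
            mean_variance_term_oracle(ds, g), rel=1e-10
        )

    def test_exact_invariance_to_group_constant_shift(self):
        """Adding a matrix whose rows are constant within groups changes
        neither the statistic nor the variance term."""
        ds = make_dataset(n=6, r=10, c=4, seed=21)
        g = ColumnGrouping([["t0", "t1"], ["t2", "t3"]])
        shift = np.zeros((10, 4))
        rng = np.random.default_rng(0)
        shift[:, :2] = rng.standard_normal((10, 1))
        shift[:, 2:] = rng.standard_normal((10, 1))
        shifted = make_dataset(values=ds.values + shift)
        a, b = mean_conservation_test(ds, g), mean_conservation_test(shifted, g)
        assert a.statistic == pytest.approx(b.statistic, rel=1e-10)
        assert a.z == pytest.approx(b.z, rel=1e-10)

    def test_one_sided_p_value_convention(self, small_ds):
        from scipy.stats import norm

        res = mean_conservation_test(small_ds, ColumnGrouping([list(small_ds.col_ids)]))
        assert res.p_value == pytest.approx(norm.sf(res.z))


class TestPairwise:
    def test_family_size_and_bh_attachment(self):
        ds = make_dataset(n=5, r=12, c=9, seed=4)
        results, adj = pairwise_conservation_tests(ds, ds.row_ids[:6], "t0")
        assert len(results) == 8 and len(adj) == 8
        for res in results:
            assert res.details["p_adj"] >= res.p_value - 1e-15

    def test_reference_overlap_rejected(self, small_ds):
        with pytest.raises(ValueError, match="also listed"):
            pairwise_conservation_tests(small_ds, small_ds.row_ids, "t0", ["t0", "t1"])


class TestBH:
    def test_hand_computed_step_up(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)

    def test_single_p_unchanged(self):
        np.testing.assert_allclose(bh_adjust([0.3]), [0.3])

    def test_input_validation(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=12))
    def test_bh_properties(self, pvals):
        adj = bh_adjust(pvals)
        assert np.all(adj >= np.asarray(pvals) - 1e-15)
        assert np.all(adj <= 1.0)
        # monotone in the ranks: sorting inputs sorts outputs
        order = np.argsort(pvals)
        assert np.all(np.diff(adj[order]) >= -1e-15)
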