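import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import dcmnet as d


class TestLaterality:
    @pytest.mark.parametrize(
        "label,side,expected",
        [("L_M1", "right", "cM1"), ("L_M1", "left", "iM1"), ("R_S1", "left", "cS1")],
    )
    def test_relabelling(self, label, side, expected):
        assert d.relabel_laterality(label, side) == expected

    def test_involution_on_side_flip(self):
        for label in ("L_M1", "R_PM", "L_SMA", "R_S1"):
            c = d.relabel_laterality(label, "right")
            i = d.relabel_laterality(label, "left")
            assert {c[0], i[0]} == {"c", "i"} and c[1:] == i[1:]

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError, match="unrecognized"):
            d.relabel_laterality("M1", "left")
        with pytest.raises(ValueError, match="moved_side"):
            d.relabel_laterality("L_M1", "up")


class TestShapiroWilk:
    def test_normal_sample_passes(self):
        rng = np.random.default_rng(0)
        w, p = d.shapiro_wilk(rng.standard_normal(500))
        assert 0.9 < w <= 1.0 and p > 0.01

    def test_uniform_sample_fails(self):
        rng = np.random.default_rng(0)
        _, p = d.shapiro_wilk(rng.uniform(0, 1, 5000))
        assert p < 0.001

    def test_domain_bounds(self):
        with pytest.raises(ValueError, match="3 <= n"):
            d.shapiro_wilk([1.0, 2.0])
        with pytest.raises(ValueError, match="constant"):
            d.shapiro_wilk([1.0, 1.0, 1.0, 1.0])


class TestPermutationTest:
    def test_exact_enumeration_example(self):
        assert d.permutation_test([1, 2, 3], [10, 11, 12]) == pytest.approx(2 / 20)

    def test_identical_samples_give_one(self):
        x = [0.3, 1.1, -0.4, 0.9]
        assert d.permutation_test(x, list(x)) == 1.0

    def test_degenerate_pooled_sample_warns(self):
        with pytest.warns(UserWarning, match="degenerate"):
            assert d.permutation_test([1.0, 1.0], [1.0, 1.0]) == 1.0

    def test_swap_and_shift_invariance(self):
        rng = np.random.default_rng(5)
        x, y = rng.normal(0, 1, 6), rng.normal(0.8, 1, 6)
        p1 = d.permutation_test(x, y, n_perm=2000, seed=7)
        p2 = d.permutation_test(y, x, n_perm=2000, seed=7)
        p3 = d.permutation_test(x + 10.0, y + 10.0, n_perm=2000, seed=7)
        assert p1 == p2 == p3

    def test_matches_independent_exact_oracle(self):
        rng = np.random.default_rng(2)
        for _ in range(3):
            x, y = rng.normal(0, 1, 5), rng.normal(1.0, 1, 5)
            mine = d.permutation_test(x, y)  # C(10,5) = 252 <= n_perm -> exact
            ref = __import__("scipy.stats", fromlist=["permutation_test"]).permutation_test(
                (x, y),
                lambda a, b, axis=-1: np.mean(a, axis=axis) - np.mean(b, axis=axis),
                permutation_type="independent",
                alternative="two-sided",
                n_resamples=np.inf,
            )
            assert mine == pytest.approx(ref.pvalue, abs=1e-12)

    def test_monte_carlo_converges(self):
        rng = np.random.default_rng(3)
        x, y = rng.normal(0, 1, 12), rng.normal(0.7, 1, 12)
        p1 = d.permutation_test(x, y, n_perm=20_000, seed=1)
        p2 = d.permutation_test(x, y, n_perm=40_000, seed=2)
        se = np.sqrt(p1 * (1 - p1) / 20_000)
        assert abs(p1 - p2) < 3 * se + 1e-4

    def test_input_validation(self):
        with pytest.raises(ValueError, match="at least 2"):
            d.permutation_test([1.0], [1.0, 2.0])
        with pytest.raises(ValueError, match="n_perm"):
            d.permutation_test([1.0, 2.0], [3.0, 4.0], n_perm=10)


class TestBhFdr:
    def test_worked_example(self):
        assert np.allclose(d.bh_fdr([0.01, 0.02, 0.03, 0.04]), 0.04)

    def test_single_and_bounds(self):
        assert d.bh_fdr([0.5]) == pytest.approx([0.5])
        with pytest.raises(ValueError):
            d.bh_fdr([0.0, 0.5])
        with pytest.raises(ValueError):
            d.bh_fdr([0.5, 1.2])

    @settings(derandomize=True, max_examples=50)
    @given(
        st.lists(st.floats(min_value=1e-9, max_value=1.0, exclude_min=False), min_size=1, max_size=40)
    )
    def test_adjustment_properties(self, pvals):
        adj = d.bh_fdr(pvals)
        p = np.asarray(pvals)
        assert np.all(adj >= p - 1e-15)
        assert np.all(adj <= 1.0)
        order = np.argsort(p, kind="stable")
        assert np.all(np.diff(adj[order]) >= -1e-12)


class TestCompareConditions:
    def test_table_shape_and_monotone_fdr(self):
        tab = d.generate_parameter_cohort(d.CohortConfig(seed=1))
        res = d.compare_conditions(tab, n_perm=2000, seed=0)
        t = res.table
        assert len(t) == 28
        assert np.all((t.p > 0) & (t.p <= 1))
        assert np.all(t.p_fdr >= t.p - 1e-15)

    def test_pools_adjusted_separately(self):
        tab = d.generate_parameter_cohort(d.CohortConfig(seed=1))
        labels = sorted(tab.label.unique())
        res = d.compare_conditions(
            tab, n_perm=2000, seed=0, pools={"x": labels[:14], "y": labels[14:]}
        )
        assert set(res.table.pool) == {"x", "y"}
        for _, grp in res.table.groupby("pool"):
            assert np.allclose(np.sort(grp.p_fdr), np.sort(d.bh_fdr(grp.p.to_numpy())))

    def test_missing_condition_rejected(self):
        tab = d.generate_parameter_cohort(d.CohortConfig(seed=1))
        tab = tab[~((tab.label == "cS1->cS1") & (tab.condition == "paretic"))]
        with pytest.raises(ValueError, match="cS1->cS1"):
            d.compare_conditions(tab, n_perm=2000)
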