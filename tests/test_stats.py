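import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import mstates as ms
from mstates.stats import _paired_t, _two_sample_t


def stacks_from_edges(values, n_ch):
    """Build symmetric subject matrices from per-subject upper-triangle values."""
    iu = np.triu_indices(n_ch, 1)
    out = np.zeros((values.shape[0], n_ch, n_ch))
    out[:, iu[0], iu[1]] = values
    out[:, iu[1], iu[0]] = values
    return out


class TestEdgeStatistics:
    def test_identical_group_means_give_zero_t(self, rng):
        vals = rng.random((4, 6))
        vals[2:] = vals[:2][::-1]  # same multiset per group
        stacks = stacks_from_edges(vals, 4)
        design = ms.DesignSpec(kind="two_sample")
        stat, p = ms.edge_statistics(stacks, design, groups=np.array([0, 0, 1, 1]))
        iu = np.triu_indices(4, 1)
        np.testing.assert_allclose(stat[iu], 0.0, atol=1e-12)
        np.testing.assert_allclose(p[iu], 1.0, atol=1e-12)

    def test_planted_edge_dominates_map(self, rng):
        vals = rng.standard_normal((12, 15)) * 0.1
        vals[6:, 7] += 3.0
        stacks = stacks_from_edges(vals, 6)
        stat, _ = ms.edge_statistics(stacks, ms.DesignSpec(kind="two_sample"),
                                     groups=np.repeat([0, 1], 6))
        iu = np.triu_indices(6, 1)
        assert np.argmax(np.abs(stat[iu])) == 7

    def test_two_plus_two_hand_formula(self):
        xa = np.array([[1.0], [2.0]])
        xb = np.array([[4.0], [6.0]])
        t, p = _two_sample_t(xa, xb)
        sp2 = ((1) * 0.5 + (1) * 2.0) / 2
        expect = (1.5 - 5.0) / np.sqrt(sp2 * (1 / 2 + 1 / 2))
        assert t[0] == pytest.approx(expect, abs=1e-12)

    def test_zero_variance_edge_excluded(self, rng):
        vals = rng.random((6, 3))
        vals[:, 1] = 2.0
        stacks = stacks_from_edges(vals, 3)
        stat, _ = ms.edge_statistics(stacks, ms.DesignSpec(kind="two_sample"),
                                     groups=np.repeat([0, 1], 3))
        iu = np.triu_indices(3, 1)
        assert np.isnan(stat[iu][1])


class TestSignedComponents:
    def test_no_suprathreshold_edges(self):
        stat = np.zeros((4, 4))
        p = np.ones((4, 4))
        pos, neg = ms.signed_components(stat, p, 0.05)
        assert pos == [] and neg == []

    def test_path_component_size_is_sum_of_t(self):
        n = 4
        stat = np.zeros((n, n))
        p = np.ones((n, n))
        for (i, j), t in zip([(0, 1), (1, 2), (2, 3)], [2.0, 3.0, 4.0]):
            stat[i, j] = stat[j, i] = t
            p[i, j] = p[j, i] = 0.001
        pos, neg = ms.signed_components(stat, p, 0.05)
        assert len(pos) == 1 and neg == []
        assert pos[0].size == pytest.approx(9.0)
        assert sorted(pos[0].edges) == [(0, 1), (1, 2), (2, 3)]

    def test_disjoint_edges_make_two_components(self):
        n = 5
        stat = np.zeros((n, n))
        p = np.ones((n, n))
        for i, j in [(0, 1), (2, 3)]:
            stat[i, j] = stat[j, i] = 2.0
            p[i, j] = p[j, i] = 0.001
        pos, _ = ms.signed_components(stat, p, 0.05)
        assert len(pos) == 2

    def test_signs_split(self):
        n = 3
        stat = np.zeros((n, n))
        p = np.full((n, n), 0.001)
        stat[0, 1] = stat[1, 0] = 2.0
        stat[1, 2] = stat[2, 1] = -2.0
        pos, neg = ms.signed_components(stat, p, 0.05)
        assert len(pos) == 1 and len(neg) == 1
        assert neg[0].size == pytest.approx(-2.0)


class TestNBS:
    def test_p_floor_with_2000_permutations(self):
        plv_a, plv_b, edges = ms.simulate_plv_cohort(
            15, n_channels=10, n_samples=1500,
            planted_edges=list(itertools.combinations([0, 2, 4, 6, 8], 2)),
            effect=5.0, seed=1)
        stacks = np.concatenate([plv_a, plv_b])
        design = ms.DesignSpec(kind="two_sample", p_thr=0.01, n_perm=2000, seed=0)
        comps = ms.nbs_test(stacks, design, groups=np.repeat([0, 1], 15))
        best = min(c.p for c in comps)
        assert best == pytest.approx(1 / 2001, abs=1e-12)

    def test_planted_component_recovered(self):
        edges = list(itertools.combinations([1, 3, 5, 7, 9], 2))
        plv_a, plv_b, _ = ms.simulate_plv_cohort(15, n_channels=16, n_samples=2000,
                                                 planted_edges=edges, effect=5.0,
                                                 seed=7)
        stacks = np.concatenate([plv_a, plv_b])
        design = ms.DesignSpec(kind="two_sample", p_thr=0.01, n_perm=500, seed=11)
        comps = ms.nbs_test(stacks, design, groups=np.repeat([0, 1], 15))
        sig = [c for c in comps if c.p < 0.05]
        found = {tuple(sorted(e)) for c in sig for e in c.edges}
        recall = len(found & set(edges)) / len(edges)
        assert recall >= 0.8

    def test_paired_and_correlation_designs_run(self, rng):
        base = rng.random((8, 6, 6))
        base = (base + base.transpose(0, 2, 1)) / 2
        shift = base + 0.3
        design = ms.DesignSpec(kind="paired", p_thr=0.05, n_perm=100, seed=3)
        comps = ms.nbs_test(base, design, stacks_b=shift)
        assert all(c.sign < 0 for c in comps if c.p < 0.05)
        scores = rng.random(8)
        design = ms.DesignSpec(kind="correlation", p_thr=0.2, n_perm=100, seed=3)
        ms.nbs_test(base, design, scores=scores)  # smoke: runs and returns

    def test_exact_enumeration_for_tiny_design(self, rng):
        vals = rng.standard_normal((6, 3))
        vals[3:] += 2.0
        stacks = stacks_from_edges(vals, 3)
        design = ms.DesignSpec(kind="two_sample", p_thr=0.2, n_perm=2000, seed=0)
        comps = ms.nbs_test(stacks, design, groups=np.repeat([0, 1], 3))
        for c in comps:
            assert c.null_summary["exact"]
            assert c.null_summary["n_perm"] == 20  # C(6, 3)

    def test_mean_fcscc(self):
        mat = np.arange(16, dtype=float).reshape(4, 4)
        comp = ms.ComponentResult(sign=1, edges=[(0, 1), (1, 2), (0, 3)], size=1.0)
        assert ms.mean_fcscc(mat, comp) == pytest.approx((1 + 6 + 3) / 3)
        with pytest.raises(ms.ParameterError):
            ms.mean_fcscc(mat, ms.ComponentResult(sign=1, edges=[], size=0.0))


class TestScalarPermutation:
    def test_paired_all_zero_differences(self):
        with pytest.warns(UserWarning, match="zero"):
            t, p = ms.permutation_test_scalar(np.ones(10), np.ones(10),
                                              design="paired")
        assert p == 1.0

    def test_p_floor_matches_formula(self, rng):
        """An observed statistic no permutation strictly beats lands on the
        (2*0+1)/(N+1) floor."""
        x = rng.random(20) + 10.0
        y = rng.random(20)
        t, p = ms.permutation_test_scalar(x, y, design="paired", n_perm=2000,
                                          seed=0)
        assert p == pytest.approx(1 / 2001, abs=1e-15)
        t, p = ms.permutation_test_scalar(x, y, design="paired", n_perm=100_000,
                                          seed=0)
        assert p == pytest.approx(1.000e-5, rel=1e-3)

    def test_two_sample_toy_matches_full_enumeration(self, rng):
        x = np.array([3.1, 2.9, 3.5])
        y = np.array([1.0, 1.4, 0.8])
        t_obs, p = ms.permutation_test_scalar(x, y, design="two_sample")
        pooled = np.concatenate([x, y])
        count = 0
        combos = list(itertools.combinations(range(6), 3))
        for combo in combos:
            mask = np.zeros(6, dtype=bool)
            mask[list(combo)] = True
            t = _two_sample_t(pooled[mask][:, None], pooled[~mask][:, None])[0][0]
            if abs(t) >= abs(t_obs) - 1e-12:
                count += 1
        assert p == pytest.approx(count / len(combos), abs=1e-12)

    def test_correlation_identity_hits_floor(self):
        x = np.arange(10.0)
        r, p = ms.permutation_correlation(x, x, n_perm=999, seed=0)
        assert r == pytest.approx(1.0)
        assert p == pytest.approx(1 / 1000, abs=1e-12)

    def test_correlation_hand_value(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        y = np.array([2.0, 1.0, 4.0, 3.0, 5.0])
        r, _ = ms.permutation_correlation(x, y, n_perm=100, seed=0)
        assert r == pytest.approx(np.corrcoef(x, y)[0, 1], abs=1e-12)

    def test_null_correlation_p_uniform(self, rng):
        """Under independence, permutation p-values are ~uniform (KS check)."""
        ps = []
        for _ in range(200):
            x = rng.standard_normal(30)
            y = rng.standard_normal(30)
            _, p = ms.permutation_correlation(x, y, n_perm=199,
                                              seed=int(rng.integers(2**31)))
            ps.append(p)
        from scipy.stats import kstest
        assert kstest(ps, "uniform").pvalue > 0.01

    def test_p_values_on_attainable_grid(self, rng):
        x = rng.standard_normal(25)
        y = rng.standard_normal(25)
        n_perm = 999
        _, p = ms.permutation_test_scalar(x, y, design="two_sample",
                                          n_perm=n_perm, seed=1)
        count = (p * (n_perm + 1) - 1) / 2
        assert count == pytest.approx(round(count), abs=1e-9)
        assert 0 < p <= 1


class TestHolm:
    def test_hand_step_down(self):
        adj = ms.holm_correction([0.01, 0.04, 0.03])
        np.testing.assert_allclose(adj, [0.03, 0.06, 0.06])

    def test_single_and_degenerate(self):
        np.testing.assert_allclose(ms.holm_correction([0.2]), [0.2])
        np.testing.assert_allclose(ms.holm_correction([1.0, 1.0]), [1.0, 1.0])

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=8))
    def test_adjusted_never_below_raw_and_monotone(self, ps):
        adj = ms.holm_correction(ps)
        assert np.all(adj >= np.asarray(ps) - 1e-15)
        order = np.argsort(ps)
        assert np.all(np.diff(adj[order]) >= -1e-15)


class TestBootstrap:
    def test_point_estimate_inside_interval(self, rng):
        x = rng.standard_normal(40)
        y = 0.6 * x + 0.8 * rng.standard_normal(40)
        from scipy.stats import pearsonr
        r = pearsonr(x, y)[0]
        lo, hi = ms.bca_bootstrap_ci(x, y, n_boot=999, seed=0)
        assert lo < r < hi

    def test_bca_close_to_percentile_when_symmetric(self, rng):
        x = rng.standard_normal(60)
        y = rng.standard_normal(60)
        lo_b, hi_b = ms.bca_bootstrap_ci(x, y, n_boot=2000, seed=1)
        from scipy.stats import bootstrap, pearsonr
        res = bootstrap((x, y), lambda a, b: pearsonr(a, b)[0], paired=True,
                        vectorized=False, n_resamples=2000, method="percentile",
                        rng=np.random.default_rng(1))
        lo_p, hi_p = res.confidence_interval
        assert lo_b == pytest.approx(lo_p, abs=0.05)
        assert hi_b == pytest.approx(hi_p, abs=0.05)

    def test_nominal_coverage(self, rng):
        """95% BCa interval covers the true correlation at the nominal rate."""
        rho = 0.5
        hits = 0
        n_rep = 120
        for _ in range(n_rep):
            x = rng.standard_normal(30)
            y = rho * x + np.sqrt(1 - rho**2) * rng.standard_normal(30)
            lo, hi = ms.bca_bootstrap_ci(x, y, n_boot=399,
                                         seed=int(rng.integers(2**31)))
            hits += lo <= rho <= hi
        rate = hits / n_rep
        half = 2.58 * np.sqrt(0.95 * 0.05 / n_rep)
        assert abs(rate - 0.95) <= half + 0.02


class TestEffectSizes:
    def test_cohens_d_reference_summaries(self):
        d = ms.cohens_d_from_summary(56.7, 12.1, 31, 58.9, 12.0, 23)
        assert round(d, 2) == -0.18

    def test_cohens_d_basics(self):
        assert ms.cohens_d_from_summary(5, 1, 10, 5, 1, 10) == 0.0
        assert ms.cohens_d_from_summary(1, 1, 10, 0, 1, 10) == pytest.approx(1.0)

    @pytest.mark.parametrize("table,expect", [
        ([[7, 24], [10, 13]], 0.22),
        ([[2, 29], [2, 21]], 0.04),
    ])
    def test_cramers_v_reference_tables(self, table, expect):
        assert round(ms.cramers_v(table), 2) == expect

    def test_cramers_v_proportional_table_is_zero(self):
        assert ms.cramers_v([[10, 20], [5, 10]]) == pytest.approx(0.0, abs=1e-12)

    def test_cramers_v_zero_margin_signalled(self):
        with pytest.raises(ms.ParameterError):
            ms.cramers_v([[0, 0], [5, 10]])
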