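import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import mstates as ms
from mstates.cluster import kl_curve


class TestGFP:
    def test_equal_channels_give_zero(self):
        rec = ms.EEGRecording(data=np.full((5, 10), 3.7), fs=250,
                              channels=list("abcde"))
        assert np.all(ms.global_field_power(rec) == 0)

    def test_two_channel_plus_minus_one(self):
        rec = ms.EEGRecording(data=np.array([[1.0], [-1.0]]), fs=250,
                              channels=["a", "b"])
        assert ms.global_field_power(rec)[0] == pytest.approx(1.0)

    def test_matches_population_sd_oracle(self, rng):
        data = rng.standard_normal((59, 200))
        rec = ms.EEGRecording(data=data, fs=250,
                              channels=[f"c{i}" for i in range(59)])
        gfp = ms.global_field_power(rec)
        oracle = np.sqrt(np.mean((data - data.mean(axis=0)) ** 2, axis=0))
        np.testing.assert_allclose(gfp, oracle, atol=1e-12)


class TestPeakExtraction:
    def test_monotone_series_has_no_peaks(self):
        assert ms.extract_gfp_peaks(np.linspace(0, 1, 100)).size == 0

    def test_sinusoidal_peaks_match_brute_force(self):
        t = np.arange(1000) / 250.0
        g = 1.0 + 0.5 * np.sin(2 * np.pi * 10 * t)
        brute = [i for i in range(1, 999) if g[i] > g[i - 1] and g[i] > g[i + 1]]
        found = ms.extract_gfp_peaks(g, discard_fraction=0.0, sd_multiple=100.0)
        np.testing.assert_array_equal(found, brute)
        # 15% discard removes exactly floor(0.15 n) of the lowest peaks
        kept = ms.extract_gfp_peaks(g, discard_fraction=0.15, sd_multiple=100.0)
        assert kept.size == len(brute) - int(np.floor(0.15 * len(brute)))

    def test_outlier_peak_excluded_by_sd_rule(self, rng):
        g = np.abs(rng.standard_normal(1000)) * 0.05
        g[500] = 4.0 * g.std() + g.mean() + 1.0  # far above mean + 3 SD
        got = ms.extract_gfp_peaks(g, discard_fraction=0.0)
        assert 500 not in got

    def test_peaks_respect_segment_boundaries(self):
        g = np.zeros(100)
        g[49] = 1.0  # local max of the whole array, but a boundary sample
        got = ms.extract_gfp_peaks(g, segments=[(0, 50), (50, 100)],
                                   discard_fraction=0.0)
        assert 49 not in got


class TestModifiedKMeans:
    def test_recovers_orthogonal_maps_under_sign_flips(self, rng):
        base = ms.generate_templates(16, 4, min_separation=1.0, seed=0)
        signs = rng.choice([-1.0, 1.0], size=400)
        maps = base[np.repeat(np.arange(4), 100)] * signs[:, None]
        est = ms.ModifiedKMeans(n_clusters=4, n_init=10, random_state=0).fit(maps)
        corr = np.abs(ms.spatial_correlation(est.cluster_centers_, base))
        from scipy.optimize import linear_sum_assignment
        r, c = linear_sum_assignment(-corr)
        assert np.all(corr[r, c] >= 0.999)

    def test_polarity_gauge_negating_input(self, rng):
        maps = rng.standard_normal((50, 16))
        a = ms.ModifiedKMeans(n_clusters=3, n_init=5, random_state=1).fit(maps)
        b = ms.ModifiedKMeans(n_clusters=3, n_init=5, random_state=1).fit(-maps)
        align = ms.spatial_correlation(a.cluster_centers_, b.cluster_centers_)
        from scipy.optimize import linear_sum_assignment
        r, c = linear_sum_assignment(-np.abs(align))
        assert np.all(np.abs(align[r, c]) > 1 - 1e-9)
        assert a.gev_ == pytest.approx(b.gev_, abs=1e-12)

    def test_k1_template_is_dominant_eigenvector(self, rng):
        maps = rng.standard_normal((80, 12))
        est = ms.ModifiedKMeans(n_clusters=1, n_init=1, random_state=0).fit(maps)
        centered = maps - maps.mean(axis=1, keepdims=True)
        w, v = np.linalg.eigh(centered.T @ centered)
        oracle = v[:, -1] - v[:, -1].mean()
        oracle /= np.linalg.norm(oracle)
        assert abs(float(est.cluster_centers_[0] @ oracle)) > 1 - 1e-9

    def test_k_larger_than_map_count_rejected(self, rng):
        with pytest.raises(ms.ParameterError):
            ms.ModifiedKMeans(n_clusters=10).fit(rng.standard_normal((5, 8)))

    def test_deterministic_under_seed(self, rng):
        maps = rng.standard_normal((60, 10))
        a = ms.ModifiedKMeans(3, n_init=5, random_state=9).fit(maps)
        b = ms.ModifiedKMeans(3, n_init=5, random_state=9).fit(maps)
        np.testing.assert_array_equal(a.cluster_centers_, b.cluster_centers_)

    def test_sklearn_params_roundtrip(self):
        est = ms.ModifiedKMeans(n_clusters=4, n_init=7)
        est2 = ms.ModifiedKMeans(**est.get_params())
        assert est2.get_params() == est.get_params()


class TestGEV:
    def test_scaled_flipped_copies_explain_everything(self, rng):
        templates = ms.generate_templates(16, 3, 0.5, seed=1)
        labels = rng.integers(0, 3, 50)
        scale = rng.uniform(0.5, 2.0, 50) * rng.choice([-1, 1], 50)
        maps = templates[labels] * scale[:, None]
        gfp = maps.std(axis=1)
        assert ms.gev(maps, gfp, templates, labels) == pytest.approx(1.0, abs=1e-12)

    def test_orthogonal_maps_explain_nothing(self):
        basis = ms.generate_templates(16, 4, min_separation=1.0, seed=0)
        templates, maps = basis[:2], basis[2:]
        labels = np.array([0, 1])
        gfp = maps.std(axis=1)
        assert ms.gev(maps, gfp, templates, labels) == pytest.approx(0.0, abs=1e-16)

    def test_three_map_hand_example(self):
        templates = ms.generate_templates(8, 2, min_separation=1.0, seed=3)
        maps = np.vstack([templates[0] * 2.0,
                          -(0.6 * templates[0] + 0.8 * templates[1]),
                          templates[1] * 0.5])
        labels = np.array([0, 0, 1])
        gfp = maps.std(axis=1, ddof=0)
        corr = np.array([1.0, 0.6, 1.0])  # |corr| with assigned template
        expected = np.sum((gfp * corr) ** 2) / np.sum(gfp**2)
        assert ms.gev(maps, gfp, templates, labels) == pytest.approx(expected, abs=1e-12)

    def test_zero_gfp_signalled(self):
        with pytest.raises(ms.ParameterError):
            ms.gev(np.zeros((3, 8)), np.zeros(3), np.zeros((2, 8)), np.array([0, 1, 0]))

    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_gev_bounded_unit_interval(self, seed):
        rng = np.random.default_rng(seed)
        maps = rng.standard_normal((20, 8))
        templates = rng.standard_normal((3, 8))
        labels = rng.integers(0, 3, 20)
        g = ms.gev(maps, maps.std(axis=1), templates, labels)
        assert 0.0 <= g <= 1.0


class TestModelOrderSelection:
    def test_sharp_elbow_selected(self):
        # dispersion drops steeply until k=5, then decays only gently
        disp = {2: 100.0, 3: 60.0, 4: 30.0, 5: 5.0, 6: 4.8, 7: 4.6, 8: 4.4,
                9: 4.2, 10: 4.0}
        assert ms.select_k_kl([disp], p=59) == 5

    def test_tie_breaks_to_smallest_k(self):
        # W(k) = (20 - 2k)/k with p=2 makes k^(2/p) W(k) linear in k, so
        # successive differences are constant and every KL value ties at 1
        disp = {k: (20.0 - 2 * k) / k for k in range(2, 8)}
        kl = kl_curve(disp, p=2)
        vals = np.array([kl[k] for k in sorted(kl)])
        assert np.allclose(vals, 1.0)
        assert ms.select_k_kl([disp], p=2) == 3

    def test_too_few_k_values_rejected(self):
        with pytest.raises(ms.ParameterError):
            kl_curve({2: 1.0, 3: 0.5}, p=10)

    def test_synthetic_five_state_data_selects_five(self, prepared_recording):
        prep, _ = prepared_recording
        gfp = ms.global_field_power(prep)
        peaks = ms.extract_gfp_peaks(gfp, prep.segments)
        maps = prep.data[:, peaks].T
        run = ms.cluster_k_range(maps, range(2, 9), n_repeats=5, seed=0)
        assert ms.select_k_kl([run.dispersion], p=59) == 5


class TestTemplateAggregation:
    def test_identical_recordings_reproduce_templates(self, templates59):
        sets = [ms.TemplateSet(maps=templates59.copy()) for _ in range(4)]
        grp = ms.group_templates(sets, 5, seed=0, n_repeats=5)
        corr = np.abs(ms.spatial_correlation(grp.maps, templates59))
        from scipy.optimize import linear_sum_assignment
        r, c = linear_sum_assignment(-corr)
        assert np.all(corr[r, c] > 1 - 1e-9)

    def test_noisy_recordings_recover_group_templates(self, templates59, rng):
        sets = []
        for _ in range(6):
            noisy = templates59 + 0.02 * rng.standard_normal(templates59.shape)
            noisy = noisy - noisy.mean(axis=1, keepdims=True)
            noisy /= np.linalg.norm(noisy, axis=1, keepdims=True)
            sets.append(ms.TemplateSet(maps=noisy))
        grp = ms.group_templates(sets, 5, seed=1, n_repeats=10)
        corr = np.abs(ms.spatial_correlation(grp.maps, templates59))
        from scipy.optimize import linear_sum_assignment
        r, c = linear_sum_assignment(-corr)
        assert np.all(corr[r, c] >= 0.99)

    def test_heterogeneous_k_rejected(self, templates59):
        sets = [ms.TemplateSet(maps=templates59),
                ms.TemplateSet(maps=templates59[:4])]
        with pytest.raises(ms.ParameterError):
            ms.group_templates(sets, 5, seed=0)

    def test_common_templates_of_identical_groups(self, templates59):
        a = ms.TemplateSet(maps=templates59)
        common = ms.common_templates(a, ms.TemplateSet(maps=templates59.copy()),
                                     seed=0, n_repeats=5)
        corr = np.abs(ms.spatial_correlation(common.maps, templates59))
        from scipy.optimize import linear_sum_assignment
        r, c = linear_sum_assignment(-corr)
        assert np.all(corr[r, c] > 1 - 1e-9)

    def test_channel_mismatch_rejected(self, templates59):
        a = ms.TemplateSet(maps=templates59)
        b = ms.TemplateSet(maps=ms.generate_templates(32, 5, 0.5, seed=0))
        with pytest.raises(ms.ParameterError):
            ms.common_templates(a, b, seed=0)


class TestTemplateOrdering:
    def test_recovers_shuffle_and_sign_flips(self, templates59, rng):
        ref = ms.TemplateSet(maps=templates59, labels=list("ABCDE"))
        perm = rng.permutation(5)
        signs = rng.choice([-1.0, 1.0], 5)
        shuffled = ms.TemplateSet(maps=templates59[perm] * signs[:, None])
        ordered = ms.order_templates(shuffled, ref)
        assert ordered.labels == list("ABCDE")
        np.testing.assert_allclose(ordered.maps, templates59, atol=1e-12)

    def test_matching_is_optimal_not_greedy(self):
        """On a crafted similarity matrix, row-wise greedy matching differs
        from the optimal assignment; the optimal one must be chosen."""
        base = ms.generate_templates(10, 3, min_separation=1.0, seed=0)
        weights = np.array([[0.90, 0.80, 0.0],
                            [0.85, 0.10, 0.0],
                            [0.0, 0.0, 0.5]])
        maps = np.stack([(w @ base) / np.linalg.norm(w @ base) for w in weights])
        corr = np.abs(ms.spatial_correlation(maps, base))
        from itertools import permutations
        totals = {p: sum(corr[i, p[i]] for i in range(3))
                  for p in permutations(range(3))}
        best = max(totals, key=totals.get)
        greedy = []
        for i in range(3):
            j = int(np.argmax(np.where(np.isin(range(3), greedy), -1, corr[i])))
            greedy.append(j)
        assert tuple(greedy) != best  # the example really separates the two
        ordered = ms.order_templates(ms.TemplateSet(maps=maps),
                                     ms.TemplateSet(maps=base, labels=list("XYZ")))
        for i in range(3):
            j = best[i]  # template i should sit at reference slot j
            assert abs(float(ordered.maps[j] @ maps[i])) > 0.999
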