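import numpy as np
import pytest

from elementscape.gwpca import (
    ScoreSet,
    element_weights,
    fit_gwpca,
    kernel_weights,
    morans_i,
    permutation_test,
    score_samples,
    select_bandwidth,
    summarize_loadings,
    variance_table,
)


def random_profiles(profile_factory, n=30, p=4, seed=0, spatial=False):
    rng = np.random.default_rng(seed)
    lons = rng.uniform(0.0, 10.0, n)
    lats = rng.uniform(0.0, 10.0, n)
    conc = rng.uniform(1.0, 10.0, (n, p))
    if spatial:
        conc[:, 0] += 3.0 * lons
    return profile_factory(lons, lats, conc)


class TestFitGWPCA:
    def test_uniform_large_bandwidth_matches_global_pca(self, profile_factory):
        profiles = random_profiles(profile_factory, n=100, p=14, seed=1)
        model = fit_gwpca(profiles, bandwidth=1e6, kernel="uniform",
                          adaptive=False)
        z = (profiles.conc - profiles.conc.mean(0)) / profiles.conc.std(0, ddof=1)
        cov = np.cov(z.T, bias=True)  # 1/n covariance of standardized data
        lam = np.sort(np.linalg.eigvalsh(cov))[::-1]
        for i in range(len(profiles)):
            np.testing.assert_allclose(model.local_eigenvalues[i], lam,
                                       rtol=1e-8, atol=1e-12)
        # loadings identical everywhere
        for i in range(1, len(profiles)):
            np.testing.assert_allclose(model.local_loadings[i],
                                       model.local_loadings[0], atol=1e-8)

    def test_perfectly_correlated_pair_gives_pc1_proportion_one(self, profile_factory):
        rng = np.random.default_rng(2)
        lons = rng.uniform(0, 5, 10)
        x = rng.uniform(1, 10, 10)
        profiles = profile_factory(lons, lons, np.column_stack([x, 2.0 * x]))
        model = fit_gwpca(profiles, bandwidth=1e6, kernel="uniform", adaptive=False)
        np.testing.assert_allclose(
            model.local_eigenvalues[:, 0]
            / model.local_eigenvalues.sum(axis=1), 1.0)

    def test_four_point_toy_matches_brute_force_weighted_eigen(self, profile_factory):
        # explicit recomputation: standardize, weight, covariance, eigh
        lons = np.array([0.0, 1.0, 0.0, 1.0])
        lats = np.array([0.0, 0.0, 1.0, 1.0])
        conc = np.array([[1.0, 5.0], [2.0, 3.0], [4.0, 2.0], [3.0, 7.0]])
        profiles = profile_factory(lons, lats, conc)
        bw = 2.0
        model = fit_gwpca(profiles, bandwidth=bw, kernel="bisquare", adaptive=False)
        z = (conc - conc.mean(0)) / conc.std(0, ddof=1)
        for i in range(4):
            d = np.hypot(lons - lons[i], lats - lats[i])
            w = (1.0 - (d / bw) ** 2) ** 2
            w = w / w.sum()
            m = w @ z
            cov = ((z - m) * w[:, None]).T @ (z - m)
            lam, vec = np.linalg.eigh(cov)
            lam = lam[::-1]
            np.testing.assert_allclose(model.local_eigenvalues[i], lam, atol=1e-12)
            for k in range(2):
                v = vec[:, ::-1][:, k]
                got = model.local_loadings[i, k]
                assert (np.allclose(got, v, atol=1e-10)
                        or np.allclose(got, -v, atol=1e-10))

    def test_loadings_orthonormal_and_eigenvalues_nonnegative(self, profile_factory):
        profiles = random_profiles(profile_factory, n=25, p=5, seed=3)
        model = fit_gwpca(profiles, bandwidth=10, kernel="bisquare")
        assert (model.local_eigenvalues >= 0).all()
        for L in model.local_loadings:
            np.testing.assert_allclose(L @ L.T, np.eye(5), atol=1e-10)

    def test_sign_convention_largest_entry_positive(self, profile_factory):
        profiles = random_profiles(profile_factory, n=25, p=5, seed=4)
        model = fit_gwpca(profiles, bandwidth=10)
        for L in model.local_loadings:
            for v in L:
                assert v[np.argmax(np.abs(v))] >= 0

    def test_needs_more_samples_than_elements(self, profile_factory):
        profiles = random_profiles(profile_factory, n=4, p=4)
        with pytest.raises(ValueError, match="more samples"):
            fit_gwpca(profiles, bandwidth=3)


class TestSummarizeLoadings:
    def test_identical_locals_summarize_to_themselves(self, profile_factory):
        profiles = random_profiles(profile_factory, n=20, p=3, seed=5)
        model = fit_gwpca(profiles, bandwidth=1e6, kernel="uniform", adaptive=False)
        summary = summarize_loadings(model, n_components=2)
        np.testing.assert_allclose(summary, model.local_loadings[0, :2], atol=1e-8)

    def test_sign_flipped_locals_align_before_averaging(self, profile_factory):
        profiles = random_profiles(profile_factory, n=10, p=3, seed=6)
        model = fit_gwpca(profiles, bandwidth=1e6, kernel="uniform", adaptive=False)
        # flip half the local copies by hand; alignment must undo it
        flipped = model.local_loadings.copy()
        flipped[::2] *= -1.0
        model.local_loadings = flipped
        summary = summarize_loadings(model, n_components=1)
        v = model.local_loadings[1, 0]
        assert np.allclose(summary[0], v, atol=1e-8) or np.allclose(
            summary[0], -v, atol=1e-8)

    def test_two_distinct_vectors_give_normalized_mean(self, profile_factory):
        profiles = random_profiles(profile_factory, n=6, p=2, seed=7)
        model = fit_gwpca(profiles, bandwidth=1e6, kernel="uniform", adaptive=False)
        a = np.array([1.0, 0.0])
        b = np.array([0.0, 1.0])
        model.local_loadings = np.tile(
            np.stack([np.stack([a, b]), np.stack([b, a])]), (3, 1, 1))
        summary = summarize_loadings(model, n_components=1)
        expected = (a + b) / np.linalg.norm(a + b)
        np.testing.assert_allclose(summary[0], expected, atol=1e-12)


class TestScoring:
    def test_zero_loadings_give_zero_scores(self, profile_factory):
        profiles = random_profiles(profile_factory, n=8, p=3)
        scores = score_samples(np.zeros((1, 3)), profiles)
        np.testing.assert_array_equal(scores.scores, 0.0)

    def test_raw_scoring_is_linear_in_concentration(self, profile_factory):
        profiles = random_profiles(profile_factory, n=8, p=3, seed=8)
        loading = np.array([[0.5, 0.5, 0.7]])
        s1 = score_samples(loading, profiles).component(0)
        doubled = profile_factory(profiles.lons, profiles.lats, 2.0 * profiles.conc,
                                  profiles.elements)
        s2 = score_samples(loading, doubled).component(0)
        np.testing.assert_allclose(s2, 2.0 * s1)

    def test_scores_permutation_equivariant(self, profile_factory):
        profiles = random_profiles(profile_factory, n=12, p=3, seed=9)
        loading = np.array([[0.2, 0.3, 0.9]])
        s = score_samples(loading, profiles).component(0)
        perm = np.random.default_rng(0).permutation(12)
        s_perm = score_samples(loading, profiles.subset(perm)).component(0)
        np.testing.assert_allclose(s_perm, s[perm])

    def test_element_order_mismatch_rejected(self, profile_factory):
        profiles = random_profiles(profile_factory, n=8, p=3)
        with pytest.raises(ValueError, match="element order|loading length"):
            score_samples(np.ones((1, 4)), profiles)


class TestVarianceTable:
    def test_two_equal_eigenvalues_split_evenly(self, profile_factory):
        profiles = random_profiles(profile_factory, n=10, p=2, seed=10)
        model = fit_gwpca(profiles, bandwidth=1e6, kernel="uniform", adaptive=False)
        model.local_eigenvalues = np.tile([2.0, 2.0], (10, 1))
        np.testing.assert_allclose(model.eigen_proportions, [0.5, 0.5])

    def test_kaiser_on_correlation_scale_spectrum(self, profile_factory):
        profiles = random_profiles(profile_factory, n=20, p=14, seed=11)
        model = fit_gwpca(profiles, bandwidth=1e6, kernel="uniform", adaptive=False)
        model.local_eigenvalues = np.tile([7.0, 3.5, 3.5] + [0.0] * 11, (20, 1))
        np.testing.assert_allclose(model.eigen_proportions[:3], [0.5, 0.25, 0.25])
        assert model.n_retained == 3
        table = variance_table(model)
        assert table.retained.sum() == 3

    def test_single_dominant_eigenvalue_retains_one(self, profile_factory):
        profiles = random_profiles(profile_factory, n=10, p=4, seed=12)
        model = fit_gwpca(profiles, bandwidth=1e6, kernel="uniform", adaptive=False)
        model.local_eigenvalues = np.tile([3.7, 0.1, 0.1, 0.1], (10, 1))
        assert model.n_retained == 1


class TestElementWeights:
    def test_weight_is_loading_times_mean(self):
        np.testing.assert_allclose(
            element_weights([0.28, 0.18], [5.415, 51.891]),
            [1.5162, 9.34038])

    def test_zero_loading_gives_zero_weight(self):
        assert element_weights([0.0], [123.4])[0] == 0.0


class TestBandwidthSelection:
    def test_single_candidate_returned(self, profile_factory):
        profiles = random_profiles(profile_factory, n=12, p=3, seed=13)
        assert select_bandwidth(profiles, candidates=[5]) == 5

    def test_chosen_bandwidth_minimizes_cv_score(self, profile_factory):
        from elementscape.gwpca import _loo_cv_score, pairwise_degree_distance

        profiles = random_profiles(profile_factory, n=20, p=3, seed=14, spatial=True)
        candidates = [4, 8, 12, 19]
        best = select_bandwidth(profiles, candidates=candidates)
        z = (profiles.conc - profiles.conc.mean(0)) / profiles.conc.std(0, ddof=1)
        dist = pairwise_degree_distance(profiles.lons, profiles.lats)
        cvs = {c: _loo_cv_score(z, dist, c, "bisquare", True, 1)
               for c in candidates}
        assert cvs[best] == min(cvs.values())

    def test_cv_score_matches_independent_brute_force(self, profile_factory):
        # explicit loop sharing no code with the implementation
        from elementscape.gwpca import _loo_cv_score

        rng = np.random.default_rng(15)
        lons = rng.uniform(0, 4, 5)
        lats = rng.uniform(0, 4, 5)
        conc = rng.uniform(1, 9, (5, 2))
        profiles = profile_factory(lons, lats, conc)
        z = (conc - conc.mean(0)) / conc.std(0, ddof=1)
        bw = 3.0
        total = 0.0
        for i in range(5):
            others = [j for j in range(5) if j != i]
            d = np.hypot(lons[others] - lons[i], lats[others] - lats[i])
            w = np.where(d < bw, (1 - (d / bw) ** 2) ** 2, 0.0)
            w = w / w.sum()
            m = sum(w[k] * z[j] for k, j in enumerate(others))
            cov = sum(w[k] * np.outer(z[j] - m, z[j] - m)
                      for k, j in enumerate(others))
            lam, vec = np.linalg.eigh(cov)
            v1 = vec[:, np.argmax(lam)]
            r = z[i] - m
            resid = r - v1 * (v1 @ r)
            total += resid @ resid
        from elementscape.gwpca import pairwise_degree_distance

        dist = pairwise_degree_distance(lons, lats)
        got = _loo_cv_score(z, dist, bw, "bisquare", False, 1)
        assert got == pytest.approx(total, rel=1e-10)

    def test_all_degenerate_candidates_error(self, profile_factory):
        profiles = random_profiles(profile_factory, n=6, p=2, seed=16)
        with pytest.raises(ValueError, match="degenerate"):
            select_bandwidth(profiles, candidates=[1e-9], adaptive=False)


class TestPermutationTest:
    def make_scores(self, values, seed=0, n=None):
        values = np.asarray(values, float)
        n = n or len(values)
        rng = np.random.default_rng(seed)
        lons = rng.uniform(0, 10, n)
        lats = rng.uniform(0, 10, n)
        return ScoreSet([f"s{i}" for i in range(n)], lons, lats,
                        values[:, None]), lons, lats

    def test_constant_scores_return_p_one_with_warning(self):
        scores, _, _ = self.make_scores(np.full(20, 3.0))
        with pytest.warns(UserWarning, match="constant"):
            stat, p = permutation_test(scores, n_perm=99, seed=0)
        assert p == 1.0 and np.isnan(stat)

    def test_strong_gradient_is_significant(self):
        rng = np.random.default_rng(21)
        lons = rng.uniform(0, 10, 40)
        lats = rng.uniform(0, 10, 40)
        values = 5.0 * lons + rng.normal(0, 0.5, 40)
        scores = ScoreSet([f"s{i}" for i in range(40)], lons, lats, values[:, None])
        _, p = permutation_test(scores, n_perm=199, seed=1)
        assert p <= 0.01

    def test_null_calibration_false_positive_rate(self):
        # shuffled locations: p should be roughly uniform
        rng = np.random.default_rng(22)
        hits = 0
        for rep in range(50):
            lons = rng.uniform(0, 10, 25)
            lats = rng.uniform(0, 10, 25)
            values = rng.normal(0, 1, 25)
            scores = ScoreSet([f"s{i}" for i in range(25)], lons, lats,
                              values[:, None])
            _, p = permutation_test(scores, n_perm=99, seed=rep)
            hits += p < 0.05
        assert 0 <= hits / 50 < 0.15

    def test_morans_i_two_point_antithetic(self):
        # two points with opposite values: I = -1 by direct arithmetic
        assert morans_i(np.array([1.0, -1.0]), np.array([0.0, 1.0]),
                        np.array([0.0, 0.0])) == pytest.approx(-1.0)
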