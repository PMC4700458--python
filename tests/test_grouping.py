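"""Grouping strategies and comparison machinery, each checked against an
independent oracle: bisection for the Gaussian crossover, closed-form 2x2
eigenvectors for PCA, brute-force normalized-cut search for spectral
clustering, direct formula evaluation (and scikit-learn) for the
Davies-Bouldin index, normal tail probabilities for the SVM overlap, and
the hand-written ANOVA-on-deviations formula for Levene's test."""

import itertools

import numpy as np
import pytest
from scipy import stats

from cardiowave import synthetic as syn
from cardiowave.grouping import (
    FitFailureError,
    _gaussian_crossover,
    davies_bouldin,
    fit_two_gaussians,
    group_population,
    levene_equal_variance,
    pca_axis,
    spectral_cluster,
    svm_overlap,
    threshold_group,
    waveform_similarity,
)


def relabel_agreement(a, b):
    """Fraction agreement of two 2-group labelings, up to label swap."""
    a, b = np.asarray(a), np.asarray(b)
    direct = np.mean(a == b)
    return max(direct, np.mean(a == 1 - b))


class TestTwoGaussians:
    def test_symmetric_crossover_is_midpoint(self):
        cx = _gaussian_crossover(np.array([100.0, 200.0]), np.array([15.0, 15.0]),
                                 np.array([0.5, 0.5]))
        assert cx == pytest.approx(150.0, abs=1e-9)

    def test_crossover_matches_bisection_oracle(self):
        means = np.array([100.0, 200.0])
        sds = np.array([10.0, 20.0])
        weights = np.array([0.5, 0.5])

        def logdiff(x):
            return (stats.norm.logpdf(x, means[0], sds[0]) + np.log(weights[0])
                    - stats.norm.logpdf(x, means[1], sds[1]) - np.log(weights[1]))

        from scipy.optimize import brentq

        oracle = brentq(logdiff, means[0], means[1])
        assert _gaussian_crossover(means, sds, weights) == pytest.approx(oracle, abs=1e-9)

    def test_fit_recovers_analytic_crossover(self):
        rng = np.random.default_rng(2024)
        x = np.concatenate([rng.normal(100.0, 15.0, 5000), rng.normal(200.0, 15.0, 5000)])
        fit = fit_two_gaussians(x, seed=0)
        assert fit.crossover_threshold == pytest.approx(150.0, abs=3.0)
        assert fit.weights.sum() == pytest.approx(1.0)
        assert fit.means[0] < fit.crossover_threshold < fit.means[1]

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            fit_two_gaussians(np.arange(10.0))

    def test_constant_data_rejected(self):
        with pytest.raises(ValueError):
            fit_two_gaussians(np.full(50, 7.0))


class TestPCA:
    def test_perfectly_correlated_variables(self):
        rng = np.random.default_rng(1)
        apd80 = rng.normal(150.0, 30.0, 200)
        apd30 = apd80 - 50.0
        pc = pca_axis(apd30, apd80)
        np.testing.assert_allclose(pc.loadings, [1 / np.sqrt(2)] * 2, atol=1e-12)
        assert pc.variance_explained_fraction == pytest.approx(1.0)

    def test_diagonal_covariance_closed_form(self):
        """Sample covariance diag(4, 1): the first axis is the APD30
        direction with 4/5 of the variance; the sign rule then makes the
        nonzero (APD30) loading positive."""
        apd30 = np.sqrt(3.0) * np.array([1.0, 1.0, -1.0, -1.0])
        apd80 = np.sqrt(3.0) / 2.0 * np.array([1.0, -1.0, 1.0, -1.0])
        cov = np.cov(np.column_stack([apd30, apd80]), rowvar=False)
        np.testing.assert_allclose(cov, np.diag([4.0, 1.0]), atol=1e-12)
        pc = pca_axis(apd30, apd80)
        np.testing.assert_allclose(np.abs(pc.loadings), [1.0, 0.0], atol=1e-12)
        assert pc.loadings[0] > 0
        assert pc.variance_explained_fraction == pytest.approx(0.8)

    def test_equal_uncorrelated_variance_tie_break(self):
        apd30 = np.array([1.0, -1.0, 1.0, -1.0])
        apd80 = np.array([1.0, 1.0, -1.0, -1.0])
        pc = pca_axis(apd30, apd80)
        np.testing.assert_allclose(pc.loadings, [1 / np.sqrt(2)] * 2, atol=1e-12)
        assert pc.variance_explained_fraction == pytest.approx(0.5)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            pca_axis(np.full(5, 1.0), np.full(5, 2.0))

    def test_scores_are_centered_projections(self):
        rng = np.random.default_rng(3)
        a30 = rng.normal(80, 20, 100)
        a80 = a30 + rng.normal(60, 10, 100)
        pc = pca_axis(a30, a80)
        x = np.column_stack([a30, a80]) - pc.center
        np.testing.assert_allclose(pc.scores, x @ pc.loadings, atol=1e-12)


class TestThreshold:
    def test_basic_split_and_tie_rule(self):
        labels = threshold_group(np.array([100.0, 149.0, 151.0, 300.0]), 150.0)
        np.testing.assert_array_equal(labels, [0, 0, 1, 1])
        assert threshold_group(np.array([150.0, 100.0]), 150.0)[0] == 1

    def test_degenerate_single_side_warns(self):
        with pytest.warns(UserWarning, match="one group"):
            labels = threshold_group(np.array([1.0, 2.0, 3.0]), 10.0)
        assert set(labels) == {0}


class TestSimilarity:
    def test_identical_waveforms_have_unit_similarity(self):
        aps = np.vstack([np.linspace(0, 1, 50)] * 3)
        sim = waveform_similarity(aps, sigma=1.0)
        np.testing.assert_allclose(sim.values, 1.0)

    def test_symmetry_and_unit_diagonal(self):
        rng = np.random.default_rng(0)
        aps = rng.standard_normal((10, 40))
        sim = waveform_similarity(aps)
        np.testing.assert_allclose(sim.values, sim.values.T, atol=1e-15)
        np.testing.assert_allclose(np.diag(sim.values), 1.0)
        assert np.all(sim.values > 0) and np.all(sim.values <= 1.0)

    def test_constant_waveform_pair_hand_sum(self):
        """Two constant waveforms differing by c over m samples:
        CSE = m c^2, and with only one nonzero distance sigma = sqrt(CSE)."""
        m, c = 30, 0.4
        aps = np.vstack([np.zeros(m), np.full(m, c)])
        sim = waveform_similarity(aps)
        cse = m * c**2
        assert sim.cse[0, 1] == pytest.approx(cse, abs=1e-12)
        assert sim.sigma == pytest.approx(np.sqrt(cse), abs=1e-12)
        assert sim.values[0, 1] == pytest.approx(np.exp(-cse / (2 * cse)), abs=1e-12)

    def test_mismatched_lengths_rejected(self):
        with pytest.raises(ValueError):
            waveform_similarity(np.zeros(5))


def normalized_cut(s, labels):
    """Exact normalized cut of a bipartition on similarity matrix s."""
    labels = np.asarray(labels, bool)
    deg = s.sum(axis=1)
    cut = s[labels][:, ~labels].sum()
    return cut / deg[labels].sum() + cut / deg[~labels].sum()


class TestSpectral:
    def test_ideal_block_structure_recovered(self):
        aps = np.vstack([np.zeros((4, 20)), np.ones((4, 20))])
        sim = waveform_similarity(aps)
        labels = spectral_cluster(sim, k=2, seed=0)
        assert relabel_agreement(labels, [0] * 4 + [1] * 4) == 1.0

    def test_matches_brute_force_normalized_cut(self, short_template, long_template):
        """For n = 8 noisy waveforms the spectral partition equals the
        exhaustive minimum-normalized-cut bipartition (127 candidates)."""
        rng = np.random.default_rng(7)
        t = np.arange(0.0, 500.0, 2.0)
        waves = [short_template.evaluate(t) + 0.05 * rng.standard_normal(t.size)
                 for _ in range(4)]
        waves += [long_template.evaluate(t) + 0.05 * rng.standard_normal(t.size)
                  for _ in range(4)]
        aps = np.vstack(waves)
        sim = waveform_similarity(aps)
        labels = spectral_cluster(sim, k=2, seed=0)
        best, best_cut = None, np.inf
        for assignment in itertools.product([0, 1], repeat=8):
            a = np.array(assignment, bool)
            if a.all() or not a.any():
                continue
            cut = normalized_cut(sim.values, a)
            if cut < best_cut:
                best, best_cut = a, cut
        assert relabel_agreement(labels, best) == 1.0

    def test_invariant_to_waveform_ordering(self):
        rng = np.random.default_rng(9)
        aps = np.vstack([rng.normal(0, 0.05, (6, 30)),
                         rng.normal(1, 0.05, (6, 30))])
        sim = waveform_similarity(aps)
        base = spectral_cluster(sim, k=2, seed=0)
        perm = rng.permutation(12)
        sim_p = waveform_similarity(aps[perm])
        permuted = spectral_cluster(sim_p, k=2, seed=0)
        assert relabel_agreement(permuted, base[perm]) == 1.0

    def test_reproducible_for_fixed_seed(self, pooled_population):
        sim = waveform_similarity(pooled_population["aps"][:300])
        l1 = spectral_cluster(sim, k=3, seed=5)
        l2 = spectral_cluster(sim, k=3, seed=5)
        np.testing.assert_array_equal(l1, l2)

    def test_bad_k_rejected(self):
        sim = waveform_similarity(np.random.default_rng(0).standard_normal((5, 10)))
        with pytest.raises(ValueError):
            spectral_cluster(sim, k=1)
        with pytest.raises(ValueError):
            spectral_cluster(sim, k=5)


class TestDaviesBouldin:
    def test_singleton_groups_have_zero_index(self):
        aps = np.vstack([np.zeros(10), np.ones(10)])
        assert davies_bouldin(aps, np.array([0, 1])) == 0.0

    def test_matches_direct_formula_on_six_waveforms(self):
        rng = np.random.default_rng(11)
        aps = np.vstack([rng.normal(0, 0.3, (3, 8)), rng.normal(2, 0.3, (3, 8))])
        labels = np.array([0, 0, 0, 1, 1, 1])
        # independent direct evaluation of the definition
        scatters, centers = [], []
        for g in (0, 1):
            member = aps[labels == g]
            center = member.mean(axis=0)
            centers.append(center)
            scatters.append(np.mean([np.sqrt(((w - center) ** 2).sum()) for w in member]))
        d01 = np.sqrt(((centers[0] - centers[1]) ** 2).sum())
        expected = 0.5 * ((scatters[0] + scatters[1]) / d01 +
                          (scatters[1] + scatters[0]) / d01)
        assert davies_bouldin(aps, labels) == pytest.approx(expected, abs=1e-12)

    def test_agrees_with_sklearn(self):
        from sklearn.metrics import davies_bouldin_score

        rng = np.random.default_rng(13)
        aps = rng.standard_normal((30, 12))
        labels = rng.integers(0, 3, 30)
        assert davies_bouldin(aps, labels) == pytest.approx(
            davies_bouldin_score(aps, labels), abs=1e-9)

    def test_planted_labels_beat_random_relabelings(self, pooled_population):
        aps = pooled_population["aps"][::8]
        labels = pooled_population["true_labels"][::8]
        planted = davies_bouldin(aps, labels)
        rng = np.random.default_rng(17)
        for _ in range(100):
            perm = rng.permutation(labels)
            if np.unique(perm).size < 2:
                continue
            assert davies_bouldin(aps, perm) > planted

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            davies_bouldin(np.zeros((4, 5)), np.zeros(4))


class TestSVMOverlap:
    def test_separable_clouds_have_zero_overlap(self):
        rng = np.random.default_rng(19)
        a = rng.normal([0, 0], 0.1, (50, 2))
        b = rng.normal([5, 5], 0.1, (50, 2))
        bo = svm_overlap(np.vstack([a, b]), np.array([0] * 50 + [1] * 50))
        assert bo.overlap_percent == 0.0

    def test_label_swap_gives_identical_boundary_and_overlap(self):
        rng = np.random.default_rng(23)
        x = np.vstack([rng.normal(0, 1, (80, 2)), rng.normal(2, 1, (80, 2))])
        y = np.array([0] * 80 + [1] * 80)
        b1 = svm_overlap(x, y)
        b2 = svm_overlap(x, 1 - y)
        line1 = b1.boundary / np.linalg.norm(b1.boundary[:2])
        line2 = b2.boundary / np.linalg.norm(b2.boundary[:2])
        np.testing.assert_allclose(np.abs(line1), np.abs(line2), atol=1e-5)
        assert b2.overlap_percent == pytest.approx(b1.overlap_percent, abs=1e-9)

    def test_overlap_matches_analytic_normal_tail(self):
        """Two isotropic Gaussian clouds two sigmas apart: the midline
        misclassifies Phi(-1) = 15.87% of points."""
        rng = np.random.default_rng(29)
        sigma, d, n = 1.0, 2.0, 5000
        a = rng.normal([0, 0], sigma, (n, 2))
        b = rng.normal([d, 0], sigma, (n, 2))
        bo = svm_overlap(np.vstack([a, b]), np.array([0] * n + [1] * n))
        analytic = 100.0 * stats.norm.cdf(-d / (2 * sigma))
        assert bo.overlap_percent == pytest.approx(analytic, abs=1.0)

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            svm_overlap(np.zeros((10, 2)), np.zeros(10))


class TestLevene:
    def test_identical_groups_give_zero_statistic(self):
        a = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        w, p = levene_equal_variance(a, a.copy())
        assert w == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0, abs=1e-12)

    def test_matches_hand_formula(self):
        a = np.array([1.0, 4.0, 6.0, 3.0])
        b = np.array([10.0, 30.0, 20.0, 15.0, 25.0])
        w, p = levene_equal_variance(a, b)
        za = np.abs(a - a.mean())
        zb = np.abs(b - b.mean())
        n1, n2 = za.size, zb.size
        zbar = np.concatenate([za, zb]).mean()
        num = (n1 * (za.mean() - zbar) ** 2 + n2 * (zb.mean() - zbar) ** 2) / (2 - 1)
        den = (((za - za.mean()) ** 2).sum() + ((zb - zb.mean()) ** 2).sum()) / (n1 + n2 - 2)
        w_hand = num / den
        assert w == pytest.approx(w_hand, abs=1e-12)
        assert p == pytest.approx(1.0 - stats.f.cdf(w_hand, 1, n1 + n2 - 2), abs=1e-12)

    def test_detects_threefold_sd_ratio(self):
        """Power check: sd ratio 3 at n = 50 per group is detected at
        p < 0.05 in at least 95 of 100 seeded replicates."""
        hits = 0
        for seed in range(100):
            rng = np.random.default_rng(1000 + seed)
            _, p = levene_equal_variance(rng.normal(0, 1, 50), rng.normal(0, 3, 50))
            hits += p < 0.05
        assert hits >= 95

    def test_degenerate_groups_rejected(self):
        with pytest.raises(ValueError):
            levene_equal_variance(np.full(5, 2.0), np.full(5, 2.0))


class TestGroupPopulation:
    def test_strategies_agree_when_apd80_determines_shape(
        self, short_template, long_template
    ):
        """On an idealized population — two phenotypes far apart in APD80,
        shape fully determined by APD80, no spatial mixing — all three
        strategies find the same two groups."""
        from cardiowave.metrics import apd_from_waveform

        rng = np.random.default_rng(31)
        t = np.arange(0.0, 600.0, 2.0)
        waves, a30s, a80s = [], [], []
        for tp in (short_template, long_template):
            clean = tp.evaluate(t)
            for _ in range(100):
                w = clean + 0.02 * rng.standard_normal(t.size)
                waves.append(w)
                j = int(np.argmax(np.diff(clean)))
                a30s.append(apd_from_waveform(clean, 2.0, j + 0.5, 0.30, baseline=0.0))
                a80s.append(apd_from_waveform(clean, 2.0, j + 0.5, 0.80, baseline=0.0))
        aps = np.vstack(waves)
        jitter = rng.normal(0, 1.0, len(a30s))  # avoid exactly-equal values
        results = group_population(aps, np.array(a30s) + jitter,
                                   np.array(a80s) + jitter, k=2, seed=0)
        assert set(results) == {"apd80_threshold", "pca_threshold", "waveform_spectral"}
        lab = {m: r.labels for m, r in results.items()}
        assert relabel_agreement(lab["apd80_threshold"], lab["waveform_spectral"]) == 1.0
        assert relabel_agreement(lab["pca_threshold"], lab["waveform_spectral"]) == 1.0
        for r in results.values():
            assert r.dbi >= 0
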