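"""Tests of the divisive peeling algorithm and its model-selection rule."""

import numpy as np
import pytest

from dragonclust.dragon import (
    DragonConfig,
    dragon_fit,
    estimate_c,
    extract_cluster,
    normalize_dlt,
    refine_cluster,
    total_likelihood,
    two_means_split_1d,
)
from dragonclust.evaluation import matched_accuracy
from dragonclust.mlcore import InvalidInputError, fit_gaussian
from dragonclust.synthdata import SyntheticSpec, cluster_centers, make_gaussian_mixture
from .conftest import brute_best_removal, refit_loglik


def two_blobs(rng, n=60, sep=10.0, d=2):
    X = np.vstack([
        rng.standard_normal((n // 2, d)),
        np.r_[sep, np.zeros(d - 1)] + rng.standard_normal((n // 2, d)),
    ])
    y = np.repeat([0, 1], n // 2)
    return X, y


class TestExtractCluster:
    def test_far_point_removed_first(self, rng):
        X = np.vstack([0.2 * rng.standard_normal((30, 2)), [[50.0, 0.0]]])
        _, trace = extract_cluster(X, range(31), DragonConfig(n_clusters=1))
        assert trace.steps[0].removed_index == 30

    def test_trace_strictly_increasing_and_stop_certified(self, rng):
        X, _ = two_blobs(rng)
        state, trace = extract_cluster(X, range(60), DragonConfig(n_clusters=2))
        lls = [trace.initial_loglik] + [s.loglik_after for s in trace.steps]
        assert all(b > a for a, b in zip(lls, lls[1:]))
        assert trace.final_loglik == lls[-1]
        if trace.stop_reason == "converged":
            # the rejected next removal would not have increased L
            assert not trace.stop_candidate.delta_loglik < 0
        else:
            assert state.n == DragonConfig().resolved_min_size(X.shape[1])

    def test_greedy_path_matches_bruteforce_refits(self, rng):
        """Every removal agrees with exhaustive from-scratch refitting."""
        X, _ = two_blobs(rng, n=40)
        state, trace = extract_cluster(X, range(40), DragonConfig(n_clusters=2))
        members = list(range(40))
        for step in trace.steps:
            assert step.removed_index == brute_best_removal(X, members)
            members.remove(step.removed_index)
            assert refit_loglik(X, members) == pytest.approx(
                step.loglik_after, rel=1e-8)

    def test_rejects_small_active_set(self, rng):
        X = rng.standard_normal((4, 2))
        with pytest.raises(InvalidInputError):
            extract_cluster(X, range(4), DragonConfig(n_clusters=1))

    def test_removed_and_kept_partition_the_active_set(self, rng):
        X, _ = two_blobs(rng)
        state, trace = extract_cluster(X, range(60), DragonConfig(n_clusters=2))
        removed = {s.removed_index for s in trace.steps}
        assert removed | set(state.member_indices) == set(range(60))
        assert removed.isdisjoint(state.member_indices)


class TestTwoMeansSplit:
    def test_perfectly_separated_values(self):
        vals = np.array([1.0, 1.1, 0.9, 10.0, 10.2, 9.8])
        mask = two_means_split_1d(vals)
        np.testing.assert_array_equal(mask, [True, True, True, False, False, False])

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_exhaustive_split_oracle(self, seed):
        rng = np.random.default_rng(seed)
        vals = rng.uniform(0, 10, size=rng.integers(4, 40))
        mask = two_means_split_1d(vals)

        def wcss(groups):
            return sum(((g - g.mean()) ** 2).sum() for g in groups if g.size)

        s = np.sort(vals)
        best = min(wcss([s[:k], s[k:]]) for k in range(1, len(s)))
        got = wcss([vals[mask], vals[~mask]])
        assert got == pytest.approx(best, abs=1e-9)
        assert vals[mask].mean() < vals[~mask].mean()

    def test_identical_values_no_split(self):
        assert two_means_split_1d(np.full(5, 3.0)).all()


class TestRefineCluster:
    def test_recovers_inner_group(self, rng):
        X, y = two_blobs(rng, n=80)
        mu0 = X[y == 0].mean(axis=0)
        refined = refine_cluster(X, range(80), mu0)
        assert set(refined) == set(np.flatnonzero(y == 0))

    def test_fixed_point_on_clean_data(self, rng):
        X, y = two_blobs(rng, n=80)
        cfg2 = DragonConfig(refine_iters=2)
        cfg3 = DragonConfig(refine_iters=3)
        mu = X[y == 1].mean(axis=0)
        chi = refine_cluster(X, range(80), mu)
        for cfg in (cfg2, cfg3):
            cur, m = None, mu
            cur = np.arange(80)
            for _ in range(cfg.refine_iters):
                cur = refine_cluster(X, range(80), m)
                m = X[cur].mean(axis=0)
            assert set(cur) == set(chi)

    def test_identical_distances_returns_active(self):
        # all points on a circle around the centroid
        ang = np.linspace(0, 2 * np.pi, 8, endpoint=False)
        X = np.c_[np.cos(ang), np.sin(ang)]
        refined = refine_cluster(X, range(8), [0.0, 0.0])
        assert set(refined) == set(range(8))


class TestDragonFit:
    def test_single_cluster_degenerate(self, rng):
        X = rng.standard_normal((30, 3))
        res = dragon_fit(X, DragonConfig(n_clusters=1))
        assert set(res.labels) == {0}
        assert res.total_loglik == pytest.approx(fit_gaussian(X, range(30)).loglik)

    def test_peeling_conservation_and_label_contiguity(self):
        X, _ = make_gaussian_mixture(SyntheticSpec(d=3, seed=1))
        res = dragon_fit(X, DragonConfig(n_clusters=4))
        assert res.labels.shape == (400,)
        assert set(res.labels) == {0, 1, 2, 3}
        assert total_likelihood(res) == pytest.approx(res.total_loglik, abs=1e-9)
        for k in range(4):
            members = np.flatnonzero(res.labels == k)
            assert res.cluster_logliks[k] == pytest.approx(
                refit_loglik(X, members), abs=1e-8)

    def test_recovery_on_density_ordered_mixture(self):
        """With a density ordering the extraction homes in on the densest
        cluster first and recovery is near-perfect; this is the regime the
        method is designed for (it tracks the highest-density cluster)."""
        accs = []
        for seed in range(5):
            rng = np.random.default_rng(seed)
            centers = cluster_centers(SyntheticSpec(d=10, separation=8.0, seed=seed))
            sds = (0.5, 0.8, 1.1, 1.4)
            X = np.vstack([centers[k] + sds[k] * rng.standard_normal((100, 10))
                           for k in range(4)])
            y = np.repeat(np.arange(4), 100)
            res = dragon_fit(X, DragonConfig(n_clusters=4))
            accs.append(matched_accuracy(y, res.labels).matched_accuracy)
        assert np.mean(accs) >= 0.9

    def test_search_count_law(self):
        """Candidate evaluations per extraction follow (1/2)(n-n1)(n+n1+1)."""
        X, _ = make_gaussian_mixture(SyntheticSpec(d=2, seed=3))
        res = dragon_fit(X, DragonConfig(n_clusters=4))
        sizes = np.bincount(res.labels)
        active_n = 400
        for k, trace in enumerate(res.traces):
            n1 = active_n - len(trace.steps)
            assert trace.n_evaluations == (active_n - n1) * (active_n + n1 + 1) // 2
            # the peeled cluster (post-refinement) shrinks the active set
            active_n -= sizes[k]

    def test_determinism(self):
        X, _ = make_gaussian_mixture(SyntheticSpec(d=4, seed=7))
        a = dragon_fit(X, DragonConfig(n_clusters=3))
        b = dragon_fit(X, DragonConfig(n_clusters=3))
        np.testing.assert_array_equal(a.labels, b.labels)
        assert a.total_loglik == b.total_loglik

    def test_infeasible_cluster_count(self, rng):
        X = rng.standard_normal((12, 2))
        with pytest.raises(InvalidInputError, match="achievable|cannot form"):
            dragon_fit(X, DragonConfig(n_clusters=5))

    def test_elbow_property_of_likelihood(self):
        """Splitting a true cluster gains far less total likelihood than
        un-merging two true clusters: the elbow the c-estimate exploits."""
        X, y = make_gaussian_mixture(SyntheticSpec(d=3, seed=2))

        def lt(labels):
            return sum(refit_loglik(X, np.flatnonzero(labels == k))
                       for k in np.unique(labels))

        merged = y.copy()
        merged[merged == 3] = 2          # c = 3: two true clusters merged
        split = y.copy()
        half = np.flatnonzero(y == 0)[:50]
        split[half] = 4                  # c = 5: one true cluster split
        gain_unmerge = lt(y) - lt(merged)
        gain_split = lt(split) - lt(y)
        assert gain_unmerge > gain_split


class TestEstimateC:
    def test_normalisation_arithmetic_on_constructed_gains(self):
        dlt = np.array([100.0, 80.0, 2.0, 1.0, 0.5])
        norm = normalize_dlt(dlt)
        np.testing.assert_allclose(
            norm, (dlt - 0.5) / 99.5, atol=1e-12)
        assert norm.min() == 0.0 and norm.max() == 1.0
        # smallest k with normalised gain below tau = 0.10 is k = 3
        assert int(np.flatnonzero(norm < 0.10)[0]) + 1 == 3

    def test_curve_contract(self):
        X, _ = make_gaussian_mixture(SyntheticSpec(d=2, seed=5))
        curve = estimate_c(X, DragonConfig(max_clusters=5))
        assert curve.total_logliks.shape[0] == curve.c_values.shape[0]
        assert curve.dlt_norm.min() == 0.0 and curve.dlt_norm.max() == 1.0
        assert 1 <= curve.chosen_c <= curve.c_values[-1]

    def test_truncates_infeasible_c(self, rng):
        X = rng.standard_normal((30, 2)) * 0.5
        X[15:] += 20.0
        curve = estimate_c(X, DragonConfig(max_clusters=8))
        assert curve.c_values[-1] < 8
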