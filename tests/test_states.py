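"""k-medians clustering and the fitted state repertoire."""

import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from dfcstates import (
    compute_le_series,
    elbow_curve,
    fit_state_model,
    kmedians,
    leading_eigenvector,
    make_state_phase_patterns,
    relabel_states,
    simulate_run,
    state_mean_dfc,
    trimmed_phases,
)


def partitions_upto_k(m: int, k: int):
    """All set partitions of range(m) into at most k blocks (restricted
    growth strings) — the exhaustive clustering oracle."""

    def rec(i, labels, n_used):
        if i == m:
            yield tuple(labels)
            return
        for lab in range(min(n_used + 1, k)):
            labels.append(lab)
            yield from rec(i + 1, labels, max(n_used, lab + 1))
            labels.pop()

    yield from rec(0, [], 0)


def exhaustive_optimum(points: np.ndarray, k: int) -> float:
    best = np.inf
    for labels in partitions_upto_k(points.shape[0], k):
        labels = np.asarray(labels)
        cost = 0.0
        for j in np.unique(labels):
            block = points[labels == j]
            cost += np.abs(block - np.median(block, axis=0)).sum()
        best = min(best, cost)
    return best


class TestKmedians:
    def test_k1_closed_form(self, rng):
        pts = rng.normal(size=(15, 4))
        labels, medians, cost = kmedians(pts, 1, n_restarts=3, seed=0)
        assert np.all(labels == 0)
        expected = np.abs(pts - np.median(pts, axis=0)).sum()
        assert cost == pytest.approx(expected, abs=1e-9)

    def test_recovers_widely_separated_clusters(self, rng):
        a = rng.normal(0.0, 0.1, size=(20, 4))
        b = rng.normal(5.0, 0.1, size=(20, 4))
        pts = np.vstack([a, b])
        labels, _, cost = kmedians(pts, 2, n_restarts=10, seed=1)
        truth = np.repeat([0, 1], 20)
        assert adjusted_rand_score(truth, labels) == 1.0

    def test_small_instance_matches_exhaustive_optimum(self, rng):
        pts = rng.normal(size=(10, 3))
        _, _, cost = kmedians(pts, 2, n_restarts=40, seed=2)
        assert cost == pytest.approx(exhaustive_optimum(pts, 2), abs=1e-9)

    def test_best_of_restarts_contract(self, rng):
        pts = rng.normal(size=(30, 3))
        _, _, best_cost = kmedians(pts, 3, n_restarts=15, seed=3)
        singles = [
            kmedians(pts, 3, n_restarts=1, seed=s)[2] for s in range(10)
        ]
        assert all(best_cost <= c + 1e-9 for c in singles)

    def test_fewer_points_than_k_rejected(self, rng):
        with pytest.raises(ValueError, match="at least k"):
            kmedians(rng.normal(size=(2, 3)), 5)

    def test_duplicate_points_empty_cluster_rule(self):
        pts = np.repeat(np.array([[0.0, 0.0], [1.0, 1.0]]), 5, axis=0)
        labels, medians, cost = kmedians(pts, 3, n_restarts=5, seed=4)
        assert labels.shape == (10,)
        assert np.isfinite(cost)

    def test_seed_reproducibility(self, rng):
        pts = rng.normal(size=(40, 5))
        out1 = kmedians(pts, 3, n_restarts=5, seed=7)
        out2 = kmedians(pts, 3, n_restarts=5, seed=7)
        assert np.array_equal(out1[0], out2[0])
        assert np.array_equal(out1[1], out2[1])


class TestElbow:
    def test_cost_zero_when_one_point_per_cluster(self, rng):
        pts = rng.normal(size=(6, 3))
        diag = elbow_curve([pts], [6], n_restarts=20, seed=0)
        assert diag.costs[0] == pytest.approx(0.0, abs=1e-9)

    def test_returns_costs_in_input_order_and_monotone(self, rng):
        pts = rng.normal(size=(40, 3))
        ks = [2, 3, 4, 5, 6]
        diag = elbow_curve([pts], ks, n_restarts=20, seed=1)
        assert diag.k_values == ks
        assert len(diag.costs) == 5
        assert all(a >= b - 1e-6 for a, b in zip(diag.costs, diag.costs[1:]))

    def test_elbow_at_true_k(self, rng):
        """Cost drops sharply up to the planted k and flattens after it."""
        centers = np.array([[0, 0], [8, 0], [0, 8]], dtype=float)
        pts = np.vstack(
            [c + rng.normal(0, 0.2, size=(15, 2)) for c in centers]
        )
        diag = elbow_curve([pts], [1, 2, 3, 4, 5], n_restarts=20, seed=2)
        drops = -np.diff(diag.costs)
        assert min(drops[0], drops[1]) > 10 * max(drops[2], drops[3])


def _noiseless_cohort(k=3, n_regions=14, n_runs=9, T=200, seed=5):
    """Single-state noiseless runs (identity chain), states balanced."""
    patterns = make_state_phase_patterns(
        k, n_regions, [0.0] + [0.25] * (k - 1), seed=seed
    )
    series, labels, thetas = [], [], []
    rng = np.random.default_rng(seed)
    for r in range(n_runs):
        ts, lab = simulate_run(
            patterns, np.eye(k), T, 0.1, 0.0, seed=rng
        )
        series.append(compute_le_series(ts).vectors)
        thetas.append(trimmed_phases(ts))
        labels.append(lab[1:-1])
    return patterns, series, labels, thetas


class TestStateModel:
    def test_region_mismatch_rejected(self, rng):
        with pytest.raises(ValueError, match="region count mismatch"):
            fit_state_model([rng.normal(size=(5, 3)), rng.normal(size=(5, 4))], 2)

    def test_noiseless_cohort_recovers_planted_partition(self):
        patterns, series, labels, _ = _noiseless_cohort()
        model = fit_state_model(series, 3, n_restarts=10, seed=0)
        ari = adjusted_rand_score(
            np.concatenate(labels), np.concatenate(model.labels)
        )
        assert ari == 1.0

    def test_noiseless_medians_equal_planted_le(self):
        patterns, series, labels, _ = _noiseless_cohort()
        model = fit_state_model(series, 3, n_restarts=10, seed=0)
        planted = np.stack(
            [leading_eigenvector(p.coherence_matrix())[0] for p in patterns]
        )
        # match each median to its closest planted pattern
        for med in model.medians:
            dists = np.abs(planted - med).sum(axis=1)
            assert dists.min() < 1e-6

    def test_mean_dfc_equals_planted_pattern(self):
        patterns, series, labels, thetas = _noiseless_cohort()
        mean_dfc = state_mean_dfc(thetas, labels, 3)
        for j, pattern in enumerate(patterns):
            assert np.allclose(
                mean_dfc[j], pattern.coherence_matrix(), atol=1e-6
            )


class TestRelabel:
    @pytest.fixture()
    def model(self):
        _, series, _, _ = _noiseless_cohort(n_runs=6)
        return fit_state_model(series, 3, n_restarts=10, seed=1)

    def test_identity_permutation_is_noop(self, model):
        out = relabel_states(model, [1, 2, 3])
        assert np.array_equal(out.medians, model.medians)
        for a, b in zip(out.labels, model.labels):
            assert np.array_equal(a, b)

    def test_default_rule_puts_most_frequent_state_first(self, model):
        out = relabel_states(model)
        counts = out.occurrence_counts()
        assert np.all(counts[:-1] >= counts[1:])
        assert out.total_cost == model.total_cost

    def test_double_application_composes(self, model):
        once = relabel_states(model, [2, 3, 1])
        twice = relabel_states(once, [2, 3, 1])
        composed = relabel_states(model, [3, 1, 2])
        assert np.array_equal(twice.medians, composed.medians)

    def test_non_permutation_rejected(self, model):
        with pytest.raises(ValueError, match="permutation"):
            relabel_states(model, [1, 1, 2])
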