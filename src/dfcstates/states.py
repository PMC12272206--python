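"""Recurring-state repertoire via k-medians clustering of LE(t) vectors.

Eigenvectors pooled over every run and subject are clustered with
Manhattan (L1) distance; each cluster is a "state" summarized by the
coordinate-wise median of its member eigenvectors (the LE state) and,
on demand, by the average of the member coherence matrices (the dFC
state).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .phase import phase_coherence_at

_CHUNK = 8192  # row block for distance computation; bounds peak memory


@dataclass
class StateModel:
    """Fitted repertoire of k recurring states.

    ``medians`` holds the k LE states (coordinate-wise medians);
    ``labels`` maps every pooled timepoint back to its run, keyed in the
    order the runs were supplied; ``total_cost`` is the summed Manhattan
    distance of pooled points to their state median.
    """

    k: int
    medians: np.ndarray
    total_cost: float
    labels: list[np.ndarray]
    mean_dfc: np.ndarray | None = None

    def occurrence_counts(self) -> np.ndarray:
        """Pooled timepoint count per state (1..k)."""
        counts = np.zeros(self.k, dtype=int)
        for lab in self.labels:
            counts += np.bincount(lab - 1, minlength=self.k)
        return counts


@dataclass(frozen=True)
class ElbowDiagnostics:
    k_values: list[int]
    costs: list[float]


def _l1_to_medians(points: np.ndarray, medians: np.ndarray) -> np.ndarray:
    """M x k matrix of Manhattan distances, computed in row blocks."""
    out = np.empty((points.shape[0], medians.shape[0]))
    for start in range(0, points.shape[0], _CHUNK):
        block = points[start : start + _CHUNK]
        out[start : start + _CHUNK] = np.abs(
            block[:, None, :] - medians[None, :, :]
        ).sum(axis=2)
    return out


def _lower_median(points: np.ndarray) -> np.ndarray:
    """Coordinate-wise lower median: for even counts, the lower of the
    two middle order statistics (keeps medians on the data lattice)."""
    m = points.shape[0]
    return np.sort(points, axis=0)[(m - 1) // 2]


def _seed_medians(points: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """k-means++-style seeding under L1: each new seed is drawn with
    probability proportional to its distance from the chosen set."""
    m = points.shape[0]
    centers = np.empty((k, points.shape[1]))
    centers[0] = points[rng.integers(m)]
    d = np.abs(points - centers[0]).sum(axis=1)
    for j in range(1, k):
        total = d.sum()
        if total <= 0:  # all points coincide with chosen seeds
            centers[j] = points[rng.integers(m)]
            continue
        centers[j] = points[rng.choice(m, p=d / total)]
        d = np.minimum(d, np.abs(points - centers[j]).sum(axis=1))
    return centers


def _random_partition_medians(
    points: np.ndarray, k: int, rng: np.random.Generator
) -> np.ndarray:
    """Medians of a uniform random partition with k nonempty blocks."""
    m = points.shape[0]
    labels = rng.integers(k, size=m)
    labels[rng.choice(m, size=k, replace=False)] = np.arange(k)
    return np.stack([_lower_median(points[labels == j]) for j in range(k)])


def _kmedians_once(
    points: np.ndarray,
    k: int,
    max_iter: int,
    rng: np.random.Generator,
    init: str = "kpp",
) -> tuple[np.ndarray, np.ndarray, float]:
    if init == "kpp":
        medians = _seed_medians(points, k, rng)
    else:
        medians = _random_partition_medians(points, k, rng)
    labels = np.full(points.shape[0], -1)
    for _ in range(max_iter):
        dists = _l1_to_medians(points, medians)
        new_labels = dists.argmin(axis=1)
        # empty-cluster rule: reseed with the point farthest (L1) from
        # its currently assigned median; each reseed claims its point so
        # two empty clusters never fight over the same one
        claimed: list[int] = []
        for j in range(k):
            if not np.any(new_labels == j):
                assigned = dists[np.arange(points.shape[0]), new_labels].copy()
                if claimed:
                    assigned[claimed] = -np.inf
                # never steal the sole member of another cluster
                sizes = np.bincount(new_labels, minlength=k)
                assigned[sizes[new_labels] <= 1] = -np.inf
                far = int(assigned.argmax())
                medians[j] = points[far]
                new_labels[far] = j
                claimed.append(far)
        if np.array_equal(new_labels, labels):
            break
        labels = new_labels
        for j in range(k):
            medians[j] = _lower_median(points[labels == j])
    cost = float(
        _l1_to_medians(points, medians)[np.arange(points.shape[0]), labels].sum()
    )
    return labels, medians, cost


def _block_cost(block: np.ndarray) -> float:
    if block.shape[0] == 0:
        return 0.0
    return float(np.abs(block - _lower_median(block)).sum())


def _refine_moves(
    points: np.ndarray, labels: np.ndarray, k: int, max_sweeps: int = 50
) -> np.ndarray:
    """First-improvement single-point moves with exact median updates.

    Alternating assignment only reaches Voronoi-consistent fixpoints;
    re-optimizing the block medians after a candidate move escapes
    fixpoints that a joint move-and-update step can still improve.
    Quadratic in the block sizes, so intended for small problems.
    """
    labels = labels.copy()
    costs = np.array(
        [_block_cost(points[labels == j]) for j in range(k)]
    )
    for _ in range(max_sweeps):
        improved = False
        for i in range(points.shape[0]):
            a = labels[i]
            if np.sum(labels == a) == 1:
                continue  # moving would empty the block
            rest_a = _block_cost(points[(labels == a) & (np.arange(len(labels)) != i)])
            for b in range(k):
                if b == a:
                    continue
                with_i = _block_cost(
                    np.vstack([points[labels == b], points[i]])
                )
                delta = (rest_a + with_i) - (costs[a] + costs[b])
                if delta < -1e-12:
                    labels[i] = b
                    costs[a] = rest_a
                    costs[b] = with_i
                    improved = True
                    break
        if not improved:
            break
    return labels


def kmedians(
    points: np.ndarray,
    k: int,
    n_restarts: int = 500,
    max_iter: int = 200,
    seed: int | np.random.SeedSequence | None = None,
    refine: bool | None = None,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Best-of-restarts k-medians with Manhattan distance.

    Alternates nearest-median (L1) assignment with coordinate-wise
    (lower-)median updates until the labelling is a fixpoint or
    ``max_iter`` is reached; the restart with the lowest total cost
    wins.  ``refine`` polishes each restart's fixpoint with exact
    single-point moves (defaults to on for M <= 500, where the extra
    cost is negligible).  Deterministic given ``seed``.

    Returns ``(labels, medians, cost)`` with labels in 0..k-1.
    """
    points = np.asarray(points, dtype=float)
    if points.ndim != 2:
        raise ValueError("points must be an M x N matrix")
    if points.shape[0] < k:
        raise ValueError(f"need at least k={k} points, got {points.shape[0]}")
    if n_restarts < 1:
        raise ValueError("n_restarts must be >= 1")
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    best: tuple[np.ndarray, np.ndarray, float] | None = None
    # alternate distance-weighted seeding with uniform random partitions:
    # the former converges fast on separated data, the latter reaches
    # interleaved optima the greedy seeds systematically miss
    if refine is None:
        refine = points.shape[0] <= 500
    for i, child in enumerate(ss.spawn(n_restarts)):
        rng = np.random.default_rng(child)
        init = "kpp" if i % 2 == 0 else "partition"
        labels, medians, cost = _kmedians_once(points, k, max_iter, rng, init)
        if refine:
            labels = _refine_moves(points, labels, k)
            medians = np.stack(
                [_lower_median(points[labels == j]) for j in range(k)]
            )
            cost = float(
                sum(_block_cost(points[labels == j]) for j in range(k))
            )
        if best is None or cost < best[2]:
            best = (labels, medians, cost)
    assert best is not None
    return best


def fit_state_model(
    le_series: list[np.ndarray],
    k: int,
    n_restarts: int = 500,
    max_iter: int = 200,
    seed: int | np.random.SeedSequence | None = None,
) -> StateModel:
    """Cluster pooled eigenvectors from all runs into k states.

    Clustering is done once at cohort level on the concatenation of all
    runs' LE(t) rows; labels (1..k) are mapped back to runs in input
    order.
    """
    arrays = [np.asarray(a, dtype=float) for a in le_series]
    if not arrays:
        raise ValueError("no eigenvector series supplied")
    n_regions = arrays[0].shape[1]
    for i, a in enumerate(arrays):
        if a.ndim != 2 or a.shape[1] != n_regions:
            raise ValueError(f"run {i}: region count mismatch ({a.shape})")
    pooled = np.concatenate(arrays, axis=0)
    labels, medians, cost = kmedians(pooled, k, n_restarts, max_iter, seed)
    per_run: list[np.ndarray] = []
    offset = 0
    for a in arrays:
        per_run.append(labels[offset : offset + a.shape[0]] + 1)
        offset += a.shape[0]
    return StateModel(k=k, medians=medians, total_cost=cost, labels=per_run)


def state_mean_dfc(
    theta_list: list[np.ndarray], labels_list: list[np.ndarray], k: int
) -> np.ndarray:
    """Average coherence matrix per state ("dFC state" patterns).

    ``theta_list`` holds region x T' phase matrices aligned with the
    label sequences (boundary-trimmed, see ``phase.trimmed_phases``).
    Returns a k x N x N stack; states with no member timepoints are NaN.
    """
    if len(theta_list) != len(labels_list):
        raise ValueError("theta_list and labels_list lengths differ")
    n = theta_list[0].shape[0]
    sums = np.zeros((k, n, n))
    counts = np.zeros(k, dtype=int)
    for theta, labels in zip(theta_list, labels_list):
        if theta.shape[1] != len(labels):
            raise ValueError("phase / label length mismatch")
        for t, lab in enumerate(labels):
            sums[lab - 1] += phase_coherence_at(theta[:, t])
            counts[lab - 1] += 1
    out = np.full_like(sums, np.nan)
    for j in range(k):
        if counts[j] > 0:
            out[j] = sums[j] / counts[j]
    return out


def elbow_curve(
    le_series: list[np.ndarray],
    k_range: list[int],
    n_restarts: int = 500,
    max_iter: int = 200,
    seed: int | np.random.SeedSequence | None = None,
) -> ElbowDiagnostics:
    """Within-cluster Manhattan cost across candidate k (elbow heuristic)."""
    pooled = np.concatenate([np.asarray(a, dtype=float) for a in le_series], axis=0)
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    costs = []
    for k, child in zip(k_range, ss.spawn(len(k_range))):
        _, _, cost = kmedians(pooled, k, n_restarts, max_iter, child)
        costs.append(cost)
    return ElbowDiagnostics(k_values=list(k_range), costs=costs)


def relabel_states(model: StateModel, order: list[int] | None = None) -> StateModel:
    """Renumber states; default puts the most frequent state first.

    ``order`` lists the current (1-based) state ids in their new order;
    ``order[0]`` becomes state 1.  Descending pooled occurrence is the
    default rule, so a dominant uniform-coherence state takes label 1.
    """
    if order is None:
        counts = model.occurrence_counts()
        order = [int(s) + 1 for s in np.argsort(-counts, kind="stable")]
    if sorted(order) != list(range(1, model.k + 1)):
        raise ValueError(f"order {order} is not a permutation of 1..{model.k}")
    old_to_new = np.empty(model.k + 1, dtype=int)
    for new_idx, old in enumerate(order, start=1):
        old_to_new[old] = new_idx
    new_labels = [old_to_new[lab] for lab in model.labels]
    idx = np.asarray(order) - 1
    mean_dfc = model.mean_dfc[idx] if model.mean_dfc is not None else None
    return replace(
        model,
        medians=model.medians[idx],
        labels=new_labels,
        mean_dfc=mean_dfc,
    )
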