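"""Per-subject state-reconfiguration metrics.

Three families of metrics summarize how a subject moves through the
state repertoire:

* frequency — per-state occurrence fractions, mean dwell times, the
  total switch count, and the k x k self-inclusive transition
  probability matrix (2k + 1 + k^2 values);
* transition distance — mean Manhattan distance between consecutive
  LE(t) vectors, stratified by the (from, to) state pair (k^2 values);
* idiosyncrasy — mean Manhattan distance between a subject's LE(t) and
  the cohort median of the assigned state (k values).

Metrics undefined in a run (state never visited, switch never observed)
are NaN-masked and excluded from the run average.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata, spearmanr


@dataclass
class ReconfigurationProfile:
    """One subject's (or run's) reconfiguration metrics; NaN = undefined."""

    k: int
    occurrence: np.ndarray  # (k,)
    dwell: np.ndarray  # (k,) timepoints
    transition_number: float
    transition_prob: np.ndarray  # (k, k)
    transition_dist: np.ndarray  # (k, k)
    idiosyncrasy: np.ndarray  # (k,)


@dataclass(frozen=True)
class StrengthVariability:
    """Per-connection temporal mean and SD of coherence, upper triangle."""

    strength: np.ndarray
    variability: np.ndarray
    rank_correlation: float  # NaN when undefined


def _check_labels(labels: np.ndarray, k: int) -> np.ndarray:
    labels = np.asarray(labels)
    if labels.size == 0:
        raise ValueError("empty label sequence")
    if labels.min() < 1 or labels.max() > k:
        raise ValueError(f"labels must lie in 1..{k}")
    return labels


def occurrences(labels: np.ndarray, k: int) -> np.ndarray:
    """Fraction of timepoints assigned to each state; sums to 1."""
    labels = _check_labels(labels, k)
    return np.bincount(labels - 1, minlength=k) / labels.size


def dwell_times(labels: np.ndarray, k: int) -> np.ndarray:
    """Mean uninterrupted-visit length per state, in timepoints.

    Visits truncated by the run boundary count as complete visits.
    States never visited are NaN.
    """
    labels = _check_labels(labels, k)
    run_lengths: list[list[int]] = [[] for _ in range(k)]
    start = 0
    for t in range(1, labels.size + 1):
        if t == labels.size or labels[t] != labels[start]:
            run_lengths[labels[start] - 1].append(t - start)
            start = t
    return np.array(
        [np.mean(r) if r else np.nan for r in run_lengths]
    )


def transition_number(labels: np.ndarray) -> int:
    """Number of consecutive label pairs that differ (state switches)."""
    labels = np.asarray(labels)
    if labels.size < 2:
        raise ValueError("need at least 2 timepoints")
    return int(np.sum(labels[1:] != labels[:-1]))


def transition_probabilities(labels: np.ndarray, k: int) -> np.ndarray:
    """Row-normalized consecutive-pair counts, self-transitions included.

    Entry (a, b) is the proportion of steps leaving state a that land in
    state b (a = b meaning the state is kept).  Rows of states with no
    outgoing step are NaN.
    """
    labels = _check_labels(labels, k)
    if labels.size < 2:
        raise ValueError("need at least 2 timepoints")
    counts = np.zeros((k, k))
    np.add.at(counts, (labels[:-1] - 1, labels[1:] - 1), 1.0)
    totals = counts.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        probs = counts / totals
    probs[totals[:, 0] == 0] = np.nan
    return probs


def transition_distances(
    le_series: np.ndarray, labels: np.ndarray, k: int
) -> np.ndarray:
    """Mean L1 distance between consecutive LE(t), per (from, to) pair.

    Pairs never observed are NaN.
    """
    le_series = np.asarray(le_series, dtype=float)
    labels = _check_labels(labels, k)
    if le_series.shape[0] != labels.size:
        raise ValueError("eigenvector series and labels lengths differ")
    step = np.abs(np.diff(le_series, axis=0)).sum(axis=1)
    sums = np.zeros((k, k))
    counts = np.zeros((k, k))
    np.add.at(sums, (labels[:-1] - 1, labels[1:] - 1), step)
    np.add.at(counts, (labels[:-1] - 1, labels[1:] - 1), 1.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = sums / counts
    out[counts == 0] = np.nan
    return out


def idiosyncrasy(
    le_series: np.ndarray, labels: np.ndarray, group_medians: np.ndarray
) -> np.ndarray:
    """Mean L1 distance of a subject's LE(t) to the group state medians.

    For each state, averages the Manhattan distance between the member
    LE(t) rows and the cohort median LE of that state; unvisited states
    are NaN.
    """
    le_series = np.asarray(le_series, dtype=float)
    group_medians = np.asarray(group_medians, dtype=float)
    k = group_medians.shape[0]
    labels = _check_labels(labels, k)
    if le_series.shape[1] != group_medians.shape[1]:
        raise ValueError("region count mismatch with group medians")
    out = np.full(k, np.nan)
    for j in range(k):
        member = le_series[labels == j + 1]
        if member.size:
            out[j] = np.abs(member - group_medians[j]).sum(axis=1).mean()
    return out


def run_profile(
    le_series: np.ndarray, labels: np.ndarray, group_medians: np.ndarray
) -> ReconfigurationProfile:
    """All reconfiguration metrics for a single run."""
    k = group_medians.shape[0]
    return ReconfigurationProfile(
        k=k,
        occurrence=occurrences(labels, k),
        dwell=dwell_times(labels, k),
        transition_number=float(transition_number(labels)),
        transition_prob=transition_probabilities(labels, k),
        transition_dist=transition_distances(le_series, labels, k),
        idiosyncrasy=idiosyncrasy(le_series, labels, group_medians),
    )


def run_average(profiles: list[ReconfigurationProfile]) -> ReconfigurationProfile:
    """Element-wise mean across runs, ignoring NaN-masked entries.

    A metric undefined in every run stays NaN.
    """
    if not profiles:
        raise ValueError("need at least one run profile")
    k = profiles[0].k
    if any(p.k != k for p in profiles):
        raise ValueError("profiles have inconsistent k")

    def nanmean(stack: list[np.ndarray]) -> np.ndarray:
        arr = np.stack(stack)
        all_nan = np.all(np.isnan(arr), axis=0)
        out = np.full(arr.shape[1:], np.nan)
        with np.errstate(invalid="ignore"):
            out[~all_nan] = np.nanmean(arr[:, ~all_nan], axis=0)
        return out

    return ReconfigurationProfile(
        k=k,
        occurrence=nanmean([p.occurrence for p in profiles]),
        dwell=nanmean([p.dwell for p in profiles]),
        transition_number=float(np.mean([p.transition_number for p in profiles])),
        transition_prob=nanmean([p.transition_prob for p in profiles]),
        transition_dist=nanmean([p.transition_dist for p in profiles]),
        idiosyncrasy=nanmean([p.idiosyncrasy for p in profiles]),
    )


def metric_names(k: int) -> list[str]:
    """Canonical metric ordering; length (2k + 1 + k^2) + k^2 + k."""
    names = [f"occur_{s}" for s in range(1, k + 1)]
    names += [f"dwell_{s}" for s in range(1, k + 1)]
    names += ["transition_number"]
    names += [f"tprob_{a}_{b}" for a in range(1, k + 1) for b in range(1, k + 1)]
    names += [f"tdist_{a}_{b}" for a in range(1, k + 1) for b in range(1, k + 1)]
    names += [f"idio_{s}" for s in range(1, k + 1)]
    return names


def metric_vector(profile: ReconfigurationProfile) -> tuple[np.ndarray, list[str]]:
    """Flatten a run-averaged profile to the canonical metric vector.

    Order: occurrences, dwell times, transition number, transition
    probabilities (row-major), transition distances (row-major),
    idiosyncrasies.  For k = 6 this yields 91 metrics, 49 of them
    frequency metrics.
    """
    vec = np.concatenate(
        [
            profile.occurrence,
            profile.dwell,
            [profile.transition_number],
            profile.transition_prob.ravel(),
            profile.transition_dist.ravel(),
            profile.idiosyncrasy,
        ]
    )
    return vec, metric_names(profile.k)


def fc_strength_variability(coherence_stack: np.ndarray) -> StrengthVariability:
    """Temporal mean (strength) vs SD (variability) per connection.

    ``coherence_stack`` is T x N x N (concatenated coherence matrices).
    Strength and variability are taken over the upper triangle; their
    association is the Spearman rank correlation, NaN when every
    connection has zero variance in either vector.
    """
    stack = np.asarray(coherence_stack, dtype=float)
    if stack.ndim != 3 or stack.shape[0] < 2:
        raise ValueError("expected a T x N x N stack with T >= 2")
    iu = np.triu_indices(stack.shape[1], k=1)
    conn = stack[:, iu[0], iu[1]]  # T x n_connections
    strength = conn.mean(axis=0)
    variability = conn.std(axis=0, ddof=0)
    if (
        np.unique(rankdata(strength)).size < 2
        or np.unique(rankdata(variability)).size < 2
    ):
        rho = float("nan")
    else:
        rho = float(spearmanr(strength, variability).statistic)
    return StrengthVariability(
        strength=strength, variability=variability, rank_correlation=rho
    )
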