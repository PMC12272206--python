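"""Instantaneous phase-coherence structure of multi-region timeseries.

Each region's signal is converted to an analytic signal via the Hilbert
transform; the instantaneous phase angles define, at every timepoint, a
phase-coherence matrix whose (i, j) entry is the cosine of the phase
difference between regions i and j.  That matrix is compressed to its
leading eigenvector LE(t), which splits regions into a coherent majority
(negative sign, by convention) and an anticoherent minority (positive
sign).  The LE(t) series is the input to state clustering.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy.signal import hilbert


@dataclass(frozen=True)
class PhaseSeries:
    """Instantaneous phase angles and amplitudes of a region x time run.

    ``theta[n, t]`` is the phase of region ``n`` at timepoint ``t`` in
    (-pi, pi]; ``amplitude`` is the analytic-signal modulus, retained for
    diagnostics only.
    """

    theta: np.ndarray
    amplitude: np.ndarray

    def __post_init__(self) -> None:
        if self.theta.shape != self.amplitude.shape:
            raise ValueError("theta and amplitude shapes differ")
        if not np.all(np.isfinite(self.theta)):
            raise ValueError("non-finite phase angles")


@dataclass(frozen=True)
class EigenvectorSeries:
    """Sign-normalized leading eigenvectors of the coherence matrices.

    ``vectors`` has one row per retained timepoint (the first and last
    timepoints of the run are dropped as filter-boundary artifacts, so a
    run of T samples yields T - 2 rows).  ``eigenvalue_share[t]`` is the
    fraction of total (absolute) eigenvalue mass carried by the leading
    eigenvalue at that timepoint.
    """

    vectors: np.ndarray
    eigenvalue_share: np.ndarray

    @property
    def n_timepoints(self) -> int:
        return self.vectors.shape[0]

    @property
    def n_regions(self) -> int:
        return self.vectors.shape[1]


def _check_finite(ts: np.ndarray) -> None:
    if not np.all(np.isfinite(ts)):
        bad = np.argwhere(~np.isfinite(np.asarray(ts)))
        r, c = bad[0]
        raise ValueError(
            f"non-finite value at region {r}, timepoint {c} "
            f"({bad.shape[0]} non-finite entries total)"
        )


def demean_rows(ts: np.ndarray) -> np.ndarray:
    """Subtract each region's temporal mean (rows are regions)."""
    ts = np.asarray(ts, dtype=float)
    if ts.ndim != 2 or ts.shape[1] < 2:
        raise ValueError("expected a region x time matrix with >= 2 timepoints")
    _check_finite(ts)
    return ts - ts.mean(axis=1, keepdims=True)


def hilbert_phase(ts: np.ndarray) -> PhaseSeries:
    """Analytic-signal phase and amplitude of each (demeaned) row."""
    ts = np.asarray(ts, dtype=float)
    if ts.ndim != 2 or ts.shape[1] < 8:
        raise ValueError("expected a region x time matrix with >= 8 timepoints")
    _check_finite(ts)
    if np.any(np.all(ts == 0.0, axis=1)):
        row = int(np.where(np.all(ts == 0.0, axis=1))[0][0])
        raise ValueError(f"all-zero row {row}: phase undefined")
    analytic = hilbert(ts, axis=1)
    return PhaseSeries(theta=np.angle(analytic), amplitude=np.abs(analytic))


def phase_coherence_at(theta_t: np.ndarray) -> np.ndarray:
    """Pairwise cosine of phase differences at one timepoint.

    Entry (i, j) is cos(theta_i - theta_j): 1 for identical phases,
    0 for a quarter-cycle (90 deg) offset, -1 for antiphase (180 deg).
    The matrix is symmetric with unit diagonal.
    """
    theta_t = np.asarray(theta_t, dtype=float)
    if theta_t.ndim != 1:
        raise ValueError("expected a 1-D vector of phases")
    if not np.all(np.isfinite(theta_t)):
        raise ValueError("non-finite phase angles")
    c = np.cos(theta_t[:, None] - theta_t[None, :])
    # enforce exact symmetry / unit diagonal against rounding
    c = 0.5 * (c + c.T)
    np.fill_diagonal(c, 1.0)
    return c


def leading_eigenvector(coherence: np.ndarray) -> tuple[np.ndarray, float]:
    """Unit leading eigenvector of a coherence matrix, sign-normalized.

    The eigenvector of the largest eigenvalue is oriented so the coherent
    majority carries negative sign: if strictly more entries are positive
    than negative the vector is negated.  On an exact tie the orientation
    with negative entry-sum is kept; a zero sum keeps the solver's
    orientation.  Returns ``(vector, eigenvalue_share)`` where the share
    is lambda_1 / sum(|lambda|).
    """
    coherence = np.asarray(coherence, dtype=float)
    if coherence.ndim != 2 or coherence.shape[0] != coherence.shape[1]:
        raise ValueError("expected a square matrix")
    eigvals, eigvecs = np.linalg.eigh(coherence)
    v = eigvecs[:, -1]
    share = float(eigvals[-1] / np.sum(np.abs(eigvals)))
    n_pos = int(np.sum(v > 0))
    n_neg = int(np.sum(v < 0))
    if n_pos > n_neg:
        v = -v
    elif n_pos == n_neg and v.sum() > 0:
        v = -v
    return v, share


def compute_le_series(
    ts: np.ndarray,
    *,
    prefilter: Callable[[np.ndarray], np.ndarray] | None = None,
) -> EigenvectorSeries:
    """Full run pipeline: demean, Hilbert phase, per-t coherence, LE(t).

    The first and last timepoints are dropped to exclude boundary
    artifacts of the transform, so a T-sample run yields T - 2 vectors.
    ``prefilter`` is an optional hook applied to the demeaned signals
    (e.g. a bandpass); the default is no filtering.
    """
    ts = np.asarray(ts, dtype=float)
    if ts.ndim != 2 or ts.shape[1] < 10:
        raise ValueError("expected a region x time matrix with >= 10 timepoints")
    x = demean_rows(ts)
    if prefilter is not None:
        x = np.asarray(prefilter(x), dtype=float)
    phases = hilbert_phase(x)
    theta = phases.theta[:, 1:-1]  # trim boundary artifacts
    n_regions, n_t = theta.shape
    vectors = np.empty((n_t, n_regions))
    shares = np.empty(n_t)
    for t in range(n_t):
        c = phase_coherence_at(theta[:, t])
        try:
            vectors[t], shares[t] = leading_eigenvector(c)
        except np.linalg.LinAlgError as err:  # pragma: no cover
            raise np.linalg.LinAlgError(
                f"eigendecomposition failed at timepoint {t}: {err}"
            ) from err
    return EigenvectorSeries(vectors=vectors, eigenvalue_share=shares)


def trimmed_phases(ts: np.ndarray) -> np.ndarray:
    """Phase angles aligned with :func:`compute_le_series` output.

    Convenience for computing per-state mean coherence patterns: returns
    the region x (T - 2) phase matrix whose columns correspond one-to-one
    with the rows of the eigenvector series.
    """
    return hilbert_phase(demean_rows(ts)).theta[:, 1:-1]
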