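"""Shared statistical utilities: ICC, Spearman, Benjamini-Hochberg FDR."""

from __future__ import annotations

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests


def icc_two_session(
    session1: np.ndarray, session2: np.ndarray, form: str = "ICC2"
) -> float:
    """Test-retest ICC between two paired sessions.

    Default is the two-way random-effects, absolute-agreement,
    single-measurement form ICC(2,1); ``form='ICC3'`` gives the two-way
    mixed, consistency form ICC(3,1).  Computed from the two-way ANOVA
    mean squares with n subjects (rows) and k = 2 sessions (columns).
    Returns NaN when between-subject variance is zero.
    """
    s1 = np.asarray(session1, dtype=float)
    s2 = np.asarray(session2, dtype=float)
    if s1.shape != s2.shape or s1.ndim != 1:
        raise ValueError("sessions must be paired 1-D vectors")
    n = s1.size
    if n < 3:
        raise ValueError("need at least 3 subjects")
    data = np.column_stack([s1, s2])
    k = 2
    grand = data.mean()
    row_means = data.mean(axis=1)
    col_means = data.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((data - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    if msr <= 0:
        return float("nan")
    if form == "ICC2":
        denom = msr + (k - 1) * mse + k * (msc - mse) / n
    elif form == "ICC3":
        denom = msr + (k - 1) * mse
    else:
        raise ValueError("form must be 'ICC2' or 'ICC3'")
    if denom == 0:
        return float("nan")
    return float((msr - mse) / denom)


def bh_fdr(
    pvalues: np.ndarray, alpha: float = 0.05
) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up adjusted p-values and rejection mask."""
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("pvalues must be a non-empty 1-D vector")
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, adjusted, *_ = multipletests(p, alpha=alpha, method="fdr_bh")
    return adjusted, reject


def spearman(x: np.ndarray, y: np.ndarray) -> float:
    """Spearman rank correlation (mid-ranks for ties); NaN when a side
    has zero rank variance."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 3:
        raise ValueError("need paired 1-D vectors with n >= 3")
    if np.unique(x).size < 2 or np.unique(y).size < 2:
        return float("nan")
    return float(sps.spearmanr(x, y).statistic)
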