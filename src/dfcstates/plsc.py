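"""Partial Least Squares Correlation with family-aware resampling.

PLSC decomposes the cross-block correlation matrix R = X'Y / (n - 1)
of two z-scored data matrices by SVD, R = U S V'.  Each dimension d
pairs a latent variable on each side (scores X u_d and Y v_d) whose
covariance is the singular value s_d.  Inference respects family
structure: permutation happens only within blocks of mutually unrelated
subjects, and bootstrap / split-half / cross-validation resample whole
families, never splitting relatives across train and test.

Confounds (age, gender) are regressed from every column before
standardization; out-of-sample data always reuse the coefficients,
means and SDs fitted on the training portion to avoid leakage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import spearmanr

_SD_TOL = 1e-12


# ---------------------------------------------------------------------------
# preprocessing


@dataclass
class Preprocessor:
    """Fitted confound-regression + z-scoring parameters (leakage guard)."""

    beta: np.ndarray | None  # (c + 1, m) OLS coefficients incl. intercept
    mean: np.ndarray  # (m,) residual means
    sd: np.ndarray  # (m,) residual SDs (ddof=1)


def _design(
    confounds: np.ndarray | None, n: int, check_rank: bool = True
) -> np.ndarray | None:
    if confounds is None:
        return None
    confounds = np.asarray(confounds, dtype=float)
    if confounds.ndim == 1:
        confounds = confounds[:, None]
    d = np.column_stack([np.ones(n), confounds])
    if check_rank and np.linalg.matrix_rank(d) < d.shape[1]:
        raise ValueError("confound matrix is rank deficient")
    return d


def residualize_and_standardize(
    M: np.ndarray,
    confounds: np.ndarray | None = None,
    params: Preprocessor | None = None,
    column_names: list[str] | None = None,
) -> tuple[np.ndarray, Preprocessor]:
    """OLS-residualize each column on the confounds, then z-score.

    When ``params`` is supplied the stored coefficients, means and SDs
    are applied instead of refitting (use for held-out data).  A column
    whose residual has (near-)zero variance is rejected by name.
    """
    M = np.asarray(M, dtype=float)
    if M.ndim != 2:
        raise ValueError("expected an n x m matrix")
    n, m = M.shape
    if params is not None:
        d = _design(confounds, n)
        resid = M - d @ params.beta if params.beta is not None else M
        return (resid - params.mean) / params.sd, params
    d = _design(confounds, n)
    if d is not None:
        if n <= d.shape[1]:
            raise ValueError("need n > number of confounds + 1")
        beta, *_ = np.linalg.lstsq(d, M, rcond=None)
        resid = M - d @ beta
    else:
        beta = None
        resid = M
    mean = resid.mean(axis=0)
    sd = resid.std(axis=0, ddof=1)
    if np.any(sd <= _SD_TOL):
        j = int(np.where(sd <= _SD_TOL)[0][0])
        name = column_names[j] if column_names else f"column {j}"
        raise ValueError(f"zero-variance residual in {name}")
    params = Preprocessor(beta=beta, mean=mean, sd=sd)
    return (resid - mean) / sd, params


def _lenient_standardize(
    M: np.ndarray, confounds: np.ndarray | None
) -> np.ndarray:
    """Resampling-path preprocessing: zero-variance columns become zeros
    instead of raising (a degenerate bootstrap draw must not abort)."""
    M = np.asarray(M, dtype=float)
    d = _design(confounds, M.shape[0], check_rank=False)
    if d is not None:
        beta, *_ = np.linalg.lstsq(d, M, rcond=None)
        M = M - d @ beta
    sd = M.std(axis=0, ddof=1)
    sd = np.where(sd <= _SD_TOL, 1.0, sd)
    return (M - M.mean(axis=0)) / sd


# ---------------------------------------------------------------------------
# core fit


@dataclass
class PlscResult:
    singular_values: np.ndarray  # (d,)
    x_weights: np.ndarray  # (p, d)
    y_weights: np.ndarray  # (q, d)
    x_scores: np.ndarray  # (n, d)
    y_scores: np.ndarray  # (n, d)
    x_loadings: np.ndarray  # (p, d)
    y_loadings: np.ndarray  # (q, d)
    covariance_explained: np.ndarray  # (d,)
    latent_correlations: np.ndarray  # (d,) Spearman of paired scores

    @property
    def n_dimensions(self) -> int:
        return self.singular_values.size


def _column_correlations(M: np.ndarray, scores: np.ndarray) -> np.ndarray:
    """Pearson correlation of every column of M with every score column."""
    Mc = M - M.mean(axis=0)
    Sc = scores - scores.mean(axis=0)
    sm = Mc.std(axis=0, ddof=1)
    ss = Sc.std(axis=0, ddof=1)
    sm = np.where(sm <= _SD_TOL, np.inf, sm)
    ss = np.where(ss <= _SD_TOL, np.inf, ss)
    return (Mc.T @ Sc) / (M.shape[0] - 1) / np.outer(sm, ss)


def _fix_signs(u: np.ndarray, v: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic orientation: the largest-|u| entry of each x-weight
    column is positive; v flips with u so scores stay paired."""
    u = u.copy()
    v = v.copy()
    for d in range(u.shape[1]):
        j = int(np.argmax(np.abs(u[:, d])))
        if u[j, d] < 0:
            u[:, d] = -u[:, d]
            v[:, d] = -v[:, d]
    return u, v


def cross_block_matrix(X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """R = X'Y / (n - 1); the cross-correlation matrix for z-scored data."""
    if X.shape[0] != Y.shape[0]:
        raise ValueError("X and Y row counts differ")
    return X.T @ Y / (X.shape[0] - 1)


def plsc_fit(
    X: np.ndarray, Y: np.ndarray, sv_convention: str = "squared"
) -> PlscResult:
    """SVD of the cross-block matrix of two preprocessed matrices.

    ``covariance_explained`` uses s_d^2 / sum(s^2) by default
    (``sv_convention='squared'``); ``'linear'`` uses s_d / sum(s).
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if X.ndim != 2 or Y.ndim != 2 or X.shape[0] != Y.shape[0]:
        raise ValueError("X and Y must be 2-D with matching rows")
    if X.shape[0] < 3:
        raise ValueError("need at least 3 observations")
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(Y))):
        raise ValueError("non-finite entries in input matrices")
    R = cross_block_matrix(X, Y)
    U, S, Vt = np.linalg.svd(R, full_matrices=False)
    V = Vt.T
    U, V = _fix_signs(U, V)
    x_scores = X @ U
    y_scores = Y @ V
    if sv_convention == "squared":
        cov_expl = S**2 / np.sum(S**2) if np.sum(S**2) > 0 else np.zeros_like(S)
    elif sv_convention == "linear":
        cov_expl = S / np.sum(S) if np.sum(S) > 0 else np.zeros_like(S)
    else:
        raise ValueError("sv_convention must be 'squared' or 'linear'")
    latent_corr = np.array(
        [
            spearmanr(x_scores[:, d], y_scores[:, d]).statistic
            for d in range(S.size)
        ]
    )
    return PlscResult(
        singular_values=S,
        x_weights=U,
        y_weights=V,
        x_scores=x_scores,
        y_scores=y_scores,
        x_loadings=_column_correlations(X, x_scores),
        y_loadings=_column_correlations(Y, y_scores),
        covariance_explained=cov_expl,
        latent_correlations=latent_corr,
    )


def projected_singular_values(
    x_weights: np.ndarray, y_weights: np.ndarray, R: np.ndarray
) -> np.ndarray:
    """Per-dimension u_d' R v_d for fixed weights (test singular values)."""
    return np.einsum("pd,pq,qd->d", x_weights, R, y_weights)


# ---------------------------------------------------------------------------
# family structure helpers


def _family_index(family_ids: np.ndarray) -> list[np.ndarray]:
    """Row indices per family, in first-appearance order."""
    family_ids = np.asarray(family_ids)
    seen: dict = {}
    for i, f in enumerate(family_ids):
        seen.setdefault(f, []).append(i)
    return [np.asarray(v) for v in seen.values()]


def exchangeability_blocks(
    family_ids: np.ndarray, rng: np.random.Generator
) -> list[np.ndarray]:
    """Blocks of mutually unrelated subjects.

    Each family's members are dealt (in an order randomized once) into
    slots 1, 2, ...; slot b across all families forms block b, which by
    construction contains at most one member of any family.  Permuting
    within blocks therefore never exchanges relatives.  Blocks of size 1
    contribute no permutation.
    """
    fams = _family_index(family_ids)
    max_size = max(len(f) for f in fams)
    blocks: list[list[int]] = [[] for _ in range(max_size)]
    for members in fams:
        members = members[rng.permutation(len(members))]
        for slot, idx in enumerate(members):
            blocks[slot].append(int(idx))
    return [np.asarray(b) for b in blocks]


def _block_permutation(
    n: int, blocks: list[np.ndarray], rng: np.random.Generator
) -> np.ndarray:
    perm = np.arange(n)
    for b in blocks:
        perm[b] = b[rng.permutation(len(b))]
    return perm


def _split_families(
    fams: list[np.ndarray], rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Random half-split keeping families intact, balancing subject counts."""
    order = rng.permutation(len(fams))
    half_a: list[int] = []
    half_b: list[int] = []
    for i in order:
        target = half_a if len(half_a) <= len(half_b) else half_b
        target.extend(int(j) for j in fams[i])
    return np.asarray(half_a), np.asarray(half_b)


def _align_to_reference(
    ref_w: np.ndarray, w: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Greedy dimension matching by |dot| of stacked weight vectors.

    Returns (order, signs): boot dimension ``order[d]`` with sign
    ``signs[d]`` corresponds to reference dimension d.
    """
    d = ref_w.shape[1]
    dots = ref_w.T @ w  # (d, d)
    order = np.full(d, -1)
    signs = np.ones(d)
    free = list(range(d))
    for i in range(d):
        j = max(free, key=lambda c: abs(dots[i, c]))
        order[i] = j
        signs[i] = 1.0 if dots[i, j] >= 0 else -1.0
        free.remove(j)
    return order, signs


# ---------------------------------------------------------------------------
# permutation test


@dataclass
class PermutationResult:
    pvalues: np.ndarray  # (d,)
    observed: np.ndarray  # (d,)
    null_svs: np.ndarray  # (n_perm, d)


def permutation_test(
    X: np.ndarray,
    Y: np.ndarray,
    family_ids: np.ndarray,
    n_perm: int = 10000,
    seed: int | np.random.SeedSequence | None = None,
    mode: str = "y",
    _batch: int = 256,
) -> PermutationResult:
    """Per-dimension significance of the singular values.

    Rows of Y are permuted within exchangeability blocks of unrelated
    subjects (``mode='both'`` additionally permutes X with an
    independent block permutation); p_d = (1 + #{s*_d >= s_d}) /
    (n_perm + 1), so the smallest attainable p is 1 / (n_perm + 1).
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    if mode not in ("y", "both"):
        raise ValueError("mode must be 'y' or 'both'")
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    n = X.shape[0]
    rng = np.random.default_rng(seed)
    blocks = exchangeability_blocks(family_ids, rng)
    observed = np.linalg.svd(cross_block_matrix(X, Y), compute_uv=False)
    null = np.empty((n_perm, observed.size))
    done = 0
    while done < n_perm:
        b = min(_batch, n_perm - done)
        perms = np.stack([_block_permutation(n, blocks, rng) for _ in range(b)])
        Yp = Y[perms]  # (b, n, q)
        if mode == "both":
            xperms = np.stack(
                [_block_permutation(n, blocks, rng) for _ in range(b)]
            )
            Xp = X[xperms]
            Rb = np.einsum("bnp,bnq->bpq", Xp, Yp) / (n - 1)
        else:
            Rb = np.einsum("np,bnq->bpq", X, Yp) / (n - 1)
        null[done : done + b] = np.linalg.svd(Rb, compute_uv=False)
        done += b
    pvalues = (1 + np.sum(null >= observed[None, :], axis=0)) / (n_perm + 1)
    return PermutationResult(pvalues=pvalues, observed=observed, null_svs=null)


# ---------------------------------------------------------------------------
# bootstrap


@dataclass
class BootstrapResult:
    bootstrap_ratios: np.ndarray  # (p + q, d); x rows first
    x_ratios: np.ndarray  # (p, d)
    y_ratios: np.ndarray  # (q, d)
    n_degenerate: int  # loadings with zero bootstrap SD (BR set to +-inf)


def bootstrap_ratios(
    X: np.ndarray,
    Y: np.ndarray,
    family_ids: np.ndarray,
    n_boot: int = 10000,
    seed: int | np.random.SeedSequence | None = None,
    confounds: np.ndarray | None = None,
) -> BootstrapResult:
    """Loading stability via whole-family bootstrap.

    Families are resampled with replacement until at least n subjects
    are drawn; preprocessing (confound regression when ``confounds`` is
    given, z-scoring always) and PLSC are refit on every resample, each
    resample's dimensions are sign/order-aligned to the original
    solution, and BR = original loading / SD of its bootstrap
    distribution.  |BR| > 2.5 is the conventional stability threshold.
    """
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    n, p = X.shape
    q = Y.shape[1]
    rng = np.random.default_rng(seed)
    fams = _family_index(family_ids)

    X0 = _lenient_standardize(X, confounds)
    Y0 = _lenient_standardize(Y, confounds)
    ref = plsc_fit(X0, Y0)
    d = ref.n_dimensions
    ref_w = np.vstack([ref.x_weights, ref.y_weights])

    boot_loadings = np.empty((n_boot, p + q, d))
    for b in range(n_boot):
        rows: list[np.ndarray] = []
        count = 0
        while count < n:
            f = fams[rng.integers(len(fams))]
            rows.append(f)
            count += len(f)
        idx = np.concatenate(rows)
        cb = confounds[idx] if confounds is not None else None
        Xb = _lenient_standardize(X[idx], cb)
        Yb = _lenient_standardize(Y[idx], cb)
        fit = plsc_fit(Xb, Yb)
        w = np.vstack([fit.x_weights, fit.y_weights])
        order, signs = _align_to_reference(ref_w, w)
        boot_loadings[b] = (
            np.vstack([fit.x_loadings, fit.y_loadings])[:, order] * signs
        )

    sd = boot_loadings.std(axis=0, ddof=1)
    ref_loadings = np.vstack([ref.x_loadings, ref.y_loadings])
    degenerate = sd <= _SD_TOL
    with np.errstate(divide="ignore", invalid="ignore"):
        br = ref_loadings / np.where(degenerate, 0.0, sd)
    sign = np.sign(ref_loadings[degenerate])
    br[degenerate] = np.where(sign == 0, np.nan, sign * np.inf)
    return BootstrapResult(
        bootstrap_ratios=br,
        x_ratios=br[:p],
        y_ratios=br[p:],
        n_degenerate=int(degenerate.sum()),
    )


# ---------------------------------------------------------------------------
# split-half reproducibility


@dataclass
class SplitHalfResult:
    z_sv: np.ndarray  # (d,) mean/SD of test singular values
    z_x_weights: np.ndarray  # (d,) of |u_train . u_test|
    z_y_weights: np.ndarray  # (d,)
    test_sv_mean: np.ndarray = field(default_factory=lambda: np.empty(0))
    test_sv_sd: np.ndarray = field(default_factory=lambda: np.empty(0))


def splithalf_reproducibility(
    X: np.ndarray,
    Y: np.ndarray,
    family_ids: np.ndarray,
    n_split: int = 10000,
    seed: int | np.random.SeedSequence | None = None,
    confounds: np.ndarray | None = None,
) -> SplitHalfResult:
    """Reproducibility Z-scores from repeated family-respecting splits.

    Each split halves the cohort without separating relatives, fits
    preprocessing and PLSC on the train half, and evaluates on the test
    half: the test singular value u_d' R_test v_d (train weights, test
    cross-block matrix, train preprocessing parameters) and the |dot|
    similarity between train and test weight vectors.  Z = mean / SD
    over splits; Z > 1.95 is the conventional reproducibility bound.
    """
    if n_split < 100:
        raise ValueError("n_split must be >= 100")
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    n = X.shape[0]
    fams = _family_index(family_ids)
    if max(len(f) for f in fams) > n // 2:
        raise ValueError("a family exceeds half the cohort; splitting impossible")
    rng = np.random.default_rng(seed)
    d = min(X.shape[1], Y.shape[1])
    sv = np.empty((n_split, d))
    xdot = np.empty((n_split, d))
    ydot = np.empty((n_split, d))
    for s in range(n_split):
        tr, te = _split_families(fams, rng)
        ctr = confounds[tr] if confounds is not None else None
        cte = confounds[te] if confounds is not None else None
        # fit leakage-free parameters on train, apply to test
        Xtr, px = residualize_lenient(X[tr], ctr)
        Ytr, py = residualize_lenient(Y[tr], ctr)
        Xte = apply_preprocessor(X[te], cte, px)
        Yte = apply_preprocessor(Y[te], cte, py)
        fit = plsc_fit(Xtr, Ytr)
        R_test = cross_block_matrix(Xte, Yte)
        sv[s] = projected_singular_values(fit.x_weights, fit.y_weights, R_test)
        test_fit = plsc_fit(Xte, Yte)
        xdot[s] = np.abs(np.sum(fit.x_weights * test_fit.x_weights, axis=0))
        ydot[s] = np.abs(np.sum(fit.y_weights * test_fit.y_weights, axis=0))

    def z(a: np.ndarray) -> np.ndarray:
        sd = a.std(axis=0, ddof=1)
        sd = np.where(sd <= _SD_TOL, np.inf, sd)
        return a.mean(axis=0) / sd

    return SplitHalfResult(
        z_sv=z(sv),
        z_x_weights=z(xdot),
        z_y_weights=z(ydot),
        test_sv_mean=sv.mean(axis=0),
        test_sv_sd=sv.std(axis=0, ddof=1),
    )


def residualize_lenient(
    M: np.ndarray, confounds: np.ndarray | None
) -> tuple[np.ndarray, Preprocessor]:
    """Fit-and-apply preprocessing that tolerates zero-variance columns
    (used on resampled halves, where a degenerate draw must not abort)."""
    M = np.asarray(M, dtype=float)
    d = _design(confounds, M.shape[0], check_rank=False)
    if d is not None:
        beta, *_ = np.linalg.lstsq(d, M, rcond=None)
        resid = M - d @ beta
    else:
        beta = None
        resid = M
    mean = resid.mean(axis=0)
    sd = resid.std(axis=0, ddof=1)
    sd = np.where(sd <= _SD_TOL, 1.0, sd)
    params = Preprocessor(beta=beta, mean=mean, sd=sd)
    return (resid - mean) / sd, params


def apply_preprocessor(
    M: np.ndarray, confounds: np.ndarray | None, params: Preprocessor
) -> np.ndarray:
    """Apply train-fitted confound coefficients, means and SDs to new data."""
    M = np.asarray(M, dtype=float)
    if params.beta is not None:
        d = _design(confounds, M.shape[0], check_rank=False)
        M = M - d @ params.beta
    return (M - params.mean) / params.sd


# ---------------------------------------------------------------------------
# cross-validation


@dataclass
class CrossValidationResult:
    oos_correlation: np.ndarray  # (d,) Spearman of pooled out-of-fold scores
    consistency_x: np.ndarray  # (d,) oos x-scores vs in-sample x-scores
    consistency_y: np.ndarray  # (d,)
    insample_correlation: np.ndarray  # (d,)
    oos_x_scores: np.ndarray  # (n, d)
    oos_y_scores: np.ndarray  # (n, d)


def cross_validate(
    X_raw: np.ndarray,
    Y_raw: np.ndarray,
    confounds: np.ndarray | None,
    family_ids: np.ndarray,
    n_folds: int = 10,
    seed: int | np.random.SeedSequence | None = None,
) -> CrossValidationResult:
    """Out-of-sample PLSC association strength by family-blocked k-fold CV.

    Each fold's test subjects are projected with the train-half weights
    (train-fitted preprocessing applied); pooled out-of-fold score pairs
    give the out-of-sample Spearman correlation per dimension, and their
    Spearman correlation with the in-sample scores gives consistency.
    """
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    X_raw = np.asarray(X_raw, dtype=float)
    Y_raw = np.asarray(Y_raw, dtype=float)
    n = X_raw.shape[0]
    rng = np.random.default_rng(seed)
    fams = _family_index(family_ids)
    if len(fams) < n_folds:
        raise ValueError("fewer families than folds")

    X0, _ = residualize_lenient(X_raw, confounds)
    Y0, _ = residualize_lenient(Y_raw, confounds)
    ref = plsc_fit(X0, Y0)
    d = ref.n_dimensions
    ref_w = np.vstack([ref.x_weights, ref.y_weights])

    # deal shuffled families into folds, balancing subject counts
    folds: list[list[int]] = [[] for _ in range(n_folds)]
    sizes = np.zeros(n_folds, dtype=int)
    for i in rng.permutation(len(fams)):
        j = int(sizes.argmin())
        folds[j].extend(int(r) for r in fams[i])
        sizes[j] += len(fams[i])

    oos_x = np.empty((n, d))
    oos_y = np.empty((n, d))
    for te_rows in folds:
        te = np.asarray(te_rows)
        tr = np.setdiff1d(np.arange(n), te)
        ctr = confounds[tr] if confounds is not None else None
        cte = confounds[te] if confounds is not None else None
        Xtr, px = residualize_lenient(X_raw[tr], ctr)
        Ytr, py = residualize_lenient(Y_raw[tr], ctr)
        fit = plsc_fit(Xtr, Ytr)
        order, signs = _align_to_reference(
            ref_w, np.vstack([fit.x_weights, fit.y_weights])
        )
        U = fit.x_weights[:, order] * signs
        V = fit.y_weights[:, order] * signs
        Xte = apply_preprocessor(X_raw[te], cte, px)
        Yte = apply_preprocessor(Y_raw[te], cte, py)
        oos_x[te] = Xte @ U
        oos_y[te] = Yte @ V

    def srho(a: np.ndarray, b: np.ndarray) -> float:
        return float(spearmanr(a, b).statistic)

    return CrossValidationResult(
        oos_correlation=np.array([srho(oos_x[:, j], oos_y[:, j]) for j in range(d)]),
        consistency_x=np.array(
            [srho(oos_x[:, j], ref.x_scores[:, j]) for j in range(d)]
        ),
        consistency_y=np.array(
            [srho(oos_y[:, j], ref.y_scores[:, j]) for j in range(d)]
        ),
        insample_correlation=ref.latent_correlations,
        oos_x_scores=oos_x,
        oos_y_scores=oos_y,
    )


# ---------------------------------------------------------------------------
# variance explained


def variance_explained(M: np.ndarray, scores: np.ndarray) -> float:
    """Fraction of Frobenius variance of M captured by the score columns.

    1 - ||M - P M||_F^2 / ||M||_F^2 where P projects onto the column
    space of ``scores``.
    """
    M = np.asarray(M, dtype=float)
    scores = np.asarray(scores, dtype=float)
    total = float(np.sum(M**2))
    if total <= 0:
        raise ValueError("zero-norm matrix")
    beta, *_ = np.linalg.lstsq(scores, M, rcond=None)
    resid = M - scores @ beta
    return 1.0 - float(np.sum(resid**2)) / total
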