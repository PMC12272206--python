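"""Synthetic multi-subject cohorts with planted state dynamics.

The generator emulates the structure the analysis pipeline assumes in
real resting-state data, with every latent quantity recorded so that
downstream stages can be tested by parameter recovery:

* k phase-locking patterns, each splitting regions into a coherent
  majority (phase offset 0) and an anticoherent minority (offset pi);
* a hidden Markov state sequence per run selecting the active pattern;
* per-subject signals sin(2 pi f t + offset + perturbation) + noise,
  whose Hilbert phases provably recover the planted offsets;
* per-subject idiosyncrasy (a fixed random phase-perturbation vector
  with subject-specific scale) and state-stickiness (a bias on the
  Markov self-transition odds), optionally correlated within families;
* age / gender confounds and behavioral scores built from a planted
  low-rank map of the true subject parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class StatePhasePattern:
    """One planted phase-locking pattern over regions.

    ``offsets`` entries are 0 (coherent majority) or pi (anticoherent
    minority); the minority is strictly smaller than half the regions.
    A zero ``minority_fraction`` gives the uniform, all-coherent pattern.
    """

    pattern_id: int
    offsets: np.ndarray
    minority_fraction: float

    @property
    def minority_mask(self) -> np.ndarray:
        return self.offsets > 0

    def coherence_matrix(self) -> np.ndarray:
        """The +-1 cosine-coherence matrix implied by the offsets."""
        return np.cos(self.offsets[:, None] - self.offsets[None, :])


@dataclass
class CohortDesign:
    """Full parameterization of a synthetic cohort.

    ``behavior_weights`` (q x 2) maps the z-scored true subject
    parameters (state-stickiness bias, idiosyncrasy scale) to the q
    behavioral scores; a zero matrix yields a null cohort.  Families
    share a Gaussian random effect (``family_effect_sd``) on the
    stickiness bias, breaking exchangeability across families.
    """

    n_subjects: int = 200
    n_runs: int = 2
    n_regions: int = 24
    n_timepoints: int = 150
    k_true: int = 4
    markov_matrix: np.ndarray | None = None  # default: sticky uniform chain
    carrier_freq: float = 0.1  # cycles per sample
    noise_sd: float = 0.3
    idio_sd_range: tuple[float, float] = (0.05, 0.45)
    family_sizes: list[int] | None = None  # default: pairs then singletons
    behavior_weights: np.ndarray | None = None  # (q, 2); default rank-1, q=10
    behavior_noise_sd: float = 1.0
    confound_effect: float = 0.2  # linear age/gender effect on both sides
    stay_bias_sd: float = 0.6
    family_effect_sd: float = 0.3
    minority_fractions: list[float] | None = None  # default: 0 then 0.25...
    seed: int = 0

    def resolved_markov(self) -> np.ndarray:
        if self.markov_matrix is not None:
            m = np.asarray(self.markov_matrix, dtype=float)
        else:
            k = self.k_true
            stay = 0.95
            m = np.full((k, k), (1 - stay) / (k - 1)) if k > 1 else np.ones((1, 1))
            if k > 1:
                np.fill_diagonal(m, stay)
        _check_markov(m)
        return m

    def resolved_family_sizes(self) -> list[int]:
        if self.family_sizes is not None:
            sizes = list(self.family_sizes)
        else:
            n_pairs = self.n_subjects // 4
            sizes = [2] * n_pairs + [1] * (self.n_subjects - 2 * n_pairs)
        if sum(sizes) != self.n_subjects or any(s < 1 for s in sizes):
            raise ValueError("family_sizes must partition the cohort")
        return sizes

    def resolved_fractions(self) -> list[float]:
        if self.minority_fractions is not None:
            fr = list(self.minority_fractions)
            if len(fr) != self.k_true:
                raise ValueError("need one minority fraction per state")
            return fr
        # pattern 1 uniform (the meta-stable all-coherent state), the
        # rest delineating distinct anticoherent minorities
        return [0.0] + [0.25] * (self.k_true - 1)

    def resolved_behavior_weights(self) -> np.ndarray:
        if self.behavior_weights is not None:
            w = np.asarray(self.behavior_weights, dtype=float)
            if w.ndim != 2 or w.shape[1] != 2:
                raise ValueError("behavior_weights must be q x 2")
            return w
        # default: rank-1 planted association loading on both parameters
        q = 10
        col = np.linspace(1.0, 0.4, q)
        return np.column_stack([0.6 * col, -0.4 * col])


@dataclass
class SyntheticTruth:
    """Ground truth recorded at generation time."""

    labels: dict[str, list[np.ndarray]]  # subject -> per-run state sequences
    stay_bias: np.ndarray  # (n_subjects,)
    idio_scale: np.ndarray  # (n_subjects,)
    true_params_z: np.ndarray  # (n_subjects, 2) z-scored (bias, scale)
    latent_cognition: np.ndarray  # (n_subjects,)
    patterns: list[StatePhasePattern] = field(default_factory=list)


@dataclass
class CohortData:
    runs: dict[str, list[np.ndarray]]  # subject -> region x time matrices
    behavior: pd.DataFrame  # subject_id + q score columns
    confounds: pd.DataFrame  # subject_id, age, gender
    families: pd.DataFrame  # subject_id, family_id
    truth: SyntheticTruth

    @property
    def subject_ids(self) -> list[str]:
        return list(self.runs.keys())


def _check_markov(m: np.ndarray) -> None:
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError("Markov matrix must be square")
    if np.any(m < 0) or not np.allclose(m.sum(axis=1), 1.0, atol=1e-8):
        raise ValueError("Markov matrix rows must be non-negative and sum to 1")


def stationary_distribution(markov_matrix: np.ndarray) -> np.ndarray:
    """Stationary row vector of a row-stochastic matrix (least squares)."""
    m = np.asarray(markov_matrix, dtype=float)
    _check_markov(m)
    k = m.shape[0]
    a = np.vstack([m.T - np.eye(k), np.ones(k)])
    b = np.concatenate([np.zeros(k), [1.0]])
    pi, *_ = np.linalg.lstsq(a, b, rcond=None)
    pi = np.clip(pi, 0, None)
    return pi / pi.sum()


def make_state_phase_patterns(
    k: int,
    n_regions: int,
    minority_fractions: list[float],
    seed: int | np.random.SeedSequence | np.random.Generator | None = None,
) -> list[StatePhasePattern]:
    """Draw k phase-locking patterns with disjointly chosen minorities.

    The minority size is round(fraction * n_regions) (nearest integer,
    ties up); any fraction >= 0.5 is rejected because the majority
    convention would be ill-defined.  Patterns with identical nonempty
    minorities are redrawn so states stay distinguishable.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if len(minority_fractions) != k:
        raise ValueError("need one minority fraction per pattern")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    patterns: list[StatePhasePattern] = []
    seen: set[tuple[int, ...]] = set()
    for i, frac in enumerate(minority_fractions, start=1):
        if not 0.0 <= frac < 0.5:
            raise ValueError(f"minority_fraction {frac} must be in [0, 0.5)")
        size = int(np.floor(frac * n_regions + 0.5))
        if size >= n_regions / 2:
            raise ValueError("minority would not be a strict minority")
        for _ in range(1000):
            members = tuple(sorted(rng.choice(n_regions, size=size, replace=False)))
            if size == 0 or members not in seen:
                break
        else:  # pragma: no cover
            raise RuntimeError("could not draw a distinct minority")
        seen.add(members)
        offsets = np.zeros(n_regions)
        offsets[list(members)] = np.pi
        patterns.append(
            StatePhasePattern(pattern_id=i, offsets=offsets, minority_fraction=frac)
        )
    return patterns


def sample_markov_labels(
    markov_matrix: np.ndarray,
    n_timepoints: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """State sequence (1..k) started at the stationary distribution."""
    m = np.asarray(markov_matrix, dtype=float)
    _check_markov(m)
    k = m.shape[0]
    labels = np.empty(n_timepoints, dtype=int)
    state = rng.choice(k, p=stationary_distribution(m))
    labels[0] = state + 1
    for t in range(1, n_timepoints):
        state = rng.choice(k, p=m[state])
        labels[t] = state + 1
    return labels


def simulate_run(
    patterns: list[StatePhasePattern],
    markov_matrix: np.ndarray,
    n_timepoints: int,
    carrier_freq: float,
    noise_sd: float,
    subject_perturbation: np.ndarray | None = None,
    seed: int | np.random.SeedSequence | np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """One run of oscillatory region signals under a hidden state chain.

    Region n at time t is sin(2 pi f t + offset_{state(t)}[n] +
    perturbation[n]) plus Gaussian noise; labels are drawn from the
    Markov chain started at its stationary distribution.  Returns
    ``(timeseries, labels)`` with timeseries of shape regions x time.
    """
    if n_timepoints < 10:
        raise ValueError("n_timepoints must be >= 10")
    if not 0.0 < carrier_freq < 0.5:
        raise ValueError("carrier_freq must lie in (0, 0.5) cycles/sample")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    n_regions = patterns[0].offsets.size
    pert = (
        np.zeros(n_regions)
        if subject_perturbation is None
        else np.asarray(subject_perturbation, dtype=float)
    )
    labels = sample_markov_labels(markov_matrix, n_timepoints, rng)
    offsets = np.stack([p.offsets for p in patterns])  # (k, N)
    t = np.arange(n_timepoints)
    phase = 2 * np.pi * carrier_freq * t[None, :] + offsets[labels - 1].T + pert[:, None]
    ts = np.sin(phase)
    if noise_sd > 0:
        ts = ts + rng.normal(0.0, noise_sd, size=ts.shape)
    return ts, labels


def _subject_markov(base: np.ndarray, stay_bias: float) -> np.ndarray:
    """Scale self-transition odds by exp(stay_bias), renormalize rows."""
    m = base.copy()
    diag = np.diag(m) * np.exp(stay_bias)
    np.fill_diagonal(m, diag)
    return m / m.sum(axis=1, keepdims=True)


def simulate_cohort(design: CohortDesign) -> CohortData:
    """Generate runs, behavior, confounds and family tables plus truth.

    Behavioral scores are ``behavior_weights @ true_params`` (z-scored
    stickiness bias and idiosyncrasy scale) plus linear age/gender
    effects and Gaussian noise; zero weights yield a null cohort.
    """
    rng = np.random.default_rng(design.seed)
    markov = design.resolved_markov()
    fam_sizes = design.resolved_family_sizes()
    weights = design.resolved_behavior_weights()
    patterns = make_state_phase_patterns(
        design.k_true, design.n_regions, design.resolved_fractions(), rng
    )

    n = design.n_subjects
    subject_ids = [f"sub-{i:04d}" for i in range(n)]
    family_ids = np.concatenate(
        [np.full(s, f"fam-{j:04d}") for j, s in enumerate(fam_sizes)]
    )

    # confounds
    age = rng.integers(22, 37, size=n).astype(float)
    gender = rng.integers(0, 2, size=n).astype(float)
    age_z = (age - age.mean()) / age.std() if age.std() > 0 else np.zeros(n)
    gender_c = gender - gender.mean()

    # true subject parameters: family-correlated stickiness, idio scale
    fam_effect = np.concatenate(
        [
            np.full(s, rng.normal(0.0, design.family_effect_sd))
            for s in fam_sizes
        ]
    )
    stay_bias = (
        fam_effect
        + rng.normal(0.0, design.stay_bias_sd, size=n)
        + design.confound_effect * age_z
    )
    lo, hi = design.idio_sd_range
    idio_scale = rng.uniform(lo, hi, size=n)

    params = np.column_stack([stay_bias, idio_scale])
    params_z = (params - params.mean(axis=0)) / params.std(axis=0, ddof=1)

    # behavior with planted low-rank association + confound effects
    behavior = params_z @ weights.T
    behavior = behavior + design.confound_effect * (age_z + gender_c)[:, None]
    behavior = behavior + rng.normal(
        0.0, design.behavior_noise_sd, size=behavior.shape
    )

    if np.any(weights != 0):
        _, _, vt = np.linalg.svd(weights, full_matrices=False)
        latent = params_z @ vt[0]
    else:
        latent = np.zeros(n)

    runs: dict[str, list[np.ndarray]] = {}
    labels: dict[str, list[np.ndarray]] = {}
    for i, sid in enumerate(subject_ids):
        m_i = _subject_markov(markov, stay_bias[i])
        pert = rng.normal(0.0, idio_scale[i], size=design.n_regions)
        runs[sid] = []
        labels[sid] = []
        for _ in range(design.n_runs):
            ts, lab = simulate_run(
                patterns,
                m_i,
                design.n_timepoints,
                design.carrier_freq,
                design.noise_sd,
                subject_perturbation=pert,
                seed=rng,
            )
            runs[sid].append(ts)
            labels[sid].append(lab)

    q = weights.shape[0]
    behavior_df = pd.DataFrame(
        behavior, columns=[f"score_{j + 1}" for j in range(q)]
    )
    behavior_df.insert(0, "subject_id", subject_ids)
    confound_df = pd.DataFrame(
        {"subject_id": subject_ids, "age": age, "gender": gender}
    )
    family_df = pd.DataFrame({"subject_id": subject_ids, "family_id": family_ids})
    truth = SyntheticTruth(
        labels=labels,
        stay_bias=stay_bias,
        idio_scale=idio_scale,
        true_params_z=params_z,
        latent_cognition=latent,
        patterns=patterns,
    )
    return CohortData(
        runs=runs,
        behavior=behavior_df,
        confounds=confound_df,
        families=family_df,
        truth=truth,
    )


# ---------------------------------------------------------------------------
# matrix-level generator for inference calibration


@dataclass
class LinkedMatrices:
    """Two matrices with a planted rank-1 cross-covariance."""

    X: np.ndarray  # (n, p)
    Y: np.ndarray  # (n, q)
    confounds: np.ndarray | None  # (n, 2) age_z, gender
    family_ids: np.ndarray  # (n,)
    x_direction: np.ndarray  # unit planted x weight vector
    y_direction: np.ndarray  # unit planted y weight vector
    planted_x: np.ndarray  # indices of contributing x variables
    planted_y: np.ndarray


def simulate_linked_matrices(
    n: int,
    p: int = 10,
    q: int = 5,
    effect: float = 0.5,
    n_planted_x: int = 3,
    n_planted_y: int = 2,
    family_size: int = 2,
    family_effect_sd: float = 0.0,
    confound_effect: float = 0.0,
    seed: int | np.random.SeedSequence | None = None,
) -> LinkedMatrices:
    """Direct generator of the two PLSC input matrices.

    A standard-normal latent score s links the blocks: the planted
    variables of X and Y receive ``effect * s`` plus unit noise
    (``effect = 0`` gives an exact null).  Families of ``family_size``
    share a random effect entering X only, so the null remains a true
    null while exchangeability across families is broken.  Optional
    age/gender confounds add linear signal to both sides.
    """
    rng = np.random.default_rng(seed)
    s = rng.normal(size=n)
    x_dir = np.zeros(p)
    x_dir[:n_planted_x] = 1.0 / np.sqrt(n_planted_x)
    y_dir = np.zeros(q)
    y_dir[:n_planted_y] = 1.0 / np.sqrt(n_planted_y)
    X = effect * np.outer(s, x_dir) + rng.normal(size=(n, p))
    Y = effect * np.outer(s, y_dir) + rng.normal(size=(n, q))

    n_fam = int(np.ceil(n / family_size))
    family_ids = np.repeat(np.arange(n_fam), family_size)[:n]
    if family_effect_sd > 0:
        fam_eff = rng.normal(0.0, family_effect_sd, size=n_fam)[family_ids]
        g = rng.normal(size=p) / np.sqrt(p)
        X = X + np.outer(fam_eff, g)

    confounds = None
    if confound_effect != 0.0:
        age_z = rng.normal(size=n)
        gender = rng.integers(0, 2, size=n).astype(float)
        confounds = np.column_stack([age_z, gender])
        X = X + confound_effect * age_z[:, None]
        Y = Y + confound_effect * (age_z + gender - gender.mean())[:, None]

    return LinkedMatrices(
        X=X,
        Y=Y,
        confounds=confounds,
        family_ids=family_ids,
        x_direction=x_dir,
        y_direction=y_dir,
        planted_x=np.arange(n_planted_x),
        planted_y=np.arange(n_planted_y),
    )
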