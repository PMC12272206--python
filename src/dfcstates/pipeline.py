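"""End-to-end orchestration: simulate/load -> LE series -> states ->
reconfiguration metrics -> PLSC inference, with provenance and logging.

Every numeric output is a deterministic function of the configuration
and the master seed; per-stage random streams are spawned from the
master seed so stages can be rerun independently.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as dio
from .metrics import metric_names, metric_vector, run_average, run_profile
from .phase import compute_le_series
from .plsc import (
    bootstrap_ratios,
    cross_validate,
    permutation_test,
    plsc_fit,
    residualize_and_standardize,
    splithalf_reproducibility,
    variance_explained,
)
from .states import fit_state_model, relabel_states
from .stats import icc_two_session
from .synthetic import CohortDesign, CohortData, simulate_cohort

PROFILES = {
    "full": dict(n_restarts=500, n_perm=10000, n_boot=10000, n_split=10000, n_folds=10),
    "test": dict(n_restarts=20, n_perm=500, n_boot=500, n_split=500, n_folds=5),
}


@dataclass
class PipelineConfig:
    """Run configuration; exactly one of ``design`` / ``input_dir`` is set."""

    design: CohortDesign | None = None
    input_dir: str | None = None
    k: int = 4
    profile: str = "test"
    seed: int = 0
    outdir: str = "results"
    n_restarts: int | None = None
    n_perm: int | None = None
    n_boot: int | None = None
    n_split: int | None = None
    n_folds: int | None = None

    def __post_init__(self) -> None:
        if (self.design is None) == (self.input_dir is None):
            raise ValueError("set exactly one of design / input_dir")
        if self.profile not in PROFILES:
            raise ValueError(f"unknown profile {self.profile!r}")
        for name, value in PROFILES[self.profile].items():
            if getattr(self, name) is None:
                setattr(self, name, value)
        for name in PROFILES["full"]:
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        design = raw.pop("design", None)
        if design is not None:
            for key in ("markov_matrix", "behavior_weights"):
                if design.get(key) is not None:
                    design[key] = np.asarray(design[key], dtype=float)
            if design.get("idio_sd_range") is not None:
                design["idio_sd_range"] = tuple(design["idio_sd_range"])
            design = CohortDesign(**design)
        return cls(design=design, **raw)

    def config_hash(self) -> str:
        def enc(o):
            if isinstance(o, np.ndarray):
                return o.tolist()
            if isinstance(o, tuple):
                return list(o)
            raise TypeError

        # outdir does not influence any numeric output, so it is not hashed
        payload = {"design": asdict(self.design) if self.design else None}
        payload.update(
            {k: v for k, v in asdict(self).items() if k not in ("design", "outdir")}
        )
        blob = json.dumps(payload, sort_keys=True, default=enc)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class PipelineResult:
    metrics: pd.DataFrame  # subject_id + metric columns (imputed)
    state_model: object
    plsc: object
    permutation: object
    bootstrap: object
    splithalf: object
    cross_validation: object
    imputation_log: dict[str, int] = field(default_factory=dict)
    dropped_columns: list[str] = field(default_factory=list)
    variance_explained_x: float = float("nan")
    variance_explained_y: float = float("nan")


def compute_metric_table(
    le_series: dict[str, list[np.ndarray]],
    labels: dict[str, list[np.ndarray]],
    group_medians: np.ndarray,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Run-averaged metric vector per subject, cohort-median imputation.

    A metric undefined for a subject across all runs (state never
    visited / switch never seen) is imputed at the cohort median;
    the returned log counts imputations per column.
    """
    k = group_medians.shape[0]
    rows = []
    for sid, series_list in le_series.items():
        profiles = [
            run_profile(le, lab, group_medians)
            for le, lab in zip(series_list, labels[sid])
        ]
        vec, names = metric_vector(run_average(profiles))
        rows.append(vec)
    df = pd.DataFrame(rows, columns=metric_names(k))
    log: dict[str, int] = {}
    for col in df.columns:
        n_missing = int(df[col].isna().sum())
        if n_missing:
            log[col] = n_missing
            df[col] = df[col].fillna(df[col].median())
    df.insert(0, "subject_id", list(le_series.keys()))
    return df, log


def reliability_table(
    le_series: dict[str, list[np.ndarray]],
    labels: dict[str, list[np.ndarray]],
    group_medians: np.ndarray,
    form: str = "ICC2",
    session_split: str = "halves",
) -> pd.DataFrame:
    """Per-metric test-retest ICC between two sessions of runs.

    ``session_split='halves'`` averages the first and second half of
    each subject's runs (mirroring day-level aggregation);
    ``'per_run'`` uses runs 1 and 2 directly.  Needs >= 2 runs.
    """
    k = group_medians.shape[0]
    n_runs = len(next(iter(le_series.values())))
    if n_runs < 2:
        raise ValueError("need at least 2 runs for test-retest ICC")
    half = n_runs // 2 if session_split == "halves" else 1
    s1_rows, s2_rows = [], []
    for sid, series_list in le_series.items():
        profs = [
            run_profile(le, lab, group_medians)
            for le, lab in zip(series_list, labels[sid])
        ]
        v1, _ = metric_vector(run_average(profs[:half]))
        v2, _ = metric_vector(run_average(profs[half : 2 * half]))
        s1_rows.append(v1)
        s2_rows.append(v2)
    s1 = np.asarray(s1_rows)
    s2 = np.asarray(s2_rows)
    names = metric_names(k)
    iccs = []
    for j in range(s1.shape[1]):
        a, b = s1[:, j], s2[:, j]
        ok = np.isfinite(a) & np.isfinite(b)
        iccs.append(
            icc_two_session(a[ok], b[ok], form=form) if ok.sum() >= 3 else np.nan
        )
    # the ANOVA estimator can undershoot -1 on degenerate small samples;
    # clamp so the table stays on the correlation scale
    iccs = np.clip(np.asarray(iccs, dtype=float), -1.0, 1.0)
    return pd.DataFrame({"metric": names, "icc": iccs})


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute all stages and write artifacts under ``config.outdir``."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_lines: list[str] = []
    t0 = time.time()

    def log(stage: str, msg: str) -> None:
        log_lines.append(f"[{time.time() - t0:8.2f}s] {stage}: {msg}")

    ss = np.random.SeedSequence(config.seed)
    seeds = dict(
        zip(
            ("cluster", "perm", "boot", "split", "cv"),
            ss.spawn(5),
        )
    )

    # ---- stage 1: data -------------------------------------------------
    stage = "simulate" if config.design is not None else "load"
    try:
        if config.design is not None:
            cohort: CohortData = simulate_cohort(config.design)
            runs = cohort.runs
            behavior = cohort.behavior
            confounds_df = cohort.confounds
            families = cohort.families
        else:
            indir = Path(config.input_dir)
            runs = dio.load_run_dir(indir / "runs")
            behavior = pd.read_csv(indir / "behavior.tsv", sep="\t")
            confounds_df = pd.read_csv(indir / "confounds.tsv", sep="\t")
            families = pd.read_csv(indir / "families.tsv", sep="\t")
        log(stage, f"{len(runs)} subjects, {len(next(iter(runs.values())))} runs each")

        # ---- stage 2: eigenvector series -------------------------------
        stage = "le-series"
        le_series = {
            sid: [compute_le_series(ts) for ts in run_list]
            for sid, run_list in runs.items()
        }
        log(stage, "leading-eigenvector series computed")

        # ---- stage 3: state model ---------------------------------------
        stage = "fit-states"
        flat_keys = [
            f"{sid}__run{r}"
            for sid, arrs in le_series.items()
            for r in range(1, len(arrs) + 1)
        ]
        flat_series = [a.vectors for arrs in le_series.values() for a in arrs]
        model = fit_state_model(
            flat_series, config.k, n_restarts=config.n_restarts, seed=seeds["cluster"]
        )
        model = relabel_states(model)
        log(stage, f"k={config.k}, cost={model.total_cost:.2f}")

        # ---- stage 4: metrics -------------------------------------------
        stage = "metrics"
        labels: dict[str, list[np.ndarray]] = {}
        i = 0
        for sid, arrs in le_series.items():
            labels[sid] = [model.labels[i + r] for r in range(len(arrs))]
            i += len(arrs)
        vec_series = {
            sid: [a.vectors for a in arrs] for sid, arrs in le_series.items()
        }
        metrics_df, imput_log = compute_metric_table(
            vec_series, labels, model.medians
        )
        log(stage, f"{metrics_df.shape[1] - 1} metrics, "
                   f"{sum(imput_log.values())} imputed values in {len(imput_log)} columns")

        # ---- stage 5: PLSC suite ----------------------------------------
        stage = "plsc"
        order = metrics_df["subject_id"].tolist()
        behavior = behavior.set_index("subject_id").loc[order].reset_index()
        confounds_df = confounds_df.set_index("subject_id").loc[order].reset_index()
        family_ids = (
            families.set_index("subject_id").loc[order, "family_id"].to_numpy()
        )
        X_raw = metrics_df.drop(columns="subject_id").to_numpy(dtype=float)
        x_names = [c for c in metrics_df.columns if c != "subject_id"]
        dropped = [x_names[j] for j in range(X_raw.shape[1])
                   if not np.all(np.isfinite(X_raw[:, j]))]
        keep = [j for j, name in enumerate(x_names) if name not in dropped]
        if dropped:
            log(stage, f"dropped all-undefined metric columns: {dropped}")
        X_raw = X_raw[:, keep]
        Y_raw = behavior.drop(columns="subject_id").to_numpy(dtype=float)
        conf = confounds_df[["age", "gender"]].to_numpy(dtype=float)

        Xp, _ = residualize_and_standardize(
            X_raw, conf, column_names=[x_names[j] for j in keep]
        )
        Yp, _ = residualize_and_standardize(Y_raw, conf)
        fit = plsc_fit(Xp, Yp)
        perm = permutation_test(
            Xp, Yp, family_ids, n_perm=config.n_perm, seed=seeds["perm"]
        )
        boot = bootstrap_ratios(
            X_raw, Y_raw, family_ids,
            n_boot=config.n_boot, seed=seeds["boot"], confounds=conf,
        )
        split = splithalf_reproducibility(
            X_raw, Y_raw, family_ids,
            n_split=config.n_split, seed=seeds["split"], confounds=conf,
        )
        cv = cross_validate(
            X_raw, Y_raw, conf, family_ids,
            n_folds=config.n_folds, seed=seeds["cv"],
        )
        # variance explained by the significant dimensions only (using all
        # min(p, q) score columns would trivially span the smaller block)
        sig = np.where(perm.pvalues < 0.05)[0]
        if sig.size == 0:
            sig = np.array([0])
        vex = variance_explained(Xp, fit.x_scores[:, sig])
        vey = variance_explained(Yp, fit.y_scores[:, sig])
        log(stage, f"dim-1 SV={fit.singular_values[0]:.3f}, "
                   f"p={perm.pvalues[0]:.4g}")
    except Exception as err:
        log(stage, f"FAILED: {err}")
        (outdir / "pipeline.log").write_text("\n".join(log_lines) + "\n")
        raise RuntimeError(f"pipeline stage '{stage}' failed: {err}") from err

    # ---- artifacts ------------------------------------------------------
    metrics_df.to_csv(outdir / "metrics.tsv", sep="\t", index=False,
                      float_format="%.10g")
    dio.write_state_model(outdir / "state_model.npz", model, flat_keys)
    pd.DataFrame(
        fit.x_weights,
        index=[x_names[j] for j in keep],
        columns=[f"dim_{d + 1}" for d in range(fit.n_dimensions)],
    ).to_csv(outdir / "x_weights.tsv", sep="\t", index_label="metric")
    pd.DataFrame(
        boot.bootstrap_ratios,
        index=[x_names[j] for j in keep]
        + [c for c in behavior.columns if c != "subject_id"],
        columns=[f"dim_{d + 1}" for d in range(fit.n_dimensions)],
    ).to_csv(outdir / "bootstrap_ratios.tsv", sep="\t", index_label="variable")
    report = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "k": config.k,
        "singular_values": fit.singular_values,
        "covariance_explained": fit.covariance_explained,
        "latent_correlations": fit.latent_correlations,
        "perm_pvalues": perm.pvalues,
        "splithalf_z_sv": split.z_sv,
        "splithalf_z_x_weights": split.z_x_weights,
        "splithalf_z_y_weights": split.z_y_weights,
        "cv_oos_correlation": cv.oos_correlation,
        "cv_consistency_x": cv.consistency_x,
        "cv_consistency_y": cv.consistency_y,
        "variance_explained_x": vex,
        "variance_explained_y": vey,
        "imputation_log": imput_log,
        "dropped_columns": dropped,
    }
    dio.write_json(outdir / "plsc_report.json", report)
    log("done", "all artifacts written")
    (outdir / "pipeline.log").write_text("\n".join(log_lines) + "\n")

    return PipelineResult(
        metrics=metrics_df,
        state_model=model,
        plsc=fit,
        permutation=perm,
        bootstrap=boot,
        splithalf=split,
        cross_validation=cv,
        imputation_log=imput_log,
        dropped_columns=dropped,
        variance_explained_x=vex,
        variance_explained_y=vey,
    )
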