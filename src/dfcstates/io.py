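"""Delimited-text and array-container I/O for cohorts and results.

Runs are stored one TSV per run (rows = regions, first column the
region id); subject-level tables (behavior, confounds, families) are
TSVs keyed by ``subject_id``; ground truth and reports are JSON;
eigenvector series and state models use NumPy ``.npz`` containers.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .states import StateModel
from .synthetic import CohortData


def write_run(path: Path, ts: np.ndarray) -> None:
    """Write a region x time matrix with a region-id index column."""
    df = pd.DataFrame(
        ts, index=[f"region_{i:03d}" for i in range(ts.shape[0])]
    )
    df.columns = [f"t{j:05d}" for j in range(ts.shape[1])]
    df.to_csv(path, sep="\t", index_label="region_id", float_format="%.10g")


def read_run(path: Path) -> np.ndarray:
    df = pd.read_csv(path, sep="\t", index_col="region_id")
    return df.to_numpy(dtype=float)


def write_cohort(cohort: CohortData, outdir: Path) -> None:
    """Serialize a synthetic cohort: runs, tables, truth sidecar."""
    outdir = Path(outdir)
    rundir = outdir / "runs"
    rundir.mkdir(parents=True, exist_ok=True)
    for sid, run_list in cohort.runs.items():
        for r, ts in enumerate(run_list, start=1):
            write_run(rundir / f"{sid}_run-{r}.tsv", ts)
    cohort.behavior.to_csv(outdir / "behavior.tsv", sep="\t", index=False)
    cohort.confounds.to_csv(outdir / "confounds.tsv", sep="\t", index=False)
    cohort.families.to_csv(outdir / "families.tsv", sep="\t", index=False)
    truth = {
        "stay_bias": cohort.truth.stay_bias.tolist(),
        "idio_scale": cohort.truth.idio_scale.tolist(),
        "latent_cognition": cohort.truth.latent_cognition.tolist(),
        "labels": {
            sid: [lab.tolist() for lab in labs]
            for sid, labs in cohort.truth.labels.items()
        },
        "patterns": [p.offsets.tolist() for p in cohort.truth.patterns],
    }
    (outdir / "truth.json").write_text(json.dumps(truth))


def load_run_dir(rundir: Path) -> dict[str, list[np.ndarray]]:
    """Load all ``<subject>_run-<r>.tsv`` files, grouped by subject.

    Region order must match across runs; checked via the id column.
    """
    rundir = Path(rundir)
    runs: dict[str, list[tuple[int, np.ndarray, list[str]]]] = {}
    for path in sorted(rundir.glob("*_run-*.tsv")):
        sid, run_tag = path.stem.rsplit("_run-", 1)
        df = pd.read_csv(path, sep="\t", index_col="region_id")
        runs.setdefault(sid, []).append(
            (int(run_tag), df.to_numpy(dtype=float), list(df.index))
        )
    out: dict[str, list[np.ndarray]] = {}
    region_ids: list[str] | None = None
    for sid, entries in runs.items():
        entries.sort(key=lambda e: e[0])
        for _, ts, ids in entries:
            if region_ids is None:
                region_ids = ids
            elif ids != region_ids:
                raise ValueError(f"region order mismatch in runs of {sid}")
        out[sid] = [ts for _, ts, _ in entries]
    return out


def write_le_series(path: Path, series: dict[str, list[np.ndarray]]) -> None:
    """Store per-run eigenvector series in one .npz container."""
    arrays = {
        f"{sid}__run{r}": arr
        for sid, arrs in series.items()
        for r, arr in enumerate(arrs, start=1)
    }
    np.savez_compressed(path, **arrays)


def read_le_series(path: Path) -> dict[str, list[np.ndarray]]:
    data = np.load(path)
    series: dict[str, list[tuple[int, np.ndarray]]] = {}
    for key in data.files:
        sid, run_tag = key.rsplit("__run", 1)
        series.setdefault(sid, []).append((int(run_tag), data[key]))
    return {
        sid: [a for _, a in sorted(v)] for sid, v in series.items()
    }


def write_state_model(path: Path, model: StateModel, keys: list[str]) -> None:
    np.savez_compressed(
        path,
        medians=model.medians,
        total_cost=np.array([model.total_cost]),
        keys=np.array(keys),
        **{f"labels_{i}": lab for i, lab in enumerate(model.labels)},
    )


def read_state_model(path: Path) -> tuple[StateModel, list[str]]:
    data = np.load(path, allow_pickle=False)
    medians = data["medians"]
    n = sum(1 for f in data.files if f.startswith("labels_"))
    labels = [data[f"labels_{i}"] for i in range(n)]
    model = StateModel(
        k=medians.shape[0],
        medians=medians,
        total_cost=float(data["total_cost"][0]),
        labels=labels,
    )
    return model, [str(k) for k in data["keys"]]


def write_json(path: Path, obj: dict) -> None:
    def default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        raise TypeError(f"not JSON-serializable: {type(o)}")

    Path(path).write_text(json.dumps(obj, indent=1, default=default))
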