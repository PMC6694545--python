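"""Cohort and report file I/O.

Cohorts are stored as two CSVs with a one-line ``# schema=v1`` comment header:
``subjects.csv`` (id, arm, categorical covariates, X_years, D) and ``labs.csv``
(id, time_years, glucose_mgdl, hba1c_pct). Times are decimal years from
randomization.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import Cohort
from .exceptions import SchemaError

SCHEMA_LINE = "# schema=v1"

SUBJECT_COLUMNS = ["id", "arm", "age_group", "gender", "bmi_group",
                   "smoking", "race", "X_years", "D"]
LAB_COLUMNS = ["id", "time_years", "glucose_mgdl", "hba1c_pct"]

__all__ = ["read_cohort", "write_cohort", "write_report", "read_report"]


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write(SCHEMA_LINE + "\n")
        # %.17g guarantees exact float64 round-trips through text
        df.to_csv(fh, index=False, float_format="%.17g")


def write_cohort(cohort: Cohort, out_dir) -> dict:
    """Write subjects.csv and labs.csv; returns the file paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    subj = cohort.subjects.rename(columns={"X": "X_years"})
    subj = subj[[c for c in SUBJECT_COLUMNS if c in subj.columns]]
    labs = cohort.labs[LAB_COLUMNS]
    paths = {"subjects": out_dir / "subjects.csv", "labs": out_dir / "labs.csv"}
    _write_csv(subj, paths["subjects"])
    _write_csv(labs, paths["labs"])
    return paths


def read_cohort(subjects_path, labs_path) -> Cohort:
    """Read and validate a cohort from its two CSV files."""
    try:
        subjects = pd.read_csv(subjects_path, comment="#",
                               float_precision="round_trip")
        labs = pd.read_csv(labs_path, comment="#",
                           float_precision="round_trip")
    except FileNotFoundError as err:
        raise SchemaError(str(err)) from err

    missing = [c for c in SUBJECT_COLUMNS if c not in subjects.columns]
    if missing:
        raise SchemaError(f"subjects file missing columns {missing}")
    missing = [c for c in LAB_COLUMNS if c not in labs.columns]
    if missing:
        raise SchemaError(f"labs file missing columns {missing}")

    bad_d = subjects[~subjects["D"].isin([0, 1])]
    if len(bad_d):
        raise SchemaError(f"D must be 0/1; offending ids: {bad_d['id'].tolist()[:10]}")
    if (subjects["X_years"] <= 0).any():
        bad = subjects.loc[subjects["X_years"] <= 0, "id"].tolist()[:10]
        raise SchemaError(f"X_years must be > 0; offending ids: {bad}")
    if (labs["time_years"] < 0).any():
        raise SchemaError("lab times must be >= 0")
    known = set(subjects["id"])
    orphan = sorted(set(labs["id"]) - known)
    if orphan:
        raise SchemaError(f"labs reference unknown subject ids: {orphan[:10]}")
    dup = labs.duplicated(subset=["id", "time_years"])
    if dup.any():
        rows = labs.loc[dup, ["id", "time_years"]].head(10).to_dict("records")
        raise SchemaError(f"duplicated (id, time) lab rows: {rows}")

    subjects = subjects.rename(columns={"X_years": "X"})
    labs = labs.sort_values(["id", "time_years"], kind="mergesort")
    arms = subjects["arm"].unique()
    arm = arms[0] if len(arms) == 1 else "mixed"
    return Cohort(subjects, labs, arm=str(arm))


def write_predictions(predictions: pd.DataFrame, path) -> None:
    _write_csv(predictions[["id", "arm", "t0", "tau", "model", "p_hat"]], Path(path))


def write_report(report, out_dir) -> dict:
    """Write report.json, report.csv and a metrics-vs-t0 plot."""
    from .protocol import StudyReport  # local import avoids a cycle

    if not isinstance(report, StudyReport):
        raise TypeError("expected a StudyReport")
    if len(report.metrics) == 0:
        raise ValueError("report has no metric rows")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    paths = {
        "json": out_dir / "report.json",
        "csv": out_dir / "report.csv",
        "plot": out_dir / "report.png",
    }
    with open(paths["json"], "w") as fh:
        json.dump(report.to_dict(), fh, indent=1, default=float)

    flat = []
    for _, r in report.metrics.iterrows():
        flat.append({"section": "metric", **r.to_dict()})
    for _, r in report.hl.iterrows():
        flat.append({"section": "hl", **r.to_dict()})
    for _, r in report.nri.iterrows():
        flat.append({"section": "nri", **r.to_dict()})
    pd.DataFrame(flat).to_csv(paths["csv"], index=False)

    _plot_report(report, paths["plot"])
    return paths


def _plot_report(report, path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 2, figsize=(10, 4))
    for metric, ax in zip(("auc", "brier"), axes):
        sub = report.metrics[report.metrics["metric"] == metric]
        for arm, arm_df in sub.groupby("arm"):
            arm_df = arm_df.sort_values("t0")
            ax.plot(arm_df["t0"], arm_df["static"], marker="o", linestyle="--",
                    label=f"{arm} static")
            ax.plot(arm_df["t0"], arm_df["dynamic"], marker="s",
                    label=f"{arm} dynamic")
        ax.set_xlabel("landmark time $t_0$ (years)")
        ax.set_ylabel(metric.upper() if metric == "auc" else "Brier score")
        ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def read_report(path):
    from .protocol import StudyReport

    with open(path) as fh:
        return StudyReport.from_dict(json.load(fh))
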