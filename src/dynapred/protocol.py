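"""Repeated-split cross-validation, bootstrap comparison and the full study.

The comparison protocol: at each landmark time fit the static (baseline) and
dynamic (landmark) models on a random 2/3 training sample, predict survival to
``tau = t0 + horizon`` for the held-out 1/3, score with IPCW metrics, repeat
and average; subject-level bootstrap (within arm) yields percentile CIs and
p-values for the dynamic-minus-static differences.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from . import landmark, metrics
from .exceptions import (
    ConvergenceError,
    DynapredError,
    NoEventsError,
    UndefinedMetricError,
)
from .metrics import AccuracyEstimate, NRIComponents

__all__ = [
    "ProtocolConfig",
    "StudyReport",
    "split_train_test",
    "cross_validated_metric",
    "cv_estimates",
    "bootstrap_difference",
    "run_full_study",
    "static_dynamic_difference",
]


@dataclass(frozen=True)
class ProtocolConfig:
    t0_list: tuple = (0.0, 1.0, 2.0, 3.0)
    horizon: float = 2.0
    cv_reps: int = 100
    cv_train_fraction: float = 2.0 / 3.0
    bootstrap_reps: int = 500
    bootstrap_cv_reps: int = 10  # reduced CV depth inside each bootstrap draw
    seed: int = 0
    resubstitution: bool = False  # debug: train == test == full data

    def __post_init__(self):
        if not 0 < self.cv_train_fraction < 1:
            raise ValueError("train fraction must be in (0, 1)")
        if self.cv_reps < 1 or self.bootstrap_reps < 0:
            raise ValueError("repetition counts must be positive")
        if self.horizon <= 0:
            raise ValueError("horizon must be > 0")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["t0_list"] = list(self.t0_list)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ProtocolConfig":
        d = dict(d)
        if "t0_list" in d:
            d["t0_list"] = tuple(float(v) for v in d["t0_list"])
        return cls(**d)


def static_dynamic_difference(dynamic_value: float, static_value: float) -> float:
    """The report's difference convention: dynamic minus static."""
    return dynamic_value - static_value


def split_train_test(ids, fraction: float, rng: np.random.Generator):
    """Disjoint, exhaustive subject-level split; train size round(n * fraction)."""
    if not 0 < fraction < 1:
        raise ValueError("fraction must be in (0, 1)")
    ids = np.asarray(ids)
    n = len(ids)
    if n < 3:
        raise ValueError("need at least 3 subjects to split")
    n_train = int(round(n * fraction))
    n_train = min(max(n_train, 1), n - 1)
    perm = rng.permutation(ids)
    return perm[:n_train], perm[n_train:]


def _rep_estimates(frame0, frame_t0, train_ids, test_ids, tau):
    """Fit on train, predict on test, score: one CV repetition."""
    static_fit = landmark.fit_landmark_model(frame0.subset(train_ids))
    dynamic_fit = landmark.fit_landmark_model(frame_t0.subset(train_ids))
    test = frame_t0.subset(test_ids)
    pred_d = landmark.predict_dynamic(dynamic_fit, test, tau)
    pred_s = landmark.predict_static_at_landmark(static_fit, test, tau)
    G = metrics.censoring_km(test)
    out = {}
    for tag, pred in (("static", pred_s), ("dynamic", pred_d)):
        out[f"auc_{tag}"] = metrics.auc_ipcw(pred, test, tau, G=G).value
        out[f"brier_{tag}"] = metrics.brier_ipcw(pred, test, tau, G=G).value
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                out[f"hl_{tag}"] = metrics.hl_statistic(pred, test, tau, G=G).value
        except UndefinedMetricError:
            # calibration strata degenerate (e.g. tied predictions); the
            # discrimination metrics for this repetition remain valid
            out[f"hl_{tag}"] = np.nan
    out["nri"] = metrics.nri_components(pred_d, pred_s, test, tau, G=G)
    return out


def cv_estimates(cohort, t0: float, config: ProtocolConfig,
                 rng: np.random.Generator | None = None,
                 cv_reps: int | None = None) -> tuple[list, int]:
    """All per-repetition metric estimates at one landmark time.

    Returns ``(reps, n_skipped)``: ``reps`` is a list of dicts with keys
    ``auc_static``, ``auc_dynamic``, ``brier_*``, ``hl_*`` and ``nri``
    (an :class:`NRIComponents`). Repetitions whose test split lacks cases,
    controls or events are skipped with a warning.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    reps = config.cv_reps if cv_reps is None else cv_reps
    tau = t0 + config.horizon
    frame0 = landmark.build_landmark_frame(
        cohort, 0.0, config.horizon, spec=landmark.static_spec()
    )
    frame_t0 = landmark.build_landmark_frame(cohort, t0, config.horizon)
    # split on the full baseline frame: the static fit uses all training
    # subjects while the landmark frames select their own risk sets
    base_ids = frame0.data["id"].to_numpy()
    out = []
    skipped = 0
    for _ in range(reps):
        if config.resubstitution:
            train_ids = test_ids = base_ids
        else:
            train_ids, test_ids = split_train_test(
                base_ids, config.cv_train_fraction, rng
            )
        try:
            out.append(_rep_estimates(frame0, frame_t0, train_ids, test_ids, tau))
        except (UndefinedMetricError, NoEventsError, ConvergenceError) as err:
            skipped += 1
            warnings.warn(f"skipping CV repetition at t0={t0}: {err}", stacklevel=2)
    if not out:
        raise DynapredError(f"all {reps} CV repetitions failed at t0={t0}")
    return out, skipped


def cross_validated_metric(cohort, t0: float, tau: float | None,
                           model_kind: str, metric: str,
                           config: ProtocolConfig,
                           rng: np.random.Generator | None = None) -> AccuracyEstimate:
    """Mean over CV repetitions of one metric for one model."""
    if model_kind not in ("static", "dynamic"):
        raise ValueError("model_kind must be 'static' or 'dynamic'")
    if metric not in ("auc", "brier", "hl"):
        raise ValueError("metric must be one of auc, brier, hl")
    if tau is not None and not np.isclose(tau, t0 + config.horizon):
        raise ValueError("tau must equal t0 + horizon")
    reps, _ = cv_estimates(cohort, t0, config, rng)
    values = np.asarray([r[f"{metric}_{model_kind}"] for r in reps])
    est = AccuracyEstimate(metric, float(values.mean()), t0, t0 + config.horizon,
                           model_tag=model_kind, n_eff=float(len(values)))
    est.rep_values = values  # retained for diagnostics
    return est


def _mean_rep_summary(reps) -> dict:
    """Averages of every metric (and NRI components) over CV repetitions."""
    summary = {}
    for key in ("auc_static", "auc_dynamic", "brier_static", "brier_dynamic"):
        summary[key] = float(np.mean([r[key] for r in reps]))
    for key in ("hl_static", "hl_dynamic"):
        vals = np.asarray([r[key] for r in reps])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            summary[key] = float(np.nanmean(vals)) if np.any(
                np.isfinite(vals)
            ) else np.nan
    comp = np.array(
        [[r["nri"].up_events, r["nri"].down_events,
          r["nri"].up_nonevents, r["nri"].down_nonevents] for r in reps]
    ).mean(axis=0)
    summary["nri_components"] = NRIComponents(*comp)
    return summary


def _percentile_ci_p(draws: np.ndarray):
    lo, hi = np.percentile(draws, [2.5, 97.5])
    frac_le = np.mean(draws <= 0)
    frac_ge = np.mean(draws >= 0)
    p = min(1.0, 2 * min(frac_le, frac_ge) + 1.0 / (len(draws) + 1))
    return (float(lo), float(hi)), float(p)


def bootstrap_difference(cohort, t0: float, tau: float | None, metric: str,
                         config: ProtocolConfig,
                         rng: np.random.Generator | None = None) -> dict:
    """Subject-level bootstrap of the dynamic-minus-static metric difference.

    Each of ``bootstrap_reps`` resamples re-runs the CV procedure (with the
    reduced ``bootstrap_cv_reps`` depth) on a with-replacement copy of the
    cohort; percentile CI and a two-sided bootstrap p-value are returned.
    """
    if metric not in ("auc", "brier", "nri"):
        raise ValueError("metric must be auc, brier or nri")
    rng = np.random.default_rng(config.seed) if rng is None else rng
    point_reps, _ = cv_estimates(cohort, t0, config, rng)
    summary = _mean_rep_summary(point_reps)
    if metric == "nri":
        point = summary["nri_components"].nri
    else:
        point = static_dynamic_difference(
            summary[f"{metric}_dynamic"], summary[f"{metric}_static"]
        )
    draws = []
    for _ in range(config.bootstrap_reps):
        boot = cohort.resample(rng)
        try:
            reps, _ = cv_estimates(boot, t0, config, rng,
                                   cv_reps=config.bootstrap_cv_reps)
        except DynapredError as err:
            warnings.warn(f"skipping bootstrap resample: {err}", stacklevel=2)
            continue
        s = _mean_rep_summary(reps)
        if metric == "nri":
            draws.append(s["nri_components"].nri)
        else:
            draws.append(static_dynamic_difference(
                s[f"{metric}_dynamic"], s[f"{metric}_static"]
            ))
    draws = np.asarray(draws)
    if draws.size == 0:
        raise DynapredError("all bootstrap resamples failed")
    ci, p = _percentile_ci_p(draws)
    return {"difference": point, "ci": ci, "p": p, "draws": draws}


@dataclass
class StudyReport:
    """Full static-vs-dynamic comparison across arms and landmark times."""

    metrics: pd.DataFrame   # arm, t0, tau, metric, static, dynamic, difference, ci, p
    hl: pd.DataFrame        # arm, t0, tau, model, statistic, df, p
    nri: pd.DataFrame       # arm, t0, tau, components, nri, ci, p
    meta: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "metrics": self.metrics.to_dict(orient="records"),
            "hl": self.hl.to_dict(orient="records"),
            "nri": self.nri.to_dict(orient="records"),
            "meta": self.meta,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "StudyReport":
        return cls(
            metrics=pd.DataFrame(d["metrics"]),
            hl=pd.DataFrame(d["hl"]),
            nri=pd.DataFrame(d["nri"]),
            meta=d.get("meta", {}),
        )


def _config_hash(config: ProtocolConfig) -> str:
    return hashlib.sha256(
        json.dumps(config.to_dict(), sort_keys=True).encode()
    ).hexdigest()[:12]


def run_full_study(cohorts, config: ProtocolConfig) -> StudyReport:
    """Run the complete protocol per arm and landmark time.

    ``cohorts`` maps arm label -> cohort (a single cohort is treated as one
    arm). For every (arm, t0): CV AUC/Brier for both models with bootstrap CI
    and p for the difference, HL statistics (CV-averaged) with chi-squared
    p-values, and NRI components with bootstrap CI.
    """
    if not isinstance(cohorts, dict):
        cohorts = {getattr(cohorts, "arm", "all"): cohorts}
    root = np.random.SeedSequence(config.seed)
    metric_rows, hl_rows, nri_rows = [], [], []
    skipped_total = 0
    for (arm, cohort), arm_seq in zip(sorted(cohorts.items()),
                                      root.spawn(len(cohorts))):
        for t0, t0_seq in zip(config.t0_list, arm_seq.spawn(len(config.t0_list))):
            rng = np.random.default_rng(t0_seq)
            tau = t0 + config.horizon
            try:
                reps, skipped = cv_estimates(cohort, t0, config, rng)
            except DynapredError as err:
                raise DynapredError(f"arm={arm} t0={t0}: {err}") from err
            skipped_total += skipped
            summary = _mean_rep_summary(reps)

            # bootstrap all three differences in one pass over resamples
            boot = {"auc": [], "brier": [], "nri": []}
            for _ in range(config.bootstrap_reps):
                resampled = cohort.resample(rng)
                try:
                    b_reps, _ = cv_estimates(resampled, t0, config, rng,
                                             cv_reps=config.bootstrap_cv_reps)
                except DynapredError:
                    continue
                s = _mean_rep_summary(b_reps)
                boot["auc"].append(static_dynamic_difference(
                    s["auc_dynamic"], s["auc_static"]))
                boot["brier"].append(static_dynamic_difference(
                    s["brier_dynamic"], s["brier_static"]))
                boot["nri"].append(s["nri_components"].nri)

            for metric in ("auc", "brier"):
                stat_v = summary[f"{metric}_static"]
                dyn_v = summary[f"{metric}_dynamic"]
                row = {
                    "arm": arm, "t0": t0, "tau": tau, "metric": metric,
                    "static": stat_v, "dynamic": dyn_v,
                    "difference": static_dynamic_difference(dyn_v, stat_v),
                    "ci_lo": np.nan, "ci_hi": np.nan, "p": np.nan,
                }
                if boot[metric]:
                    (row["ci_lo"], row["ci_hi"]), row["p"] = _percentile_ci_p(
                        np.asarray(boot[metric])
                    )
                metric_rows.append(row)
            for tag in ("static", "dynamic"):
                hl_rows.append({
                    "arm": arm, "t0": t0, "tau": tau, "model": tag,
                    "statistic": summary[f"hl_{tag}"], "df": 4,
                    "p": metrics.chisq_pvalue(summary[f"hl_{tag}"], 4),
                })
            comp = summary["nri_components"]
            nri_row = {
                "arm": arm, "t0": t0, "tau": tau,
                "up_e": comp.up_events, "down_e": comp.down_events,
                "up_ne": comp.up_nonevents, "down_ne": comp.down_nonevents,
                "nri": comp.nri, "ci_lo": np.nan, "ci_hi": np.nan, "p": np.nan,
            }
            if boot["nri"]:
                (nri_row["ci_lo"], nri_row["ci_hi"]), nri_row["p"] = \
                    _percentile_ci_p(np.asarray(boot["nri"]))
            nri_rows.append(nri_row)

    meta = {
        "seed": config.seed,
        "config": config.to_dict(),
        "config_hash": _config_hash(config),
        "skipped_cv_reps": skipped_total,
        "arms": sorted(cohorts),
    }
    return StudyReport(
        metrics=pd.DataFrame(metric_rows),
        hl=pd.DataFrame(hl_rows),
        nri=pd.DataFrame(nri_rows),
        meta=meta,
    )
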