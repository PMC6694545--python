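"""Landmark risk sets, updated model fits, and static/dynamic predictions.

At each landmark time ``t0`` the risk set contains subjects still event-free
and uncensored at ``t0``. Covariates are baseline categoricals, baseline lab
values, and (for ``t0 > 0``) the change in each lab from baseline to ``t0``
(last observation carried forward). The updated ("dynamic") model is refit on
the risk set; the "static" comparator is a single baseline fit whose lab slots
are filled with the current values — with no conditioning on survival to
``t0``, mirroring how one-time risk equations are used in practice.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import cox
from .cox import CovariateSpec, CoxModelFit
from .exceptions import EmptyRiskSetError

__all__ = [
    "LandmarkFrame",
    "baseline_covariate_spec",
    "static_spec",
    "dynamic_spec",
    "extract_current_labs",
    "build_landmark_frame",
    "fit_landmark_model",
    "fit_static_model",
    "predict_dynamic",
    "predict_static_at_landmark",
]

CATEGORICAL_BLOCKS = {
    "age_group": (("<40", "40-44", "45-49", "50-54", "55-59", "60-64", "65+"), "<40"),
    "gender": (("male", "female"), "male"),
    "bmi_group": (("<30", "30-35", "35+"), "<30"),
    "smoking": (("yes", "no", "not_available"), "no"),
    "race": (("white", "black", "hispanic", "other"), "white"),
}


def baseline_covariate_spec() -> dict:
    return dict(CATEGORICAL_BLOCKS)


def static_spec() -> CovariateSpec:
    """Baseline categoricals plus the two lab slots (filled with baseline
    values when fitting; with current values when predicting at t0 > 0)."""
    return CovariateSpec(
        categorical=dict(CATEGORICAL_BLOCKS),
        numeric=("glucose", "hba1c"),
    )


def dynamic_spec() -> CovariateSpec:
    """Baseline categoricals + baseline labs + change-from-baseline labs."""
    return CovariateSpec(
        categorical=dict(CATEGORICAL_BLOCKS),
        numeric=("glucose", "hba1c", "glucose_change", "hba1c_change"),
    )


@dataclass
class LandmarkFrame:
    """Risk set at ``t0`` with assembled covariates.

    ``data`` columns: id, X, D, the categorical covariates, ``glucose`` /
    ``hba1c`` (baseline values), ``glucose_t0`` / ``hba1c_t0`` (carried-forward
    values at t0) and ``glucose_change`` / ``hba1c_change``. ``excluded``
    records (id, reason) for subjects removed from the risk set.
    """

    t0: float
    horizon: float
    data: pd.DataFrame
    excluded: pd.DataFrame
    spec: CovariateSpec = field(default_factory=dynamic_spec)

    @property
    def tau(self) -> float:
        return self.t0 + self.horizon

    def __len__(self) -> int:
        return len(self.data)

    def subset(self, ids) -> "LandmarkFrame":
        ids = np.asarray(ids)
        return LandmarkFrame(
            t0=self.t0,
            horizon=self.horizon,
            data=self.data[self.data["id"].isin(ids)].reset_index(drop=True),
            excluded=self.excluded,
            spec=self.spec,
        )


def extract_current_labs(labs: pd.DataFrame, t0: float):
    """Last (glucose, hba1c) measurement at or before ``t0`` (carry-forward).

    Returns ``(nan, nan)``-containing tuple entries when no measurement of
    that lab exists at or before ``t0``.
    """
    at_or_before = labs[labs["time_years"] <= t0]
    glucose = np.nan
    hba1c = np.nan
    g = at_or_before["glucose_mgdl"].dropna()
    if len(g):
        glucose = float(g.iloc[-1])
    h = at_or_before["hba1c_pct"].dropna()
    if len(h):
        hba1c = float(h.iloc[-1])
    return glucose, hba1c


def _locf(labs: pd.DataFrame, col: str, t0: float) -> pd.Series:
    """Per-subject last non-missing value of ``col`` at or before t0."""
    sel = labs[(labs["time_years"] <= t0) & labs[col].notna()]
    sel = sel.sort_values(["id", "time_years"], kind="mergesort")
    return sel.groupby("id")[col].last()


def build_landmark_frame(cohort, t0: float, horizon: float = 2.0,
                         spec: CovariateSpec | None = None) -> LandmarkFrame:
    """Assemble the risk set at ``t0`` with change-from-baseline covariates."""
    if t0 < 0:
        raise ValueError("t0 must be >= 0")
    subj = cohort.subjects
    labs = cohort.labs

    reasons = {}
    at_risk = subj["X"] > t0
    for row in subj[~at_risk].itertuples(index=False):
        reasons[row.id] = "event_before_t0" if row.D == 1 else "censored_before_t0"

    base_g = _locf(labs, "glucose_mgdl", 0.0)
    base_h = _locf(labs, "hba1c_pct", 0.0)
    cur_g = _locf(labs, "glucose_mgdl", t0)
    cur_h = _locf(labs, "hba1c_pct", t0)

    rows = subj[at_risk].copy()
    rows["glucose"] = rows["id"].map(base_g)
    rows["hba1c"] = rows["id"].map(base_h)
    rows["glucose_t0"] = rows["id"].map(cur_g)
    rows["hba1c_t0"] = rows["id"].map(cur_h)

    missing = rows[["glucose", "hba1c", "glucose_t0", "hba1c_t0"]].isna().any(axis=1)
    for sid in rows.loc[missing, "id"]:
        reasons[sid] = "missing_baseline_lab"
    rows = rows[~missing].copy()
    if len(rows) == 0:
        raise EmptyRiskSetError(f"no subjects at risk at t0={t0}")

    rows["glucose_change"] = rows["glucose_t0"] - rows["glucose"]
    rows["hba1c_change"] = rows["hba1c_t0"] - rows["hba1c"]
    if t0 == 0:
        rows["glucose_change"] = 0.0
        rows["hba1c_change"] = 0.0

    excluded = pd.DataFrame(
        {"id": list(reasons), "reason": list(reasons.values())}
    ).sort_values("id").reset_index(drop=True)
    keep_cols = ["id", "arm", "X", "D", *CATEGORICAL_BLOCKS,
                 "glucose", "hba1c", "glucose_t0", "hba1c_t0",
                 "glucose_change", "hba1c_change"]
    keep_cols = [c for c in keep_cols if c in rows.columns]
    return LandmarkFrame(
        t0=float(t0),
        horizon=float(horizon),
        data=rows[keep_cols].reset_index(drop=True),
        excluded=excluded,
        spec=spec if spec is not None else dynamic_spec(),
    )


def fit_landmark_model(frame: LandmarkFrame, ties_method: str = "efron") -> CoxModelFit:
    """Fit the updated Cox model on the landmark risk set.

    At ``t0 = 0`` the change columns are constant zero and get dropped, so the
    fit coincides exactly with the static (baseline) model on the same data.
    """
    import warnings

    with warnings.catch_warnings():
        if frame.t0 == 0:
            warnings.filterwarnings(
                "ignore", message="dropping constant", category=UserWarning
            )
        return cox.fit_cox(frame, frame.spec, ties_method=ties_method)


def fit_static_model(cohort, horizon: float = 2.0,
                     ties_method: str = "efron") -> CoxModelFit:
    """Single baseline Cox fit on all subjects with baseline covariates."""
    frame = build_landmark_frame(cohort, 0.0, horizon, spec=static_spec())
    return cox.fit_cox(frame, static_spec(), ties_method=ties_method)


def _predictions_df(frame: LandmarkFrame, tau: float, model_tag: str,
                    p_hat: np.ndarray, extrapolated: bool) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "id": frame.data["id"].to_numpy(),
            "arm": frame.data["arm"].to_numpy() if "arm" in frame.data else "",
            "t0": frame.t0,
            "tau": tau,
            "model": model_tag,
            "p_hat": p_hat,
            "extrapolated": extrapolated,
        }
    )


def predict_dynamic(fit: CoxModelFit, frame: LandmarkFrame,
                    tau: float | None = None) -> pd.DataFrame:
    """Survival-to-tau predictions from the landmark fit for frame members."""
    if tau is None:
        tau = frame.tau
    if fit.t0 != frame.t0:
        raise ValueError(f"fit t0={fit.t0} does not match frame t0={frame.t0}")
    Z = fit.design(frame.data)
    p = cox.predict_survival(fit, Z, tau)
    return _predictions_df(frame, tau, "dynamic", np.atleast_1d(p),
                           cox.is_extrapolated(fit, tau))


def predict_static_at_landmark(static_fit: CoxModelFit, frame: LandmarkFrame,
                               tau: float | None = None,
                               conditional: bool = False) -> pd.DataFrame:
    """Predictions from the single baseline model with updated lab values.

    The default (``conditional=False``) returns the unconditional
    P(T > tau | Z-tilde) where Z-tilde carries the labs observed at ``t0`` in
    the baseline-lab slots; ``conditional=True`` instead applies the
    conditional-survival transformation of the same baseline fit.
    """
    if tau is None:
        tau = frame.tau
    if static_fit.t0 != 0:
        raise ValueError("the static comparator must be a baseline (t0=0) fit")
    shifted = frame.data.copy()
    shifted["glucose"] = shifted["glucose_t0"]
    shifted["hba1c"] = shifted["hba1c_t0"]
    Z = static_fit.design(shifted)
    if conditional:
        p = cox.conditional_survival_static(static_fit, Z, frame.t0, tau)
    else:
        p = cox.predict_survival(static_fit, Z, tau)
    return _predictions_df(frame, tau, "static", np.atleast_1d(p),
                           cox.is_extrapolated(static_fit, tau))
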