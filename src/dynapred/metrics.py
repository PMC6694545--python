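"""Censoring-robust prediction-accuracy metrics.

Inverse-probability-of-censoring-weighted (IPCW) AUC, Brier score, a
survival-data extension of the Hosmer-Lemeshow calibration statistic, and the
continuous net reclassification improvement, all evaluated for predictions of
survival from a landmark time ``t0`` to a horizon ``tau``.

Risk orientation: every function consumes *survival* probabilities ``p_hat``;
"higher risk" always means lower ``p_hat``. The single conversion to risk
(``1 - p_hat``) happens inside this module.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .exceptions import UndefinedMetricError
from .stepfun import StepFunction

__all__ = [
    "AccuracyEstimate",
    "NRIComponents",
    "censoring_km",
    "ipcw_weights",
    "auc_ipcw",
    "brier_ipcw",
    "hl_statistic",
    "chisq_pvalue",
    "nri_components",
    "combine_nri",
]


@dataclass
class AccuracyEstimate:
    metric: str
    value: float
    t0: float
    tau: float
    model_tag: str = ""
    n_eff: float = np.nan
    ci: tuple | None = None
    p_value: float | None = None


@dataclass
class NRIComponents:
    """Reclassification percentages among events and non-events.

    ``up_*`` / ``down_*`` are the IPCW-weighted percentages whose risk under
    the new (dynamic) model is strictly higher / lower than under the old
    (static) model; exact ties are excluded from both and reported in
    ``tie_*``. Within each outcome group the three percentages sum to 100.
    """

    up_events: float
    down_events: float
    up_nonevents: float
    down_nonevents: float
    tie_events: float = 0.0
    tie_nonevents: float = 0.0

    @property
    def nri(self) -> float:
        return combine_nri(self.up_events, self.down_events,
                           self.up_nonevents, self.down_nonevents)


def _frame_arrays(frame):
    X = frame.data["X"].to_numpy(dtype=float)
    D = frame.data["D"].to_numpy(dtype=int)
    return X, D


def censoring_km(frame_or_X, D=None) -> StepFunction:
    """Kaplan-Meier of the censoring distribution (event indicator flipped).

    At tied event/censoring times the true events are kept in the censoring
    risk set (events occur "first"), the standard convention for IPCW.
    Accepts a landmark frame or raw ``(X, D)`` arrays.
    """
    if D is None:
        X, D = _frame_arrays(frame_or_X)
    else:
        X = np.asarray(frame_or_X, dtype=float)
        D = np.asarray(D, dtype=int)
    if len(X) == 0:
        raise UndefinedMetricError("empty frame")
    cens = 1 - D
    order = np.argsort(X, kind="mergesort")
    Xs, Cs = X[order], cens[order]
    times = np.unique(Xs[Cs == 1])
    if times.size == 0:
        return StepFunction(np.empty(0), np.empty(0), value_before=1.0)
    surv = np.empty_like(times)
    g = 1.0
    for k, t in enumerate(times):
        lo = np.searchsorted(Xs, t, side="left")
        hi = np.searchsorted(Xs, t, side="right")
        at_risk = len(Xs) - lo
        d = Cs[lo:hi].sum()
        g *= 1.0 - d / at_risk
        surv[k] = g
    return StepFunction(times, surv, value_before=1.0)


def ipcw_weights(X, D, G: StepFunction, t0: float, tau: float) -> np.ndarray:
    """Per-subject IPCW weights for the (t0, tau] evaluation window.

    Events in (t0, tau]: G(t0)/G(X-); survivors past tau: G(t0)/G(tau);
    subjects censored inside the window: 0. ``G`` is the Kaplan-Meier of the
    censoring distribution; evaluating at the left limit X- keeps weights
    finite for events tied with the last censoring time.
    """
    X = np.asarray(X, dtype=float)
    D = np.asarray(D, dtype=int)
    g_t0 = float(G(t0))
    if g_t0 <= 0:
        raise UndefinedMetricError(f"censoring survival is 0 at t0={t0}")
    w = np.zeros(len(X))
    is_event = (D == 1) & (X > t0) & (X <= tau)
    is_survivor = X > tau
    if np.any(is_event):
        g_x = np.asarray(G.left_limit(X[is_event]), dtype=float)
        if np.any(g_x <= 0):
            raise UndefinedMetricError("censoring survival 0 at an event time")
        w[is_event] = g_t0 / g_x
    if np.any(is_survivor):
        g_tau = float(G(tau))
        if g_tau <= 0:
            raise UndefinedMetricError(f"censoring survival is 0 at tau={tau}")
        w[is_survivor] = g_t0 / g_tau
    return w


def _align_predictions(predictions, frame):
    """p_hat aligned to frame rows; accepts a predictions DataFrame or array."""
    if hasattr(predictions, "columns"):
        mapping = dict(zip(predictions["id"], predictions["p_hat"]))
        ids = frame.data["id"].to_numpy()
        missing = [i for i in ids if i not in mapping]
        if missing:
            raise ValueError(f"predictions missing for ids {missing[:5]}...")
        return np.asarray([mapping[i] for i in ids], dtype=float)
    p = np.asarray(predictions, dtype=float)
    if len(p) != len(frame.data):
        raise ValueError("prediction vector length does not match frame")
    return p


def _weights_for(frame, t0, tau, G=None):
    X, D = _frame_arrays(frame)
    if G is None:
        G = censoring_km(X, D)
    return X, D, ipcw_weights(X, D, G, t0, tau)


def auc_ipcw(predictions, frame, tau: float | None = None,
             t0: float | None = None, G: StepFunction | None = None) -> AccuracyEstimate:
    """IPCW AUC: weighted P(p_case < p_control), prediction ties credited 1/2.

    Cases are events in (t0, tau]; controls survive past tau; each pair is
    weighted by the product of the two IPCW weights.
    """
    t0 = frame.t0 if t0 is None else t0
    tau = frame.tau if tau is None else tau
    if tau <= t0:
        raise ValueError("tau must exceed t0")
    p = _align_predictions(predictions, frame)
    X, D, w = _weights_for(frame, t0, tau, G)
    case = (D == 1) & (X > t0) & (X <= tau)
    ctrl = X > tau
    if not case.any():
        raise UndefinedMetricError(f"no events in ({t0}, {tau}]")
    if not ctrl.any():
        raise UndefinedMetricError(f"no survivors past tau={tau}")
    pc, wc = p[case], w[case]
    pn, wn = p[ctrl], w[ctrl]
    pairw = np.outer(wc, wn)
    diff = pc[:, None] - pn[None, :]
    conc = np.where(diff < 0, 1.0, np.where(diff == 0, 0.5, 0.0))
    total = pairw.sum()
    value = float((pairw * conc).sum() / total)
    return AccuracyEstimate("auc", value, t0, tau, n_eff=float(w.sum()))


def brier_ipcw(predictions, frame, tau: float | None = None,
               t0: float | None = None, G: StepFunction | None = None) -> AccuracyEstimate:
    """IPCW Brier score: weighted mean of (I(survived past tau) - p_hat)^2."""
    t0 = frame.t0 if t0 is None else t0
    tau = frame.tau if tau is None else tau
    p = _align_predictions(predictions, frame)
    X, D, w = _weights_for(frame, t0, tau, G)
    total = w.sum()
    if total <= 0:
        raise UndefinedMetricError("total IPCW weight is 0")
    survived = (X > tau).astype(float)
    value = float(np.sum(w * (survived - p) ** 2) / total)
    return AccuracyEstimate("brier", value, t0, tau, n_eff=float(total))


def chisq_pvalue(stat: float, df: int) -> float:
    """Upper-tail chi-squared probability."""
    if df < 1:
        raise ValueError("df must be >= 1")
    if stat < 0:
        raise ValueError("statistic must be >= 0")
    return float(stats.chi2.sf(stat, df))


def hl_statistic(predictions, frame, tau: float | None = None,
                 t0: float | None = None, g: int = 5,
                 G: StepFunction | None = None) -> AccuracyEstimate:
    """Hosmer-Lemeshow calibration statistic extended to survival data.

    Subjects are split into ``g`` strata by quantiles of predicted risk
    (1 - p_hat). Per stratum the observed event proportion O is IPCW-weighted,
    the expected proportion E is the mean predicted risk, and the statistic is
    sum n_g (O - E)^2 / (E (1 - E)) with n_g the stratum's effective (weight)
    size, referred to chi-squared with g - 1 degrees of freedom. Strata with
    degenerate E are skipped with a warning and the df reduced.
    """
    t0 = frame.t0 if t0 is None else t0
    tau = frame.tau if tau is None else tau
    p = _align_predictions(predictions, frame)
    risk = 1.0 - p
    if len(np.unique(risk)) < g:
        raise UndefinedMetricError(
            f"need >= {g} distinct prediction values for {g} strata"
        )
    X, D, w = _weights_for(frame, t0, tau, G)
    edges = np.quantile(risk, np.linspace(0, 1, g + 1)[1:-1])
    stratum = np.searchsorted(edges, risk, side="right")
    stat = 0.0
    used = 0
    for s in range(g):
        m = stratum == s
        if not m.any() or w[m].sum() <= 0:
            warnings.warn(f"HL stratum {s} empty; df reduced", stacklevel=2)
            continue
        n_g = w[m].sum()
        event_in_window = ((D == 1) & (X > t0) & (X <= tau)).astype(float)
        O = float(np.sum(w[m] * event_in_window[m]) / n_g)
        E = float(risk[m].mean())
        if E <= 0 or E >= 1:
            warnings.warn(f"HL stratum {s} has degenerate expected rate {E}; "
                          "skipped, df reduced", stacklevel=2)
            continue
        stat += n_g * (O - E) ** 2 / (E * (1 - E))
        used += 1
    if used < 2:
        raise UndefinedMetricError("fewer than 2 usable HL strata")
    df = used - 1
    return AccuracyEstimate("hl", float(stat), t0, tau, n_eff=float(w.sum()),
                            p_value=chisq_pvalue(stat, df))


def nri_components(pred_dynamic, pred_static, frame, tau: float | None = None,
                   t0: float | None = None, G: StepFunction | None = None) -> NRIComponents:
    """Reclassification components of the continuous NRI.

    Among events in (t0, tau] and among survivors past tau separately, the
    IPCW-weighted percentage whose predicted risk under the dynamic model is
    strictly higher (``up``) or strictly lower (``down``) than under the
    static model; exact ties are reported separately.
    """
    t0 = frame.t0 if t0 is None else t0
    tau = frame.tau if tau is None else tau
    p_d = _align_predictions(pred_dynamic, frame)
    p_s = _align_predictions(pred_static, frame)
    risk_d = 1.0 - p_d
    risk_s = 1.0 - p_s
    X, D, w = _weights_for(frame, t0, tau, G)
    event = (D == 1) & (X > t0) & (X <= tau)
    nonevent = X > tau
    if not event.any():
        raise UndefinedMetricError(f"no events in ({t0}, {tau}]")
    if not nonevent.any():
        raise UndefinedMetricError(f"no survivors past tau={tau}")

    def pct(group):
        wt = w[group]
        total = wt.sum()
        up = np.sum(wt * (risk_d[group] > risk_s[group])) / total * 100
        down = np.sum(wt * (risk_d[group] < risk_s[group])) / total * 100
        tie = np.sum(wt * (risk_d[group] == risk_s[group])) / total * 100
        return up, down, tie

    up_e, down_e, tie_e = pct(event)
    up_ne, down_ne, tie_ne = pct(nonevent)
    return NRIComponents(up_e, down_e, up_ne, down_ne, tie_e, tie_ne)


def combine_nri(up_events: float, down_events: float,
                up_nonevents: float, down_nonevents: float) -> float:
    """Net reclassification improvement from its four components (percent):
    (up_e - down_e) - (up_ne - down_ne)."""
    for v in (up_events, down_events, up_nonevents, down_nonevents):
        if not 0 <= v <= 100:
            raise ValueError("components must be percentages in [0, 100]")
    return (up_events - down_events) - (up_nonevents - down_nonevents)
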