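"""Cox proportional hazards engine.

Partial-likelihood fitting by Newton-Raphson (Efron or Breslow tie handling),
the Breslow baseline cumulative hazard, absolute survival predictions and the
conditional-survival transformation of a baseline fit.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .exceptions import ConvergenceError, NoEventsError
from .stepfun import StepFunction

__all__ = [
    "CovariateSpec",
    "CoxModelFit",
    "fit_cox",
    "breslow_cumhaz",
    "predict_survival",
    "conditional_survival_static",
    "hazard_ratio_table",
]


@dataclass(frozen=True)
class CovariateSpec:
    """Design-matrix specification: dummy-coded categoricals plus numerics.

    ``categorical`` maps a column name to ``(levels, reference)``; each
    non-reference level becomes one indicator column named ``col[level]``.
    ``numeric`` columns enter as-is.
    """

    categorical: dict = field(default_factory=dict)
    numeric: tuple = ()

    def __post_init__(self):
        names = list(self.categorical) + list(self.numeric)
        if len(set(names)) != len(names):
            raise ValueError("covariate names must be unique")
        for col, (levels, ref) in self.categorical.items():
            if ref not in levels:
                raise ValueError(f"reference level {ref!r} not in levels of {col!r}")
            if len(set(levels)) != len(levels):
                raise ValueError(f"duplicate levels for {col!r}")

    @property
    def design_names(self) -> list:
        names = []
        for col, (levels, ref) in self.categorical.items():
            names.extend(f"{col}[{lev}]" for lev in levels if lev != ref)
        names.extend(self.numeric)
        return names

    def design(self, df) -> np.ndarray:
        """Build the (n, p) design matrix from a DataFrame."""
        cols = []
        for col, (levels, ref) in self.categorical.items():
            vals = df[col].to_numpy()
            unknown = set(np.unique(vals)) - set(levels)
            if unknown:
                raise ValueError(f"unknown levels {unknown} in column {col!r}")
            for lev in levels:
                if lev != ref:
                    cols.append((vals == lev).astype(float))
        for col in self.numeric:
            cols.append(df[col].to_numpy(dtype=float))
        if not cols:
            return np.empty((len(df), 0))
        return np.column_stack(cols)

    def to_dict(self) -> dict:
        return {
            "categorical": {
                c: {"levels": list(v[0]), "reference": v[1]}
                for c, v in self.categorical.items()
            },
            "numeric": list(self.numeric),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CovariateSpec":
        cat = {
            c: (tuple(v["levels"]), v["reference"])
            for c, v in d.get("categorical", {}).items()
        }
        return cls(categorical=cat, numeric=tuple(d.get("numeric", ())))


@dataclass
class CoxModelFit:
    """A converged Cox fit: coefficients, covariance, baseline hazard.

    ``t0`` is the landmark time the risk sets were conditioned on (0 for a
    baseline/static fit); ``baseline_cumhaz`` is zero at and before ``t0``.
    ``dropped`` lists design columns removed as constant (unidentifiable).
    """

    spec: CovariateSpec
    names: list
    coefficients: np.ndarray
    vcov: np.ndarray
    baseline_cumhaz: StepFunction | None
    t0: float
    ties_method: str
    n: int
    n_events: int
    loglik: float = np.nan
    n_iter: int = 0
    dropped: list = field(default_factory=list)

    def linear_predictor(self, Z: np.ndarray) -> np.ndarray:
        Z = np.atleast_2d(np.asarray(Z, dtype=float))
        return Z @ self.coefficients

    def design(self, df) -> np.ndarray:
        """Design matrix for this fit (dropped columns removed)."""
        Z = self.spec.design(df)
        if self.dropped:
            keep = [i for i, nm in enumerate(self.spec.design_names)
                    if nm not in self.dropped]
            # contiguous copy keeps BLAS summation order (and hence
            # predictions) bitwise identical to an undropped design
            Z = np.ascontiguousarray(Z[:, keep])
        return Z

    @property
    def se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.vcov))

    def to_dict(self) -> dict:
        return {
            "spec": self.spec.to_dict(),
            "names": list(self.names),
            "coefficients": self.coefficients.tolist(),
            "vcov": self.vcov.tolist(),
            "baseline_cumhaz": (
                None if self.baseline_cumhaz is None
                else self.baseline_cumhaz.to_dict()
            ),
            "t0": self.t0,
            "ties_method": self.ties_method,
            "n": self.n,
            "n_events": self.n_events,
            "loglik": self.loglik,
            "n_iter": self.n_iter,
            "dropped": list(self.dropped),
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def from_dict(cls, d: dict) -> "CoxModelFit":
        return cls(
            spec=CovariateSpec.from_dict(d["spec"]),
            names=list(d["names"]),
            coefficients=np.asarray(d["coefficients"], dtype=float),
            vcov=np.asarray(d["vcov"], dtype=float),
            baseline_cumhaz=(
                None if d["baseline_cumhaz"] is None
                else StepFunction.from_dict(d["baseline_cumhaz"])
            ),
            t0=float(d["t0"]),
            ties_method=d["ties_method"],
            n=int(d["n"]),
            n_events=int(d["n_events"]),
            loglik=float(d["loglik"]),
            n_iter=int(d["n_iter"]),
            dropped=list(d.get("dropped", [])),
        )

    @classmethod
    def from_json(cls, path) -> "CoxModelFit":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def _event_groups(durations, events):
    """Distinct event times with slices into the time-sorted arrays."""
    order = np.argsort(durations, kind="mergesort")
    d = durations[order]
    e = events[order].astype(bool)
    uniq_times = np.unique(d[e])
    return order, d, e, uniq_times


def _loglik_grad_hess(beta, Z, durations, events, ties):
    """Cox partial log-likelihood with analytic gradient and Hessian.

    Risk-set sums are accumulated from the largest time downward, so the
    cost is O(n p^2) plus O(#distinct event times) bookkeeping. Efron's
    correction for each tie group is evaluated in closed form.
    """
    n, p = Z.shape
    lp = Z @ beta
    # guard against overflow in exp for diverging beta
    lp = np.clip(lp, -700, 700)
    theta = np.exp(lp)

    order = np.argsort(durations, kind="mergesort")
    d = durations[order]
    e = events[order].astype(bool)
    Zs = Z[order]
    th = theta[order]
    lps = lp[order]

    # boundaries of distinct times, iterated from latest to earliest
    starts = np.flatnonzero(np.r_[True, d[1:] != d[:-1]])
    stops = np.r_[starts[1:], n]

    ll = 0.0
    grad = np.zeros(p)
    hess = np.zeros((p, p))
    S0 = 0.0
    S1 = np.zeros(p)
    S2 = np.zeros((p, p))
    for k in range(len(starts) - 1, -1, -1):
        lo, hi = starts[k], stops[k]
        blk_th = th[lo:hi]
        blk_Z = Zs[lo:hi]
        S0 += blk_th.sum()
        S1 += blk_th @ blk_Z
        S2 += (blk_Z * blk_th[:, None]).T @ blk_Z
        ev = e[lo:hi]
        m = int(ev.sum())
        if m == 0:
            continue
        ev_Z = blk_Z[ev]
        ev_th = blk_th[ev]
        s0 = ev_th.sum()
        s1 = ev_th @ ev_Z
        s2 = (ev_Z * ev_th[:, None]).T @ ev_Z
        if ties == "efron":
            c = np.arange(m) / m
        else:  # breslow
            c = np.zeros(m)
        denom = S0 - c * s0
        w = 1.0 / denom
        A0, A1 = w.sum(), (w * c).sum()
        w2 = w * w
        B0, B1, B2 = w2.sum(), (w2 * c).sum(), (w2 * c * c).sum()
        ll += lps[lo:hi][ev].sum() - np.log(denom).sum()
        g1 = A0 * S1 - A1 * s1
        grad += ev_Z.sum(axis=0) - g1
        outer = (
            B0 * np.outer(S1, S1)
            - B1 * (np.outer(S1, s1) + np.outer(s1, S1))
            + B2 * np.outer(s1, s1)
        )
        hess -= (A0 * S2 - A1 * s2) - outer
    return ll, grad, hess


def fit_cox(frame, spec: CovariateSpec | None = None, ties_method: str = "efron",
            tol: float = 1e-8, max_iter: int = 100) -> CoxModelFit:
    """Fit a Cox model on a landmark frame by maximizing the partial likelihood.

    ``frame`` must expose ``.data`` (DataFrame with ``X`` and ``D`` columns),
    ``.t0`` and, if ``spec`` is omitted, ``.spec``. Constant design columns
    are dropped (with a warning) rather than fit; frames with no events raise
    :class:`NoEventsError`; monotone likelihood raises
    :class:`ConvergenceError` naming the offending covariate.
    """
    if ties_method not in ("efron", "breslow"):
        raise ValueError(f"unknown ties method {ties_method!r}")
    if spec is None:
        spec = frame.spec
    df = frame.data
    t0 = float(frame.t0)
    durations = df["X"].to_numpy(dtype=float)
    events = df["D"].to_numpy(dtype=int)
    n = len(df)
    n_events = int(events.sum())
    if n == 0:
        raise NoEventsError("empty risk set")
    if n_events == 0:
        raise NoEventsError(f"no events in risk set at t0={t0}")

    Z_full = spec.design(df)
    all_names = spec.design_names
    if not np.all(np.isfinite(Z_full)):
        bad = [all_names[j] for j in np.where(~np.isfinite(Z_full).all(axis=0))[0]]
        raise ValueError(f"non-finite covariate values in {bad}; exclude missing rows first")
    keep = np.ptp(Z_full, axis=0) > 0 if Z_full.shape[1] else np.ones(0, bool)
    dropped = [nm for nm, k in zip(all_names, keep) if not k]
    if dropped:
        warnings.warn(
            f"dropping constant (unidentifiable) covariate columns: {dropped}",
            stacklevel=2,
        )
    Z = Z_full[:, keep]
    names = [nm for nm, k in zip(all_names, keep) if k]
    p = Z.shape[1]
    if p == 0:
        beta = np.zeros(0)
        ll, _, H = _loglik_grad_hess(beta, Z, durations, events, ties_method)
        fit = CoxModelFit(spec, names, beta, np.zeros((0, 0)), None, t0,
                          ties_method, n, n_events, ll, 0, dropped)
        fit.baseline_cumhaz = breslow_cumhaz(fit, frame)
        return fit

    # center and scale columns for numerical stability; map back at the end
    mu = Z.mean(axis=0)
    sd = Z.std(axis=0)
    sd[sd == 0] = 1.0
    Zc = (Z - mu) / sd

    beta = np.zeros(p)
    ll, grad, hess = _loglik_grad_hess(beta, Zc, durations, events, ties_method)
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        try:
            delta = np.linalg.solve(hess, -grad)
        except np.linalg.LinAlgError as err:
            raise ConvergenceError(f"singular information matrix: {err}") from err
        step = 1.0
        for _ in range(40):
            beta_new = beta + step * delta
            ll_new, grad_new, hess_new = _loglik_grad_hess(
                beta_new, Zc, durations, events, ties_method
            )
            if np.isfinite(ll_new) and ll_new >= ll - 1e-12:
                break
            step /= 2.0
        else:
            raise ConvergenceError("step-halving failed to improve the likelihood")
        beta, ll, grad, hess = beta_new, ll_new, grad_new, hess_new
        # on standardized covariates a |log HR| this large per SD means the
        # likelihood is drifting to a boundary (separation), not converging
        if np.max(np.abs(beta)) > 10:
            worst = names[int(np.argmax(np.abs(beta)))]
            raise ConvergenceError(
                f"monotone likelihood (possible perfect separation) in {worst!r}",
                covariate=worst,
            )
        if np.max(np.abs(grad)) < tol:
            break
    else:
        worst = names[int(np.argmax(np.abs(grad)))]
        raise ConvergenceError(
            f"no convergence in {max_iter} iterations (worst gradient: {worst!r})",
            covariate=worst,
        )

    info = -hess
    try:
        vcov_c = np.linalg.inv(info)
    except np.linalg.LinAlgError as err:
        raise ConvergenceError(f"information matrix not invertible: {err}") from err
    # undo scaling: beta_j = beta_c_j / sd_j ; vcov scales accordingly
    beta_out = beta / sd
    scale = np.outer(1.0 / sd, 1.0 / sd)
    vcov = vcov_c * scale

    fit = CoxModelFit(spec, names, beta_out, vcov, None, t0, ties_method,
                      n, n_events, ll, n_iter, dropped)
    fit.baseline_cumhaz = breslow_cumhaz(fit, frame)
    return fit


def breslow_cumhaz(fit: CoxModelFit, frame) -> StepFunction:
    """Breslow estimator of the baseline cumulative hazard.

    Steps d_k / sum_{j at risk} exp(beta' Z_j) at each distinct event time,
    cumulated; for a landmark fit (t0 > 0) the estimate is 0 at and before t0
    by construction since all frame members have X > t0.
    """
    df = frame.data
    durations = df["X"].to_numpy(dtype=float)
    events = df["D"].to_numpy(dtype=int)
    Z = fit.design(df)
    theta = np.exp(np.clip(fit.linear_predictor(Z), -700, 700)) \
        if Z.shape[1] else np.ones(len(df))

    order = np.argsort(durations, kind="mergesort")
    d = durations[order]
    e = events[order].astype(bool)
    th = theta[order]
    # suffix sums of theta give the risk-set denominator at each time
    suffix = np.cumsum(th[::-1])[::-1]
    event_times = np.unique(d[e])
    increments = np.empty_like(event_times)
    for k, t in enumerate(event_times):
        lo = np.searchsorted(d, t, side="left")
        hi = np.searchsorted(d, t, side="right")
        increments[k] = e[lo:hi].sum() / suffix[lo]
    return StepFunction(event_times, np.cumsum(increments), value_before=0.0)


def _cumhaz_at(fit: CoxModelFit, tau: float, warn_extrapolation: bool = True) -> float:
    ch = fit.baseline_cumhaz
    if ch is None:
        raise ValueError("fit has no baseline cumulative hazard attached")
    if ch.knots.size and tau > ch.last_knot and warn_extrapolation:
        warnings.warn(
            f"tau={tau} beyond last event time {ch.last_knot}; "
            "baseline hazard clamped at its final value",
            stacklevel=3,
        )
    return float(ch(min(tau, ch.last_knot))) if ch.knots.size else 0.0


def is_extrapolated(fit: CoxModelFit, tau: float) -> bool:
    ch = fit.baseline_cumhaz
    return bool(ch is not None and ch.knots.size and tau > ch.last_knot)


def predict_survival(fit: CoxModelFit, Z, tau: float):
    """P(T > tau | Z) = exp(-Lambda0(tau) exp(beta'Z)); clamps beyond data."""
    if tau < 0:
        raise ValueError("tau must be nonnegative")
    lam = _cumhaz_at(fit, tau)
    Z = np.asarray(Z, dtype=float)
    scalar = Z.ndim == 1
    lp = fit.linear_predictor(Z)
    out = np.exp(-lam * np.exp(np.clip(lp, -700, 700)))
    return float(out[0]) if scalar else out


def conditional_survival_static(fit: CoxModelFit, Z, t0: float, tau: float):
    """P(T > tau | T > t0, Z) from a baseline fit:
    exp{-(Lambda0(tau) - Lambda0(t0)) exp(beta'Z)}."""
    if tau < t0:
        raise ValueError("tau must be >= t0")
    if t0 < 0:
        raise ValueError("t0 must be nonnegative")
    lam = _cumhaz_at(fit, tau) - _cumhaz_at(fit, t0, warn_extrapolation=False)
    Z = np.asarray(Z, dtype=float)
    scalar = Z.ndim == 1
    lp = fit.linear_predictor(Z)
    out = np.exp(-lam * np.exp(np.clip(lp, -700, 700)))
    return float(out[0]) if scalar else out


def hazard_ratio_table(fit: CoxModelFit):
    """Per-covariate hazard ratios with 95% Wald CIs and significance stars."""
    import pandas as pd

    se = fit.se
    coef = fit.coefficients
    z = np.divide(coef, se, out=np.zeros_like(coef), where=se > 0)
    p = 2 * stats.norm.sf(np.abs(z))
    stars = np.where(p < 0.001, "***", np.where(p < 0.05, "*", ""))
    return pd.DataFrame(
        {
            "covariate": fit.names,
            "hr": np.exp(coef),
            "ci_lo": np.exp(coef - 1.96 * se),
            "ci_hi": np.exp(coef + 1.96 * se),
            "p": p,
            "stars": stars,
        }
    )
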