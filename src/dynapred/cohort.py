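"""Synthetic longitudinal cohort generator.

Produces trial-like cohorts: categorical baseline covariates drawn from
configured marginal frequencies, truncated-normal baseline labs, Gaussian
random-walk biomarker paths observed on a visit schedule, event times drawn
from a piecewise-exponential proportional-hazards model on the current
covariate path, interval detection of events at visits, and independent
dropout plus administrative censoring snapped to the last attended visit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import ConfigurationError

__all__ = [
    "BiomarkerDrift",
    "TimeVaryingEffect",
    "HazardSpec",
    "CensoringSpec",
    "CohortConfig",
    "Cohort",
    "SubjectRecord",
    "generate_cohort",
    "simulate_biomarker_paths",
    "simulate_event_times",
    "apply_censoring_and_detection",
]

GLUCOSE_CENTER = 107.35
HBA1C_CENTER = 5.91

# marginal frequencies of the default trial-like population
DEFAULT_COVARIATE_FREQS = {
    "age_group": {
        "<40": 0.139, "40-44": 0.149, "45-49": 0.205, "50-54": 0.183,
        "55-59": 0.124, "60-64": 0.098, "65+": 0.103,
    },
    "gender": {"male": 0.335, "female": 0.665},
    "bmi_group": {"<30": 0.323, "30-35": 0.301, "35+": 0.375},
    "smoking": {"yes": 0.066, "no": 0.858, "not_available": 0.076},
    "race": {"white": 0.578, "black": 0.214, "hispanic": 0.160, "other": 0.048},
}


@dataclass(frozen=True)
class BiomarkerDrift:
    """Random-walk parameters: increments over dt are
    N((mean_annual + subject drift) * dt, (increment_sd^2) * dt)."""

    mean_annual: float = 0.0
    increment_sd: float = 0.0
    between_subject_sd: float = 0.0
    floor: float = 0.0

    def validate(self, label: str) -> None:
        if self.increment_sd < 0 or self.between_subject_sd < 0:
            raise ConfigurationError(f"{label}: drift SDs must be >= 0")


@dataclass(frozen=True)
class TimeVaryingEffect:
    """Multiplies the coefficients of ``features`` by ``multiplier`` for
    t >= onset_time, breaking proportional hazards in baseline-only models."""

    features: tuple = ("glucose", "hba1c")
    multiplier: float = 1.0
    onset_time: float = 0.0


@dataclass(frozen=True)
class HazardSpec:
    """lambda(t) = base_rate * arm_multiplier * exp(sum coefs * features(t)).

    Feature keys: ``glucose``/``hba1c`` (current value minus its center),
    ``glucose_baseline``/``hba1c_baseline`` (baseline minus center),
    ``glucose_change``/``hba1c_change`` (current minus baseline), or a
    categorical indicator ``column=level``.
    """

    base_rate: float = 0.08
    coefs: dict = field(default_factory=dict)
    arm_multiplier: float = 1.0
    time_varying: TimeVaryingEffect | None = None

    def validate(self) -> None:
        if not (self.base_rate > 0):
            raise ConfigurationError("base hazard rate must be > 0")
        if not np.isfinite(self.base_rate) or not all(
            np.isfinite(v) for v in self.coefs.values()
        ):
            raise ConfigurationError("non-finite hazard specification")


@dataclass(frozen=True)
class CensoringSpec:
    """Administrative end ~ Uniform(admin_lo, admin_hi); dropout ~
    Exponential(dropout_rate) (rate 0 disables dropout).

    Censoring is snapped down to the last attended visit. Cohorts with brief
    interim visits between lab visits can set ``snap_grid_step`` to snap onto
    a finer grid than the lab schedule (0 snaps to the lab schedule itself).
    """

    admin_lo: float = 6.5
    admin_hi: float = 9.5
    dropout_rate: float = 0.01
    snap_grid_step: float = 0.25

    def validate(self) -> None:
        if self.admin_lo > self.admin_hi or self.admin_lo < 0:
            raise ConfigurationError("administrative window must satisfy 0 <= lo <= hi")
        if self.dropout_rate < 0:
            raise ConfigurationError("dropout rate must be >= 0")
        if self.snap_grid_step < 0:
            raise ConfigurationError("snap_grid_step must be >= 0")


def _default_schedule() -> tuple:
    # baseline, 6 months, then annual visits
    return (0.0, 0.5) + tuple(float(v) for v in range(1, 11))


@dataclass(frozen=True)
class CohortConfig:
    n_subjects: int = 1000
    arm: str = "placebo"
    covariate_freqs: dict = field(
        default_factory=lambda: {
            k: dict(v) for k, v in DEFAULT_COVARIATE_FREQS.items()
        }
    )
    glucose_baseline: tuple = (107.35, 7.84)
    hba1c_baseline: tuple = (5.91, 0.51)
    glucose_drift: BiomarkerDrift = field(
        default_factory=lambda: BiomarkerDrift(1.5, 5.0, 1.0, floor=40.0)
    )
    hba1c_drift: BiomarkerDrift = field(
        default_factory=lambda: BiomarkerDrift(0.03, 0.12, 0.02, floor=3.0)
    )
    hazard: HazardSpec = field(
        default_factory=lambda: HazardSpec(
            base_rate=0.075,
            coefs={"glucose": 0.055, "hba1c": 0.45, "bmi_group=35+": 0.25},
        )
    )
    visit_schedule: tuple = field(default_factory=_default_schedule)
    censoring: CensoringSpec = field(default_factory=CensoringSpec)
    missing_baseline_hba1c_frac: float = 8.0 / 2057.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_subjects < 0:
            raise ConfigurationError("n_subjects must be >= 0")
        for col, freqs in self.covariate_freqs.items():
            probs = np.asarray(list(freqs.values()), dtype=float)
            if np.any(probs < 0) or np.any(probs > 1):
                raise ConfigurationError(f"{col}: probabilities must lie in [0, 1]")
            if not np.isclose(probs.sum(), 1.0, atol=0.02):
                raise ConfigurationError(
                    f"{col}: frequencies sum to {probs.sum():.3f}, expected ~1"
                )
        for label, (mean, sd) in (
            ("glucose_baseline", self.glucose_baseline),
            ("hba1c_baseline", self.hba1c_baseline),
        ):
            if sd < 0:
                raise ConfigurationError(f"{label}: SD must be >= 0")
        self.glucose_drift.validate("glucose_drift")
        self.hba1c_drift.validate("hba1c_drift")
        self.hazard.validate()
        self.censoring.validate()
        sched = np.asarray(self.visit_schedule, dtype=float)
        if sched.size == 0 or sched[0] != 0.0 or np.any(np.diff(sched) <= 0):
            raise ConfigurationError(
                "visit schedule must start at 0 and be strictly increasing"
            )
        if not 0 <= self.missing_baseline_hba1c_frac < 1:
            raise ConfigurationError("missing_baseline_hba1c_frac must be in [0, 1)")

    # ---- presets -----------------------------------------------------------

    @classmethod
    def default(cls, n_subjects: int = 1000, arm: str = "placebo",
                seed: int = 0, **overrides) -> "CohortConfig":
        return cls(n_subjects=n_subjects, arm=arm, seed=seed, **overrides)

    @classmethod
    def correct_ph(cls, n_subjects: int = 2000, seed: int = 0,
                   arm: str = "placebo") -> "CohortConfig":
        """Hazard depends on baseline values only: both static and landmark
        models are correctly specified (landmark change terms have true
        coefficient 0). Biomarker paths carry only small measurement-style
        noise so the plug-in-current-labs static comparator is not
        handicapped by drift."""
        return cls(
            n_subjects=n_subjects,
            arm=arm,
            seed=seed,
            glucose_drift=BiomarkerDrift(0.0, 1.0, 0.0, floor=40.0),
            hba1c_drift=BiomarkerDrift(0.0, 0.03, 0.0, floor=3.0),
            hazard=HazardSpec(
                base_rate=0.075,
                coefs={
                    "glucose_baseline": 0.055,
                    "hba1c_baseline": 0.45,
                    "bmi_group=35+": 0.25,
                },
            ),
        )

    @classmethod
    def misspecified(cls, n_subjects: int = 1000, seed: int = 0,
                     arm: str = "placebo") -> "CohortConfig":
        """Hazard follows the *current* biomarker path with an effect that
        strengthens after ``onset_time``; a baseline-only proportional-hazards
        model is misspecified under this generator."""
        return cls(
            n_subjects=n_subjects,
            arm=arm,
            seed=seed,
            glucose_drift=BiomarkerDrift(2.0, 7.0, 2.0, floor=40.0),
            hba1c_drift=BiomarkerDrift(0.05, 0.18, 0.04, floor=3.0),
            hazard=HazardSpec(
                base_rate=0.06,
                coefs={"glucose": 0.06, "hba1c": 0.6, "bmi_group=35+": 0.25},
                time_varying=TimeVaryingEffect(
                    features=("glucose", "hba1c"), multiplier=2.5, onset_time=1.0
                ),
            ),
        )

    def to_dict(self) -> dict:
        d = asdict(self)
        d["visit_schedule"] = list(self.visit_schedule)
        d["glucose_baseline"] = list(self.glucose_baseline)
        d["hba1c_baseline"] = list(self.hba1c_baseline)
        if self.hazard.time_varying is not None:
            d["hazard"]["time_varying"]["features"] = list(
                self.hazard.time_varying.features
            )
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "CohortConfig":
        d = dict(d)
        for key, klass in (
            ("glucose_drift", BiomarkerDrift),
            ("hba1c_drift", BiomarkerDrift),
            ("censoring", CensoringSpec),
        ):
            if key in d and isinstance(d[key], dict):
                d[key] = klass(**d[key])
        if "hazard" in d and isinstance(d["hazard"], dict):
            h = dict(d["hazard"])
            tv = h.get("time_varying")
            if isinstance(tv, dict):
                tv = dict(tv)
                tv["features"] = tuple(tv.get("features", ()))
                h["time_varying"] = TimeVaryingEffect(**tv)
            d["hazard"] = HazardSpec(**h)
        for key in ("glucose_baseline", "hba1c_baseline", "visit_schedule"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass(frozen=True)
class SubjectRecord:
    """One subject: baseline covariates, lab series, observed (X, D) and the
    latent onset time (kept for simulation diagnostics, never for fitting)."""

    id: int
    arm: str
    age_group: str
    gender: str
    bmi_group: str
    smoking: str
    race: str
    labs: pd.DataFrame  # columns: time_years, glucose_mgdl, hba1c_pct
    X: float
    D: int
    true_onset: float


class Cohort:
    """Column-oriented cohort: a subjects table and a long labs table."""

    def __init__(self, subjects: pd.DataFrame, labs: pd.DataFrame, arm: str | None = None):
        self.subjects = subjects.reset_index(drop=True)
        self.labs = labs.reset_index(drop=True)
        self.arm = arm if arm is not None else (
            subjects["arm"].iloc[0] if len(subjects) else "unknown"
        )

    def __len__(self) -> int:
        return len(self.subjects)

    def __iter__(self):
        labs_by_id = dict(tuple(self.labs.groupby("id", sort=False)))
        for row in self.subjects.itertuples(index=False):
            labs = labs_by_id.get(row.id)
            labs = (
                labs[["time_years", "glucose_mgdl", "hba1c_pct"]].reset_index(drop=True)
                if labs is not None
                else pd.DataFrame(columns=["time_years", "glucose_mgdl", "hba1c_pct"])
            )
            yield SubjectRecord(
                id=row.id, arm=row.arm, age_group=row.age_group,
                gender=row.gender, bmi_group=row.bmi_group, smoking=row.smoking,
                race=row.race, labs=labs, X=row.X, D=int(row.D),
                true_onset=getattr(row, "true_onset", np.nan),
            )

    def subset(self, ids) -> "Cohort":
        ids = np.asarray(ids)
        subj = self.subjects[self.subjects["id"].isin(ids)]
        labs = self.labs[self.labs["id"].isin(ids)]
        return Cohort(subj, labs, arm=self.arm)

    def resample(self, rng: np.random.Generator) -> "Cohort":
        """Subject-level bootstrap resample; duplicated subjects get fresh ids."""
        ids = self.subjects["id"].to_numpy()
        picks = rng.choice(ids, size=len(ids), replace=True)
        labs_by_id = dict(tuple(self.labs.groupby("id", sort=False)))
        subj_by_id = self.subjects.set_index("id", drop=False)
        subj_rows, lab_rows = [], []
        for new_id, old_id in enumerate(picks):
            row = subj_by_id.loc[old_id].copy()
            row["id"] = new_id
            subj_rows.append(row)
            lb = labs_by_id[old_id].copy()
            lb["id"] = new_id
            lab_rows.append(lb)
        subjects = pd.DataFrame(subj_rows).reset_index(drop=True)
        labs = pd.concat(lab_rows, ignore_index=True)
        return Cohort(subjects, labs, arm=self.arm)


# ---------------------------------------------------------------------------
# simulation primitives
# ---------------------------------------------------------------------------

def _truncated_normal(mean, sd, size, rng, lower=0.0):
    if sd == 0:
        return np.full(size, float(mean))
    a = (lower - mean) / sd
    return stats.truncnorm.rvs(a, np.inf, loc=mean, scale=sd,
                               size=size, random_state=rng)


def simulate_biomarker_paths(baseline: np.ndarray, schedule, drift: BiomarkerDrift,
                             rng: np.random.Generator) -> np.ndarray:
    """Gaussian random walk on the visit schedule, one row per subject.

    Each subject carries an individual drift ~ N(mean_annual,
    between_subject_sd^2); increments over an interval dt are
    N(drift * dt, increment_sd^2 * dt). Values are floored at the
    configured physiological minimum.
    """
    schedule = np.asarray(schedule, dtype=float)
    if schedule[0] != 0:
        raise ConfigurationError("visit schedule must start at 0")
    n = len(baseline)
    k = len(schedule)
    paths = np.empty((n, k))
    paths[:, 0] = baseline
    if k > 1:
        dts = np.diff(schedule)
        subj_drift = drift.mean_annual + drift.between_subject_sd * rng.standard_normal(n)
        noise = rng.standard_normal((n, k - 1)) * (drift.increment_sd * np.sqrt(dts))
        increments = subj_drift[:, None] * dts[None, :] + noise
        paths[:, 1:] = baseline[:, None] + np.cumsum(increments, axis=1)
    return np.maximum(paths, drift.floor)


def simulate_event_times(piece_starts, piece_rates, rng: np.random.Generator,
                         u: np.ndarray | None = None) -> np.ndarray:
    """Exact inverse-transform draws from a piecewise-constant hazard.

    ``piece_starts`` (k,) are the left endpoints of the hazard pieces (first
    must be 0; the last piece extends to infinity); ``piece_rates`` (n, k)
    the per-subject rates on each piece.
    """
    piece_starts = np.asarray(piece_starts, dtype=float)
    rates = np.atleast_2d(np.asarray(piece_rates, dtype=float))
    if piece_starts[0] != 0:
        raise ConfigurationError("hazard pieces must start at 0")
    if not np.all(np.isfinite(rates)) or np.any(rates <= 0):
        raise ConfigurationError("hazard rates must be finite and positive")
    n, k = rates.shape
    e = rng.exponential(size=n) if u is None else np.asarray(u, dtype=float)
    if k == 1:
        return e / rates[:, 0]
    dts = np.diff(piece_starts)
    cumhaz = np.concatenate(
        [np.zeros((n, 1)), np.cumsum(rates[:, :-1] * dts[None, :], axis=1)], axis=1
    )  # cumulative hazard at each piece start
    j = np.sum(cumhaz <= e[:, None], axis=1) - 1
    rows = np.arange(n)
    return piece_starts[j] + (e - cumhaz[rows, j]) / rates[rows, j]


def apply_censoring_and_detection(true_onset, schedule, censoring: CensoringSpec,
                                  rng: np.random.Generator):
    """Interval detection at visits plus snapped censoring.

    Detection time is the first visit at or after the latent onset (infinite
    if onset falls beyond the last visit). The raw censoring time is the
    minimum of the administrative end and an exponential dropout time, then
    snapped down to the last attended visit (never earlier than the first
    post-baseline visit, so X > 0). D = 1 iff detection <= censoring.
    """
    true_onset = np.asarray(true_onset, dtype=float)
    schedule = np.asarray(schedule, dtype=float)
    if schedule.size == 0:
        raise ConfigurationError("visit schedule must be nonempty")
    n = len(true_onset)

    admin = rng.uniform(censoring.admin_lo, censoring.admin_hi, size=n)
    if censoring.dropout_rate > 0:
        dropout = rng.exponential(1.0 / censoring.dropout_rate, size=n)
    else:
        dropout = np.full(n, np.inf)
    c_raw = np.minimum(admin, dropout)

    det_idx = np.searchsorted(schedule, true_onset, side="left")
    detection = np.where(det_idx < len(schedule),
                         schedule[np.clip(det_idx, 0, len(schedule) - 1)], np.inf)
    if censoring.snap_grid_step > 0:
        step = censoring.snap_grid_step
        grid = np.unique(np.concatenate(
            [schedule, np.arange(0.0, schedule[-1] + step / 2, step)]
        ))
    else:
        grid = schedule
    snap_idx = np.searchsorted(grid, c_raw, side="right") - 1
    # censoring never before the first post-baseline contact, keeping X > 0
    min_time = schedule[1] if len(schedule) > 1 else schedule[0]
    min_idx = np.searchsorted(grid, min_time, side="left")
    censor = grid[np.clip(snap_idx, min_idx, None)]

    D = (detection <= censor).astype(int)
    X = np.where(D == 1, detection, censor)
    return X, D


def _hazard_features(config: CohortConfig, covariates: pd.DataFrame,
                     glucose: np.ndarray, hba1c: np.ndarray) -> dict:
    """Feature arrays (n, k) for every coefficient key in the hazard spec."""
    n, k = glucose.shape
    feats = {}
    for key in config.hazard.coefs:
        if key == "glucose":
            feats[key] = glucose - GLUCOSE_CENTER
        elif key == "hba1c":
            feats[key] = hba1c - HBA1C_CENTER
        elif key == "glucose_baseline":
            feats[key] = np.repeat(glucose[:, :1] - GLUCOSE_CENTER, k, axis=1)
        elif key == "hba1c_baseline":
            feats[key] = np.repeat(hba1c[:, :1] - HBA1C_CENTER, k, axis=1)
        elif key == "glucose_change":
            feats[key] = glucose - glucose[:, :1]
        elif key == "hba1c_change":
            feats[key] = hba1c - hba1c[:, :1]
        elif "=" in key:
            col, lev = key.split("=", 1)
            if col not in covariates.columns:
                raise ConfigurationError(f"unknown hazard covariate column {col!r}")
            ind = (covariates[col].to_numpy() == lev).astype(float)
            feats[key] = np.repeat(ind[:, None], k, axis=1)
        else:
            raise ConfigurationError(f"unknown hazard feature {key!r}")
    return feats


def generate_cohort(config: CohortConfig) -> Cohort:
    """Generate a cohort; deterministic for a fixed config seed."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_subjects
    schedule = np.asarray(config.visit_schedule, dtype=float)

    covs = {}
    for col, freqs in config.covariate_freqs.items():
        levels = list(freqs)
        probs = np.asarray([freqs[l] for l in levels], dtype=float)
        probs = probs / probs.sum()
        covs[col] = rng.choice(levels, size=n, p=probs)
    covariates = pd.DataFrame(covs) if n else pd.DataFrame(
        {c: pd.Series(dtype=object) for c in config.covariate_freqs}
    )

    g_mean, g_sd = config.glucose_baseline
    h_mean, h_sd = config.hba1c_baseline
    glucose0 = _truncated_normal(g_mean, g_sd, n, rng)
    hba1c0 = _truncated_normal(h_mean, h_sd, n, rng)

    glucose = simulate_biomarker_paths(glucose0, schedule, config.glucose_drift, rng)
    hba1c = simulate_biomarker_paths(hba1c0, schedule, config.hba1c_drift, rng)

    if n:
        feats = _hazard_features(config, covariates, glucose, hba1c)
        lp = np.zeros((n, len(schedule)))
        tv = config.hazard.time_varying
        for key, coef in config.hazard.coefs.items():
            contrib = coef * feats[key]
            if tv is not None and key in tv.features and tv.multiplier != 1.0:
                boost = np.where(schedule >= tv.onset_time, tv.multiplier, 1.0)
                contrib = contrib * boost[None, :]
            lp += contrib
        rates = config.hazard.base_rate * config.hazard.arm_multiplier * np.exp(
            np.clip(lp, -30, 30)
        )
        true_onset = simulate_event_times(schedule, rates, rng)
        X, D = apply_censoring_and_detection(true_onset, schedule, config.censoring, rng)
    else:
        true_onset = np.empty(0)
        X = np.empty(0)
        D = np.empty(0, dtype=int)

    # withhold baseline HbA1c for a configured fraction of subjects
    if n and config.missing_baseline_hba1c_frac > 0:
        miss = rng.random(n) < config.missing_baseline_hba1c_frac
    else:
        miss = np.zeros(n, dtype=bool)

    subjects = pd.DataFrame(
        {
            "id": np.arange(n),
            "arm": config.arm,
            **{c: covariates[c] for c in covariates.columns},
            "X": X,
            "D": D,
            "true_onset": true_onset,
        }
    )

    # labs recorded only at attended visits (times <= X)
    if n:
        attended = schedule[None, :] <= X[:, None]
        sid, vid = np.nonzero(attended)
        hb = hba1c[sid, vid]
        hb = np.where(miss[sid] & (vid == 0), np.nan, hb)
        labs = pd.DataFrame(
            {
                "id": sid,
                "time_years": schedule[vid],
                "glucose_mgdl": glucose[sid, vid],
                "hba1c_pct": hb,
            }
        )
    else:
        labs = pd.DataFrame(
            {"id": pd.Series(dtype=int), "time_years": pd.Series(dtype=float),
             "glucose_mgdl": pd.Series(dtype=float),
             "hba1c_pct": pd.Series(dtype=float)}
        )
    return Cohort(subjects, labs, arm=config.arm)
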