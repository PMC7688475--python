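"""Survival analysis with pseudo-time in place of physical time.

Every observation on a trajectory contributes its pseudo-time as a
time-on-study value: observations with a recorded terminal outcome are
events, the rest are right-censored at their pseudo-time.  Because
pseudo-times measured along different trajectories are not comparable, each
trajectory is analyzed with its own risk set: all estimators here accept a
single :class:`EventTable`, built per trajectory with
:func:`events_for_trajectory`, and never pool across trajectories.

The cumulative hazard uses the non-parametric Nelson-Aalen estimator

    H(t) = sum_{t_i <= t} d_i / n_i

(d_i events among n_i at risk at pseudo-time t_i) with the standard variance
sum d_i / n_i^2 and log-transformed confidence intervals.  Cause-specific
hazards treat one cause as the event and all other outcomes as censoring,
so the per-step increments across causes partition the all-cause increments.
Survival functions (Kaplan-Meier) and multivariate proportional-hazards
regression (Cox) are delegated to lifelines.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter

__all__ = [
    "EventTable",
    "HazardCurve",
    "CoxFit",
    "events_for_trajectory",
    "nelson_aalen",
    "cause_specific_hazards",
    "kaplan_meier",
    "cox_regression",
]


@dataclass
class EventTable:
    """Pseudo-time-ordered events for one trajectory.

    durations : pseudo-time of each observation (time on study, >= 0).
    events : 1 if the observation's terminal outcome occurred, else censored.
    causes : optional cause label per event (required for cause-specific
        hazards); censored observations may carry any placeholder.
    covariates : optional observation × covariate frame for Cox regression.
    """

    durations: np.ndarray
    events: np.ndarray
    causes: np.ndarray | None = None
    covariates: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.durations = np.asarray(self.durations, dtype=float)
        self.events = np.asarray(self.events, dtype=int)
        if (self.durations < 0).any():
            raise ValueError("durations (pseudo-times) must be >= 0")
        if len(self.durations) != len(self.events):
            raise ValueError("durations and events must have equal length")
        if self.causes is not None:
            self.causes = np.asarray(self.causes)
            if len(self.causes) != len(self.durations):
                raise ValueError("causes must match durations in length")
        if self.covariates is not None and len(self.covariates) != len(self.durations):
            raise ValueError("covariates must match durations in length")

    @property
    def n(self) -> int:
        return len(self.durations)


@dataclass
class HazardCurve:
    """Nelson-Aalen cumulative hazard over pseudo-time."""

    times: np.ndarray
    cumulative_hazard: np.ndarray
    variance: np.ndarray
    at_risk: np.ndarray

    def at(self, t: float) -> float:
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 0.0 if idx < 0 else float(self.cumulative_hazard[idx])

    def confidence_interval(self, alpha: float = 0.05) -> pd.DataFrame:
        """Log-transformed (1 - alpha) pointwise interval for H(t)."""
        from scipy.stats import norm

        z = norm.ppf(1 - alpha / 2)
        h = self.cumulative_hazard
        se = np.sqrt(self.variance)
        with np.errstate(divide="ignore", invalid="ignore"):
            theta = np.where(h > 0, np.exp(z * se / np.where(h > 0, h, 1.0)), 1.0)
        return pd.DataFrame(
            {"time": self.times, "lower": h / theta, "upper": h * theta}
        )


@dataclass
class CoxFit:
    """Cox proportional-hazards fit on pseudo-time."""

    summary: pd.DataFrame  # per covariate: coef, se, hazard_ratio, ci_lower, ci_upper, p
    log_likelihood: float
    converged: bool
    flag: str | None = None

    def top_coefficients(self, k: int = 10) -> pd.DataFrame:
        """Top-k most positive and top-k most negative coefficients."""
        s = self.summary.sort_values("coef")
        return pd.concat([s.head(k).assign(direction="negative"),
                          s.tail(k).assign(direction="positive")])


def events_for_trajectory(
    pseudotime_table,
    trajectory_id: int,
    events,
    causes=None,
    covariates: pd.DataFrame | None = None,
) -> EventTable:
    """Build the risk set of a single trajectory.

    Selects the observations belonging to the trajectory and pairs their
    pseudo-times with the given event indicators (and optional causes and
    covariates, aligned with the full observation set).
    """
    mask = pseudotime_table.trajectory_members[trajectory_id]
    durations = pseudotime_table.table["pt"].to_numpy()[mask]
    ev = np.asarray(events)[mask]
    ca = np.asarray(causes)[mask] if causes is not None else None
    cov = covariates.loc[mask].reset_index(drop=True) if covariates is not None else None
    return EventTable(durations=durations, events=ev, causes=ca, covariates=cov)


# ---------------------------------------------------------------------------
# estimators


def nelson_aalen(events: EventTable) -> HazardCurve:
    """Nelson-Aalen cumulative hazard H(t) = sum_{t_i<=t} d_i / n_i.

    Non-events are right-censored at their pseudo-time; with no events the
    curve is identically zero.
    """
    if events.n == 0:
        raise ValueError("need at least one observation")
    t = events.durations
    d = events.events
    event_times = np.unique(t[d == 1])
    if len(event_times) == 0:
        return HazardCurve(np.array([0.0]), np.array([0.0]), np.array([0.0]),
                           np.array([events.n]))
    h_inc = np.empty(len(event_times))
    v_inc = np.empty(len(event_times))
    at_risk = np.empty(len(event_times), dtype=int)
    for i, ti in enumerate(event_times):
        n_i = int(np.sum(t >= ti))
        d_i = int(np.sum((t == ti) & (d == 1)))
        h_inc[i] = d_i / n_i
        v_inc[i] = d_i / n_i**2
        at_risk[i] = n_i
    return HazardCurve(event_times, np.cumsum(h_inc), np.cumsum(v_inc), at_risk)


def cause_specific_hazards(events: EventTable, causes=None) -> dict[object, HazardCurve]:
    """One Nelson-Aalen curve per cause of the terminal outcome.

    For each cause, events of that cause count and everything else is
    censored at its pseudo-time; the per-step increments therefore partition
    the all-cause increments.
    """
    ca = events.causes if causes is None else np.asarray(causes)
    if ca is None:
        raise ValueError("cause labels are required for cause-specific hazards")
    labels = np.unique(ca[events.events == 1])
    out = {}
    for lab in labels:
        ev = ((events.events == 1) & (ca == lab)).astype(int)
        out[lab] = nelson_aalen(EventTable(events.durations, ev))
    return out


def kaplan_meier(events: EventTable, groups=None, labels=None) -> dict[object, pd.DataFrame]:
    """Product-limit survival function per group over pseudo-time.

    Returns, per group, a frame (time, survival) evaluated on the union of
    event times across groups.  With ``groups=None`` a single group is fit;
    ``labels`` may list the expected groups (an empty group is an error).
    """
    g = np.zeros(events.n, dtype=int) if groups is None else np.asarray(groups)
    labels = np.unique(g) if labels is None else np.asarray(labels)
    union_times = np.unique(events.durations[events.events == 1])
    if len(union_times) == 0:
        union_times = np.array([0.0])
    out = {}
    for lab in labels:
        sel = g == lab
        if not sel.any():
            raise ValueError(f"empty group {lab!r}")
        kmf = KaplanMeierFitter()
        kmf.fit(events.durations[sel], events.events[sel])
        surv = kmf.survival_function_at_times(union_times).to_numpy()
        out[lab] = pd.DataFrame({"time": union_times, "survival": surv})
    return out


def cox_regression(
    events: EventTable,
    standardize: bool = True,
    penalizer_fallback: float = 0.1,
) -> CoxFit:
    """Cox proportional-hazards regression of events on covariates.

    Covariates are standardized by default so coefficients are comparable.
    Exactly collinear covariates are rejected up front (singular information
    matrix); non-convergence or monotone likelihood triggers a flagged
    ridge-stabilized refit.
    """
    if events.covariates is None:
        raise ValueError("EventTable has no covariates")
    if int(events.events.sum()) < 2:
        raise ValueError("need >= 2 events for Cox regression")
    X = events.covariates.copy().astype(float)
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        raise ValueError("collinear covariates: information matrix would be singular")
    if standardize:
        sd = X.std(ddof=0).replace(0.0, 1.0)
        X = (X - X.mean()) / sd
    df = X.copy()
    df["pt"] = events.durations
    df["event"] = events.events
    flag = None
    cph = CoxPHFitter()
    try:
        cph.fit(df, duration_col="pt", event_col="event")
        converged = True
    except Exception:
        cph = CoxPHFitter(penalizer=penalizer_fallback)
        cph.fit(df, duration_col="pt", event_col="event")
        converged = True
        flag = "ridge-stabilized fallback fit"
    s = cph.summary
    summary = pd.DataFrame(
        {
            "coef": s["coef"],
            "se": s["se(coef)"],
            "hazard_ratio": s["exp(coef)"],
            "ci_lower": np.exp(s["coef lower 95%"]),
            "ci_upper": np.exp(s["coef upper 95%"]),
            "p": s["p"],
        }
    )
    return CoxFit(summary=summary, log_likelihood=float(cph.log_likelihood_),
                  converged=converged, flag=flag)
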