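"""Survival layer: endpoint construction, Kaplan-Meier, reverse KM,
absolute risk reduction, log-rank, and Cox proportional hazards.

Two endpoints are supported. Under all-cause death, a CRT-D upgrade, LVAD
implantation, or heart transplantation right-censors the patient at the
procedure date (in addition to administrative censoring). Under the
composite sensitivity endpoint, LVAD and transplantation count as events
and only the upgrade censors.

KM estimation, the log-rank test, and Cox fitting (Efron ties) are
delegated to lifelines; Greenwood variances and log-transform confidence
intervals are computed from the event table, and the absolute risk
reduction ARR(t) = [(1 - S_P(t)) - (1 - S_D(t))] * 100 gets a normal CI
from the summed Greenwood variances, with significance declared iff 0
falls outside the interval.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank

__all__ = [
    "EndpointSpec",
    "ALL_CAUSE_DEATH",
    "COMPOSITE",
    "KMCurve",
    "ARREntry",
    "CoxResult",
    "apply_endpoint",
    "km_estimate",
    "reverse_km",
    "arr_table",
    "logrank",
    "cox_fit",
    "COVARIATE_SETS",
]

_VALID_REASONS = {"none", "admin", "crtd_upgrade", "lvad", "htx"}

# multivariable adjustment sets; the "caption" set is the default, the
# "methods" set swaps atrial-fibrillation history for etiology
COVARIATE_SETS = {
    "caption": ["age", "sex", "af_history", "va_history"],
    "methods": ["age", "sex", "ischemic_etiology", "va_history"],
}


@dataclass(frozen=True)
class EndpointSpec:
    name: str
    censor_reasons_applied: frozenset
    extra_event_reasons: frozenset = frozenset()


ALL_CAUSE_DEATH = EndpointSpec(
    "all_cause_death", frozenset({"crtd_upgrade", "lvad", "htx"})
)
COMPOSITE = EndpointSpec(
    "composite", frozenset({"crtd_upgrade"}), frozenset({"lvad", "htx"})
)


def apply_endpoint(records: pd.DataFrame, spec: EndpointSpec = ALL_CAUSE_DEATH):
    """Map survival records to ``(times, events)`` under an endpoint.

    ``records`` needs columns ``time_years``, ``event`` (death flag) and
    ``censor_reason``.
    """
    reasons = records["censor_reason"].astype(str)
    unknown = set(reasons.unique()) - _VALID_REASONS
    if unknown:
        raise ValueError(f"unknown censor_reason values: {sorted(unknown)}")
    events = records["event"].astype(bool) | reasons.isin(spec.extra_event_reasons)
    return records["time_years"].to_numpy(dtype=float), events.to_numpy()


@dataclass
class KMCurve:
    """Product-limit estimate with Greenwood variance and log-CI."""

    event_times: np.ndarray
    at_risk: np.ndarray
    n_events: np.ndarray
    survival: np.ndarray
    greenwood_var: np.ndarray
    ci_lo: np.ndarray
    ci_hi: np.ndarray

    def survival_at(self, t: float) -> float:
        """Left-continuous step value: S at the last event time <= t."""
        idx = np.searchsorted(self.event_times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])

    def variance_at(self, t: float) -> float:
        idx = np.searchsorted(self.event_times, t, side="right") - 1
        return 0.0 if idx < 0 else float(self.greenwood_var[idx])

    @property
    def max_time(self) -> float:
        return float(self.event_times[-1]) if len(self.event_times) else 0.0


def km_estimate(times, events, alpha: float = 0.05) -> KMCurve:
    """Kaplan-Meier via lifelines, with Greenwood variance and the
    log-transform 95% CI ``S * exp(±z * sqrt(sum d/(n(n-d))))``, clipped
    to [0, 1]."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    if times.size == 0:
        raise ValueError("no observations")
    if np.any(times <= 0):
        raise ValueError("times must be positive")
    kmf = KaplanMeierFitter()
    kmf.fit(times, events)
    tab = kmf.event_table
    tab = tab[tab["observed"] > 0]
    t = tab.index.to_numpy(dtype=float)
    d = tab["observed"].to_numpy(dtype=float)
    n = tab["at_risk"].to_numpy(dtype=float)
    surv = kmf.survival_function_at_times(t).to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        inc = np.where(n > d, d / (n * (n - d)), np.inf)
    cum = np.cumsum(inc)  # var of log S
    var_s = np.where(np.isfinite(cum), surv**2 * cum, 0.0)
    z = 1.959963984540054 if alpha == 0.05 else _z(alpha)
    with np.errstate(over="ignore", invalid="ignore"):
        lo = np.where(surv > 0, surv * np.exp(-z * np.sqrt(cum)), 0.0)
        hi = np.where(surv > 0, surv * np.exp(z * np.sqrt(cum)), 0.0)
    return KMCurve(
        event_times=t,
        at_risk=n,
        n_events=d,
        survival=surv,
        greenwood_var=var_s,
        ci_lo=np.clip(np.nan_to_num(lo), 0.0, 1.0),
        ci_hi=np.clip(np.nan_to_num(hi, posinf=1.0), 0.0, 1.0),
    )


def _z(alpha: float) -> float:
    from scipy.stats import norm

    return float(norm.ppf(1 - alpha / 2))


def reverse_km(times, events):
    """Median follow-up and IQR by reverse Kaplan-Meier.

    Event and censor roles are swapped, so the 'event' is end of follow-up
    and deaths censor. Quantiles the curve never reaches come back as NaN.
    Returns ``(median, (q1, q3))`` in the input time unit.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    if times.size == 0:
        raise ValueError("no observations")
    kmf = KaplanMeierFitter()
    kmf.fit(times, ~events)
    sf = kmf.survival_function_.iloc[:, 0]

    def first_time_at_or_below(level: float) -> float:
        hit = sf[sf <= level + 1e-12]
        return float(hit.index[0]) if len(hit) else float("nan")

    median = first_time_at_or_below(0.5)
    q1 = first_time_at_or_below(0.75)
    q3 = first_time_at_or_below(0.25)
    if np.isnan(median):
        warnings.warn("reverse-KM curve never reaches 0.5; median follow-up undefined")
    return median, (q1, q3)


@dataclass
class ARREntry:
    horizon: float
    arr: float  # percentage points, comparator minus treatment mortality
    ci_lo: float
    ci_hi: float
    significant: bool
    available: bool = True

    def __post_init__(self):
        if self.available:
            assert self.significant == (not self.ci_lo <= 0.0 <= self.ci_hi)


def arr_table(curve_comparator: KMCurve, curve_treatment: KMCurve, horizons) -> list:
    """Absolute risk reduction of treatment vs comparator at each horizon.

    ARR(t) = [(1 - S_comparator(t)) - (1 - S_treatment(t))] * 100 in
    percentage points; the 95% CI uses the sum of the two Greenwood
    variances; significant iff 0 lies outside the CI. Horizons beyond both
    curves' support are flagged unavailable.
    """
    out = []
    support = max(curve_comparator.max_time, curve_treatment.max_time)
    for t in horizons:
        if t > support:
            out.append(ARREntry(t, float("nan"), float("nan"), float("nan"), False, False))
            continue
        arr = (curve_treatment.survival_at(t) - curve_comparator.survival_at(t)) * 100.0
        se = float(
            np.sqrt(curve_comparator.variance_at(t) + curve_treatment.variance_at(t))
        ) * 100.0
        lo, hi = arr - 1.96 * se, arr + 1.96 * se
        out.append(ARREntry(t, arr, lo, hi, not lo <= 0.0 <= hi))
    return out


def arr_frame(entries) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "horizon_years": e.horizon,
                "arr_pp": e.arr,
                "ci_lo": e.ci_lo,
                "ci_hi": e.ci_hi,
                "significant": e.significant,
                "available": e.available,
            }
            for e in entries
        ]
    )


def logrank(times_a, events_a, times_b, events_b):
    """Two-group log-rank test; returns (chi-square statistic, p)."""
    if len(times_a) == 0 or len(times_b) == 0:
        raise ValueError("both arms must be non-empty")
    res = _ll_logrank(times_a, times_b, np.asarray(events_a, bool), np.asarray(events_b, bool))
    return float(res.test_statistic), float(res.p_value)


@dataclass
class CoxResult:
    """Cox PH fit summary: per-covariate effects plus model-level facts."""

    table: pd.DataFrame  # index: covariate; coef, hr, ci_lo, ci_hi, se, p
    log_likelihood: float
    n: int
    n_events: int
    dropped_covariates: list = field(default_factory=list)

    def hazard_ratio(self, covariate: str) -> float:
        return float(self.table.loc[covariate, "hr"])


def cox_fit(times, events, covariates: pd.DataFrame) -> CoxResult:
    """Cox proportional-hazards fit (partial likelihood, Efron ties).

    Constant covariate columns carry no information for the partial
    likelihood and are dropped with a warning rather than breaking the
    optimizer. Non-convergence raises with lifelines' diagnostics.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    cov = covariates.reset_index(drop=True).astype(float)
    if cov.isna().any().any():
        bad = list(cov.columns[cov.isna().any()])
        raise ValueError(f"missing values in covariates {bad}; Cox models require complete data")
    dropped = [c for c in cov.columns if cov[c].nunique() <= 1]
    if dropped:
        warnings.warn(f"dropping constant covariate(s): {dropped}")
        cov = cov.drop(columns=dropped)
    if cov.shape[1] == 0:
        raise ValueError("no usable covariates")
    df = cov.copy()
    df["_time"] = times
    df["_event"] = events.astype(int)
    cph = CoxPHFitter()
    try:
        cph.fit(df, duration_col="_time", event_col="_event")
    except Exception as exc:  # lifelines raises ConvergenceError and friends
        raise RuntimeError(f"Cox model failed to converge: {exc}") from exc
    summ = cph.summary
    table = pd.DataFrame(
        {
            "coef": summ["coef"],
            "hr": np.exp(summ["coef"]),
            "ci_lo": np.exp(summ["coef"] - 1.96 * summ["se(coef)"]),
            "ci_hi": np.exp(summ["coef"] + 1.96 * summ["se(coef)"]),
            "se": summ["se(coef)"],
            "p": summ["p"],
        }
    )
    return CoxResult(
        table=table,
        log_likelihood=float(cph.log_likelihood_),
        n=len(times),
        n_events=int(events.sum()),
        dropped_covariates=dropped,
    )
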