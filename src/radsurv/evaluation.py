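"""Survival-model evaluation and risk stratification.

Harrell's C-index and the maximally-selected log-rank cutpoint are
implemented here; the Kaplan–Meier estimator, log-rank test and
proportional-hazards tables delegate to lifelines, and the 3-year
time-dependent (cumulative/dynamic) AUC with Kaplan–Meier IPCW delegates
to scikit-survival. Undefined quantities (no comparable pairs, no cases
or controls at the horizon) are returned as NaN with a warning, never as
a silent zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank
from sksurv.metrics import cumulative_dynamic_auc
from sksurv.util import Surv

__all__ = [
    "harrell_cindex",
    "time_dependent_auc",
    "KaplanMeierEstimate",
    "km_estimate",
    "logrank_test",
    "optimal_cutpoint",
    "cox_table",
    "evaluate_endpoint",
]

EVALUATION_HORIZON_MONTHS = 36.0  # "3-year" throughout


def _as_arrays(risk, time, event):
    r = np.asarray(risk, dtype=float)
    t = np.asarray(time, dtype=float)
    e = np.asarray(event, dtype=int)
    if not (r.shape == t.shape == e.shape):
        raise ValueError("risk, time and event must have identical shapes")
    return r, t, e


def harrell_cindex(risk, time, event) -> float:
    """Harrell's concordance index for right-censored data.

    A pair (i, j) is comparable iff the strictly smaller time is an
    observed event; it is concordant when the shorter-lived patient has
    the higher predicted risk; risk ties count 0.5. Returns NaN (with a
    warning) when no pair is comparable.
    """
    r, t, e = _as_arrays(risk, time, event)
    comparable = (t[:, None] < t[None, :]) & (e[:, None] == 1)
    n_comp = int(comparable.sum())
    if n_comp == 0:
        warnings.warn("no comparable pairs; C-index undefined", stacklevel=2)
        return float("nan")
    higher = r[:, None] > r[None, :]
    tied = r[:, None] == r[None, :]
    concordant = (comparable & higher).sum() + 0.5 * (comparable & tied).sum()
    return float(concordant / n_comp)


def time_dependent_auc(risk, time, event, t: float = EVALUATION_HORIZON_MONTHS) -> float:
    """Cumulative/dynamic AUC at horizon *t* with Kaplan–Meier IPCW.

    Cases are subjects with an event by *t*, controls those event-free
    past *t*; inverse-probability-of-censoring weights come from the KM
    estimate of the censoring distribution. With no censoring this equals
    the plain binary AUC of (event by t) against risk.
    """
    r, tt, e = _as_arrays(risk, time, event)
    cases = ((tt <= t) & (e == 1)).sum()
    controls = (tt > t).sum()
    if cases == 0 or controls == 0:
        warnings.warn(f"no cases or no controls at t={t}; AUC undefined", stacklevel=2)
        return float("nan")
    y = Surv.from_arrays(e.astype(bool), tt)
    try:
        auc, _ = cumulative_dynamic_auc(y, y, r, [t])
    except ValueError as exc:
        warnings.warn(f"time-dependent AUC undefined at t={t}: {exc}", stacklevel=2)
        return float("nan")
    return float(auc[0])


@dataclass
class KaplanMeierEstimate:
    """Product-limit survival curve with point queries."""

    fitter: KaplanMeierFitter

    def survival_at(self, t) -> float | np.ndarray:
        val = self.fitter.predict(t)
        return float(val) if np.isscalar(t) else np.asarray(val, dtype=float)

    @property
    def curve(self) -> pd.DataFrame:
        return self.fitter.survival_function_


def km_estimate(time, event) -> KaplanMeierEstimate:
    kmf = KaplanMeierFitter()
    kmf.fit(np.asarray(time, dtype=float), np.asarray(event, dtype=int))
    return KaplanMeierEstimate(kmf)


def logrank_test(time_a, event_a, time_b, event_b) -> tuple[float, float]:
    """Two-group two-sided log-rank test: (chi-square statistic, p)."""
    ta, tb = np.asarray(time_a, float), np.asarray(time_b, float)
    if ta.size == 0 or tb.size == 0:
        raise ValueError("both groups must be nonempty")
    res = _ll_logrank(ta, tb, event_observed_A=np.asarray(event_a, int),
                      event_observed_B=np.asarray(event_b, int))
    return float(res.test_statistic), float(res.p_value)


def optimal_cutpoint(risk, time, event, min_group_frac: float = 0.10) -> float:
    """Risk cutoff maximizing the log-rank statistic between the groups
    ``risk < c`` and ``risk >= c``.

    Candidates are the observed risk values leaving at least
    ``min_group_frac`` of patients on each side (a guard against
    degenerate groups; set to 0 to scan every split). Ties in the
    statistic resolve to the lower cutoff.
    """
    r, t, e = _as_arrays(risk, time, event)
    if r.size < 10:
        raise ValueError("need at least 10 patients for cutpoint selection")
    if e.sum() == 0:
        raise ValueError("no events; cutpoint undefined")
    n = r.size
    min_count = max(1, int(np.ceil(min_group_frac * n)))
    candidates = [c for c in np.unique(r)
                  if min_count <= (r < c).sum() and min_count <= (r >= c).sum()]
    if not candidates:
        raise ValueError("no admissible cutoff (risks too concentrated)")
    best_c, best_stat = None, -np.inf
    for c in candidates:  # ascending: strict improvement keeps the lower tie
        lo = r < c
        stat, _ = logrank_test(t[lo], e[lo], t[~lo], e[~lo])
        if stat > best_stat:
            best_c, best_stat = float(c), stat
    return best_c


_UNSTABLE_COEF = 15.0  # |log HR| beyond this flags monotone-likelihood separation


def _fit_cox(df: pd.DataFrame, covariates: list[str]) -> pd.DataFrame:
    cph = CoxPHFitter()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cph.fit(df[["time", "event"] + covariates], duration_col="time",
                event_col="event", show_progress=False)
    return cph.summary


def cox_table(covariates: pd.DataFrame, time, event,
              horizon: float = EVALUATION_HORIZON_MONTHS) -> pd.DataFrame:
    """Univariate + multivariate proportional-hazards table (Efron ties).

    One row per covariate with HR, 95% CI and p from the univariate fit,
    the multivariate p from the joint fit of all covariates, and — for
    binary covariates — the per-level Kaplan–Meier survival (%) at
    *horizon*. Exactly collinear covariates are rejected; a fit driven to
    monotone-likelihood separation is flagged ``unstable`` with NaN
    estimates rather than reported as a number.
    """
    cov = covariates.astype(float)
    t = np.asarray(time, dtype=float)
    e = np.asarray(event, dtype=int)
    if cov.isna().any().any():
        raise ValueError("covariates must be complete")
    x = cov.values - cov.values.mean(axis=0)
    if np.linalg.matrix_rank(x) < cov.shape[1]:
        raise ValueError("covariates are collinear; multivariate fit is not identifiable")
    n_terms = cov.shape[1]
    if e.sum() < n_terms:
        warnings.warn(f"only {e.sum()} events for {n_terms} multivariate terms",
                      stacklevel=2)

    base = pd.DataFrame({"time": t, "event": e}, index=cov.index)
    multi = _fit_cox(base.join(cov), list(cov.columns))

    rows = []
    for name in cov.columns:
        uni = _fit_cox(base.join(cov[[name]]), [name])
        coef = float(uni.loc[name, "coef"])
        ses = (float(uni.loc[name, "se(coef)"]), float(multi.loc[name, "se(coef)"]))
        unstable = (abs(coef) > _UNSTABLE_COEF
                    or abs(float(multi.loc[name, "coef"])) > _UNSTABLE_COEF
                    or any(not np.isfinite(s) or s > 100.0 for s in ses))
        row = {
            "variable": name,
            "hr": float(np.exp(coef)) if not unstable else float("nan"),
            "ci_low": float(uni.loc[name, "exp(coef) lower 95%"]) if not unstable else float("nan"),
            "ci_high": float(uni.loc[name, "exp(coef) upper 95%"]) if not unstable else float("nan"),
            "p_univariate": float(uni.loc[name, "p"]),
            "p_multivariate": float(multi.loc[name, "p"]),
            "unstable": bool(unstable),
        }
        vals = np.unique(cov[name])
        if len(vals) == 2:
            for label, level in (("survival_low_pct", vals[0]), ("survival_high_pct", vals[1])):
                sel = cov[name].values == level
                row[label] = 100.0 * km_estimate(t[sel], e[sel]).survival_at(horizon)
        rows.append(row)
    return pd.DataFrame(rows).set_index("variable")


def evaluate_endpoint(risk_train, time_train, event_train,
                      risk_val, time_val, event_val,
                      horizon: float = EVALUATION_HORIZON_MONTHS) -> dict:
    """Full validation report for one fitted model and endpoint.

    The risk cutpoint is derived on the training risks and applied frozen
    to the validation set.
    """
    report: dict = {
        "cindex_validation": harrell_cindex(risk_val, time_val, event_val),
        "cindex_training": harrell_cindex(risk_train, time_train, event_train),
        "auc_horizon_validation": time_dependent_auc(risk_val, time_val, event_val, horizon),
        "horizon_months": horizon,
    }
    try:
        cut = optimal_cutpoint(risk_train, time_train, event_train)
    except ValueError as exc:
        warnings.warn(f"cutpoint not derivable: {exc}", stacklevel=2)
        report["cutpoint"] = float("nan")
        return report
    report["cutpoint"] = cut
    rv = np.asarray(risk_val, dtype=float)
    tv = np.asarray(time_val, dtype=float)
    ev = np.asarray(event_val, dtype=int)
    lo = rv < cut
    report["n_low_risk"] = int(lo.sum())
    report["n_high_risk"] = int((~lo).sum())
    if 0 < lo.sum() < rv.size:
        stat, p = logrank_test(tv[lo], ev[lo], tv[~lo], ev[~lo])
        report["logrank_statistic"] = stat
        report["logrank_p"] = p
        report["survival_low_pct"] = 100.0 * km_estimate(tv[lo], ev[lo]).survival_at(horizon)
        report["survival_high_pct"] = 100.0 * km_estimate(tv[~lo], ev[~lo]).survival_at(horizon)
        try:
            hr_tab = cox_table(pd.DataFrame({"risk_group": (~lo).astype(float)}),
                               tv, ev, horizon=horizon)
            row = hr_tab.loc["risk_group"]
            report["risk_group_hr"] = float(row["hr"])
            report["risk_group_hr_ci"] = [float(row["ci_low"]), float(row["ci_high"])]
            report["risk_group_p"] = float(row["p_univariate"])
        except (ValueError, np.linalg.LinAlgError) as exc:
            warnings.warn(f"risk-group hazard ratio not estimable: {exc}", stacklevel=2)
    else:
        report["logrank_statistic"] = float("nan")
        report["logrank_p"] = float("nan")
    return report
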