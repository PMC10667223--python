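"""Survival analysis: censoring rules, Kaplan-Meier, log-rank, Cox models.

Follow-up runs from the device-upgrade date; death from any cause is the
event.  Right censoring is applied at the earliest of (1) 10 years after
the upgrade, (2) a subsequent CRT-D upgrade in a CRT-P patient, (3) heart
transplantation, or (4) the outcome-query date for patients still alive —
a death occurring after any censoring event does not count.

The estimators are implemented here rather than delegated: the product-
limit estimator with Greenwood variance and log-log confidence bands, the
reverse Kaplan-Meier follow-up estimate (censoring indicator treated as the
event), the k-group Mantel-Cox log-rank test, and Cox partial likelihood
with the Efron correction for tied event times maximized by damped Newton
iteration.  Only generic numerics (numpy / scipy) are used underneath.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

DAYS_PER_YEAR = 365.25

CENSOR_REASONS = ("none", "admin_10y", "subsequent_upgrade", "transplant", "query_date")


# ---------------------------------------------------------------------------
# censoring rules

def apply_censoring(raw: pd.DataFrame, horizon_years: float = 10.0,
                    query_date: str | pd.Timestamp | None = None) -> pd.DataFrame:
    """Derive (time_years, event, censor_reason) from raw date columns.

    ``raw`` needs ``upgrade_date`` and ``death_date`` (nullable); optional
    ``subsequent_upgrade_date`` and ``transplant_date`` (nullable).  Dates
    are ISO-8601 strings or timestamps.  The earliest applicable censoring
    rule wins; death after a censoring event does not count as an event.
    Patients alive and uncensored at the query date are censored there.
    """
    dates = raw.copy()
    for col in ("upgrade_date", "death_date", "subsequent_upgrade_date", "transplant_date"):
        if col in dates.columns:
            dates[col] = pd.to_datetime(dates[col])
    if query_date is not None:
        query_date = pd.Timestamp(query_date)

    out = []
    for _, row in dates.iterrows():
        t0 = row["upgrade_date"]
        candidates: list[tuple[float, str]] = [(horizon_years, "admin_10y")]
        for col, reason in (("subsequent_upgrade_date", "subsequent_upgrade"),
                            ("transplant_date", "transplant")):
            if col in dates.columns and pd.notna(row.get(col)):
                candidates.append((((row[col] - t0).days) / DAYS_PER_YEAR, reason))
        if query_date is not None:
            candidates.append(((query_date - t0).days / DAYS_PER_YEAR, "query_date"))
        censor_t, censor_reason = min(candidates, key=lambda c: c[0])
        if censor_t < 0:
            raise ValueError(f"negative follow-up for patient {row.get('patient_id', '?')}")
        death_t = np.inf
        if pd.notna(row.get("death_date")):
            death_t = (row["death_date"] - t0).days / DAYS_PER_YEAR
            if death_t < 0:
                raise ValueError(
                    f"death precedes upgrade for patient {row.get('patient_id', '?')}")
        if death_t <= censor_t:
            out.append((death_t, 1, "none"))
        else:
            out.append((censor_t, 0, censor_reason))
    result = raw.copy()
    result[["time_years", "event"]] = pd.DataFrame([(t, e) for t, e, _ in out],
                                                   index=raw.index)
    result["censor_reason"] = [r for _, _, r in out]
    return result


# ---------------------------------------------------------------------------
# Kaplan-Meier

@dataclass
class KMCurve:
    """Product-limit estimate with Greenwood SEs and log-log 95% CI."""

    times: np.ndarray           # distinct event times
    survival: np.ndarray        # S(t) at each event time
    std_err: np.ndarray         # Greenwood SE of S(t)
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    at_risk: np.ndarray         # numbers at risk just before each event time
    n_events: np.ndarray

    def survival_at(self, t: float | np.ndarray) -> float | np.ndarray:
        """Step-function evaluation S(t); S = 1 before the first event."""
        t = np.asarray(t, dtype=float)
        if self.times.size == 0:
            s = np.ones_like(t)
        else:
            idx = np.searchsorted(self.times, t, side="right") - 1
            s = np.where(idx >= 0, self.survival[np.clip(idx, 0, None)], 1.0)
        return float(s) if s.ndim == 0 else s

    def median(self) -> float:
        """First time the curve drops to <= 0.5 (NaN if it never does)."""
        below = np.flatnonzero(self.survival <= 0.5)
        return float(self.times[below[0]]) if below.size else float("nan")


def km_estimate(time: np.ndarray, event: np.ndarray, alpha: float = 0.05) -> KMCurve:
    """Kaplan-Meier estimator with Greenwood variance and log-log CI."""
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if time.size == 0:
        raise ValueError("need >= 1 record")
    if (time < 0).any():
        raise ValueError("times must be non-negative")
    order = np.argsort(time, kind="stable")
    time, event = time[order], event[order]

    event_times = np.unique(time[event == 1])
    n = time.size
    surv, se, lo, hi, at_risk, d_list = [], [], [], [], [], []
    s = 1.0
    greenwood_sum = 0.0
    z = stats.norm.ppf(1 - alpha / 2)
    for t in event_times:
        n_t = int((time >= t).sum())
        d_t = int(((time == t) & (event == 1)).sum())
        s *= 1.0 - d_t / n_t
        if n_t > d_t:
            greenwood_sum += d_t / (n_t * (n_t - d_t))
        var = s * s * greenwood_sum
        surv.append(s)
        se.append(np.sqrt(var))
        if 0 < s < 1:
            # log(-log S) scale keeps the bounds inside [0, 1].
            theta_se = np.sqrt(greenwood_sum) / abs(np.log(s))
            lo.append(s ** np.exp(z * theta_se))
            hi.append(s ** np.exp(-z * theta_se))
        else:
            lo.append(s)
            hi.append(s)
        at_risk.append(n_t)
        d_list.append(d_t)
    return KMCurve(times=event_times, survival=np.array(surv), std_err=np.array(se),
                   ci_lower=np.array(lo), ci_upper=np.array(hi),
                   at_risk=np.array(at_risk), n_events=np.array(d_list))


def reverse_km_followup(time: np.ndarray, event: np.ndarray) -> dict:
    """Median follow-up (with IQR) by the reverse Kaplan-Meier method.

    The censoring indicator (1 - event) is treated as the event, so deaths
    censor the follow-up process.  If the flipped curve never reaches 0.5
    the median is undefined (NaN) with a warning.
    """
    event = np.asarray(event, dtype=int)
    curve = km_estimate(time, 1 - event)

    def quantile(q: float) -> float:
        below = np.flatnonzero(curve.survival <= q)
        return float(curve.times[below[0]]) if below.size else float("nan")

    median = quantile(0.5)
    if np.isnan(median):
        warnings.warn("reverse-KM curve never reaches 0.5; median follow-up undefined")
    return {"median": median, "q1": quantile(0.75), "q3": quantile(0.25)}


# ---------------------------------------------------------------------------
# log-rank

def logrank(time: np.ndarray, event: np.ndarray, group: np.ndarray) -> dict:
    """Mantel-Cox k-group log-rank test (chi-square with k-1 df)."""
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    group = np.asarray(group)
    labels, gidx = np.unique(group, return_inverse=True)
    k = labels.size
    if k < 2:
        raise ValueError("need >= 2 groups")
    counts = np.bincount(gidx, minlength=k)
    if (counts == 0).any():
        raise ValueError("every group needs >= 1 patient")
    if event.sum() == 0:
        raise ValueError("need >= 1 event")

    event_times = np.unique(time[event == 1])
    O = np.zeros(k)
    E = np.zeros(k)
    V = np.zeros((k, k))
    for t in event_times:
        at_risk = time >= t
        n_t = int(at_risk.sum())
        d_t = int(((time == t) & (event == 1)).sum())
        n_g = np.bincount(gidx[at_risk], minlength=k).astype(float)
        d_g = np.bincount(gidx[(time == t) & (event == 1)], minlength=k).astype(float)
        O += d_g
        E += d_t * n_g / n_t
        if n_t > 1:
            # hypergeometric covariance of the group-wise death counts
            factor = d_t * (n_t - d_t) / (n_t - 1)
            V += factor * (np.diag(n_g / n_t) - np.outer(n_g, n_g) / n_t ** 2)
    diff = (O - E)[:-1]
    Vsub = V[:-1, :-1]
    chi2 = float(diff @ np.linalg.pinv(Vsub) @ diff)
    df = k - 1
    p = float(stats.chi2.sf(chi2, df))
    return {"statistic": chi2, "df": df, "p": p, "observed": O, "expected": E}


# ---------------------------------------------------------------------------
# Cox proportional hazards (Efron ties)

@dataclass
class CoxResult:
    """Fitted Cox model: per-covariate effects and model-level summaries."""

    names: list[str]
    coef: np.ndarray            # log hazard ratios
    hr: np.ndarray
    se: np.ndarray
    ci_lower: np.ndarray        # on the HR scale
    ci_upper: np.ndarray
    p: np.ndarray               # Wald
    log_likelihood: float
    n: int
    n_events: int
    n_iter: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "covariate": self.names, "coef": self.coef, "HR": self.hr,
            "se": self.se, "ci_lower": self.ci_lower, "ci_upper": self.ci_upper,
            "p": self.p,
        })


#: Covariates of the published multivariable all-cause-mortality model
#: (besides device type): age, sex, AF history, HF etiology, creatinine,
#: LVEF, ACE-I/ARB use and loop-diuretic use.
MULTIVARIABLE_PRESET: tuple[str, ...] = (
    "device_type", "age", "sex", "af", "ischemic_etiology",
    "creatinine", "lvef", "acei_arb", "loop_diuretic",
)


def _efron_loglik(beta, X, time, event):
    """Efron-tie log partial likelihood with gradient and Hessian.

    Loops over distinct event times; risk sets are suffix sums of the
    time-sorted data.
    """
    n, p = X.shape
    eta = X @ beta
    # guard against overflow in exp for extreme steps
    eta = np.clip(eta, -500, 500)
    w = np.exp(eta)
    wX = X * w[:, None]

    order = np.argsort(-time, kind="stable")  # descending time
    Xs, ts, es, ws, wXs = X[order], time[order], event[order], w[order], wX[order]
    cum_w = np.cumsum(ws)
    cum_wX = np.cumsum(wXs, axis=0)
    cum_wXX = np.cumsum(wXs[:, :, None] * Xs[:, None, :], axis=0)

    ll = 0.0
    grad = np.zeros(p)
    hess = np.zeros((p, p))
    i = 0
    while i < n:
        j = i
        while j < n and ts[j] == ts[i]:
            j += 1
        tied = np.arange(i, j)[es[i:j] == 1]
        d = tied.size
        if d:
            S0_R = cum_w[j - 1]
            S1_R = cum_wX[j - 1]
            S2_R = cum_wXX[j - 1]
            S0_D = ws[tied].sum()
            S1_D = wXs[tied].sum(axis=0)
            S2_D = (wXs[tied][:, :, None] * Xs[tied][:, None, :]).sum(axis=0)
            ll += Xs[tied].sum(axis=0) @ beta
            for l in range(d):
                f = l / d
                s0 = S0_R - f * S0_D
                s1 = S1_R - f * S1_D
                s2 = S2_R - f * S2_D
                ll -= np.log(s0)
                grad -= s1 / s0
                hess -= s2 / s0 - np.outer(s1, s1) / s0 ** 2
            grad += Xs[tied].sum(axis=0)
        i = j
    return ll, grad, hess


def cox_fit(time: np.ndarray, event: np.ndarray, X: np.ndarray,
            names: list[str] | None = None, tol: float = 1e-8,
            max_iter: int = 100, alpha: float = 0.05) -> CoxResult:
    """Cox proportional-hazards fit (Efron ties, damped Newton iteration).

    Convergence on the change in log partial likelihood (< ``tol``); Wald
    CIs from the observed information.  Raises on constant covariates and
    on non-convergence (with the iteration trace in the message); warns
    when events < covariates.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != time.size:
        X = X.T
    n, p = X.shape
    names = list(names) if names is not None else [f"x{j}" for j in range(p)]
    const = X.std(axis=0) == 0
    if const.any():
        bad = [names[j] for j in np.flatnonzero(const)]
        raise ValueError(f"constant covariate(s): {bad}")
    n_events = int(event.sum())
    if n_events < p:
        warnings.warn(f"only {n_events} events for {p} covariates; estimates unstable")

    # Center covariates for numerical stability (does not change beta).
    mu = X.mean(axis=0)
    Xc = X - mu
    beta = np.zeros(p)
    ll, grad, hess = _efron_loglik(beta, Xc, time, event)
    trace = [ll]
    converged = False
    for it in range(1, max_iter + 1):
        try:
            step = np.linalg.solve(-hess, grad)
        except np.linalg.LinAlgError as exc:
            raise ValueError(f"singular information matrix (separation?): {exc}") from exc
        # Damped step: halve until the likelihood does not decrease.
        scale = 1.0
        for _ in range(30):
            new_beta = beta + scale * step
            new_ll, new_grad, new_hess = _efron_loglik(new_beta, Xc, time, event)
            if new_ll >= ll - 1e-12:
                break
            scale /= 2
        else:
            raise ValueError(f"step halving failed; trace={trace}")
        delta = new_ll - ll
        beta, ll, grad, hess = new_beta, new_ll, new_grad, new_hess
        trace.append(ll)
        if abs(delta) < tol:
            converged = True
            break
    if not converged:
        raise ValueError(f"Cox fit did not converge in {max_iter} iterations; trace={trace}")
    # a log-HR beyond ~e^20 has no clinical meaning and signals separation
    if np.abs(beta).max() > 20:
        raise ValueError(f"divergent coefficients (separation?): {beta}")

    cov = np.linalg.inv(-hess)
    se = np.sqrt(np.diag(cov))
    z = stats.norm.ppf(1 - alpha / 2)
    return CoxResult(
        names=names, coef=beta, hr=np.exp(beta), se=se,
        ci_lower=np.exp(beta - z * se), ci_upper=np.exp(beta + z * se),
        p=2 * stats.norm.sf(np.abs(beta) / se),
        log_likelihood=float(ll), n=n, n_events=n_events, n_iter=it,
    )


# ---------------------------------------------------------------------------
# subgroup (forest-plot) analysis

#: Subgroup splits of the published forest plot: HF etiology, age at 80,
#: sex, NYHA class, GFR at 60, AF history, DM history, and LVEF at 30.
SUBGROUP_DEFINITIONS: dict[str, tuple] = {
    "ischemic_etiology": ("binary", {1: "ischemic", 0: "non-ischemic"}),
    "age": ("threshold", 80.0, "< 80", ">= 80"),
    "sex": ("binary", {1: "male", 0: "female"}),
    "nyha_34": ("binary", {1: "NYHA III-IV", 0: "NYHA II"}),
    "gfr": ("threshold", 60.0, "GFR < 60", "GFR >= 60"),
    "af": ("binary", {1: "AF", 0: "no AF"}),
    "dm": ("binary", {1: "DM", 0: "no DM"}),
    "lvef": ("threshold", 30.0, "LVEF < 30", "LVEF >= 30"),
}


def subgroup_forest(cohort: pd.DataFrame, treatment: str = "device_type",
                    definitions: dict | None = None) -> pd.DataFrame:
    """Univariable treatment HR within each clinical subgroup.

    For every stratum of every splitting variable, fits a univariable Cox
    model of the treatment indicator.  Strata with zero events (or where
    the fit degenerates) report an undefined (NaN) HR rather than raising.
    Returns a tidy table ready for a forest plot.
    """
    definitions = definitions or SUBGROUP_DEFINITIONS
    rows = []
    for var, rule in definitions.items():
        if rule[0] == "binary":
            strata = [(label, cohort[var] == value) for value, label in rule[1].items()]
        else:
            _, cut, lab_lo, lab_hi = rule
            strata = [(lab_lo, cohort[var] < cut), (lab_hi, cohort[var] >= cut)]
        for label, mask in strata:
            mask = mask & cohort[var].notna()
            sub = cohort.loc[mask]
            row = {"variable": var, "stratum": label, "n": int(len(sub)),
                   "n_events": int(sub["event"].sum()),
                   "hr": np.nan, "ci_lower": np.nan, "ci_upper": np.nan, "p": np.nan}
            if row["n_events"] > 0 and sub[treatment].nunique() == 2:
                try:
                    fit = cox_fit(sub["time_years"].to_numpy(), sub["event"].to_numpy(),
                                  sub[[treatment]].to_numpy(), names=[treatment])
                    row.update(hr=float(fit.hr[0]), ci_lower=float(fit.ci_lower[0]),
                               ci_upper=float(fit.ci_upper[0]), p=float(fit.p[0]))
                except ValueError:
                    pass  # degenerate stratum: HR stays undefined
            rows.append(row)
    return pd.DataFrame(rows)
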