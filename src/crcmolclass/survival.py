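"""Disease-free-survival analysis by molecular group.

Kaplan–Meier curves and Cox proportional-hazards fits (Efron tie
correction, via lifelines), with administrative truncation at 5 years
applied before every analysis and all fits conditioned on the
clinico-pathological covariates.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError

from .association import binary_factor
from .cohort import GRADE_ORDER, Cohort

__all__ = [
    "KmCurve", "CoxFitResult", "truncate_followup",
    "km_estimate", "cox_fit", "group_survival_analysis",
    "CLINPATH_COVARIATES",
]

#: Full clinico-pathological adjustment set.
CLINPATH_COVARIATES = ("sex", "age", "site", "stage", "grade", "arm", "chemo", "radio")


@dataclasses.dataclass
class KmCurve:
    group: str
    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    censor_times: np.ndarray

    def at(self, t: float) -> float:
        """Step-function evaluation S(t)."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return float(self.survival[idx]) if idx >= 0 else 1.0


@dataclasses.dataclass
class CoxFitResult:
    terms: pd.DataFrame     # coef, se, hr, ci_low, ci_high, p  (per covariate)
    log_partial_likelihood: float
    n: int
    events: int

    def hr(self, term: str) -> float:
        return float(self.terms.loc[term, "hr"])

    def ci(self, term: str) -> tuple[float, float]:
        row = self.terms.loc[term]
        return float(row["ci_low"]), float(row["ci_high"])


def truncate_followup(times, events, horizon: float = 5.0):
    """Administrative truncation: events after the horizon become censorings
    at the horizon."""
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    over = t > horizon
    return np.where(over, horizon, t), np.where(over, 0, e)


def km_estimate(times, events, labels=None, horizon: float = 5.0) -> dict[str, KmCurve]:
    """Product-limit estimator per group label (single group "all" if no
    labels), after administrative truncation."""
    t, e = truncate_followup(times, events, horizon)
    if (t < 0).any():
        raise ValueError("negative survival time")
    labels = np.asarray(["all"] * len(t)) if labels is None else np.asarray(labels, dtype=object)
    out: dict[str, KmCurve] = {}
    for g in pd.unique(labels):
        sel = labels == g
        if not sel.any():
            warnings.warn(f"empty group {g!r} skipped")
            continue
        kmf = KaplanMeierFitter()
        kmf.fit(t[sel], e[sel])
        sf = kmf.survival_function_
        times_g = sf.index.to_numpy(dtype=float)
        surv_g = sf.iloc[:, 0].to_numpy(dtype=float)
        at_risk = np.array([np.sum(t[sel] >= u) for u in times_g])
        out[str(g)] = KmCurve(
            group=str(g), times=times_g, survival=surv_g, at_risk=at_risk,
            censor_times=np.sort(t[sel][e[sel] == 0]))
    return out


def _covariate_frame(cohort: Cohort, covariates) -> pd.DataFrame:
    cols = {}
    for c in covariates:
        if c == "age":
            cols[c] = cohort.df["age"].astype(float)
        elif c == "grade":
            cols[c] = cohort.df["grade"].map(GRADE_ORDER).astype(float)
        else:
            cols[c] = binary_factor(cohort, c).astype(float)
    return pd.DataFrame(cols)


def cox_fit(cohort: Cohort, covariates: list[str],
            truncate: float = 5.0) -> CoxFitResult:
    """Cox proportional-hazards fit on complete cases.

    Partial likelihood with the Efron correction for ties, Newton-type
    maximization, Wald p-values.  Complete separation or non-convergence
    raises with the offending covariates named.
    """
    X = _covariate_frame(cohort, covariates)
    t, e = truncate_followup(cohort.df["dfs_years"], cohort.df["dfs_event"].astype(float),
                             truncate)
    frame = X.copy()
    frame["_time"] = t
    frame["_event"] = e
    frame = frame.dropna()
    if frame["_event"].sum() < 1:
        raise ValueError("no events in follow-up window")
    cph = CoxPHFitter()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(frame, duration_col="_time", event_col="_event")
    except ConvergenceError as exc:
        raise ValueError(f"Cox fit failed for covariates {covariates}: {exc}") from exc
    s = cph.summary
    terms = pd.DataFrame({
        "coef": s["coef"],
        "se": s["se(coef)"],
        "hr": s["exp(coef)"],
        "ci_low": s["exp(coef) lower 95%"],
        "ci_high": s["exp(coef) upper 95%"],
        "p": s["p"],
    })
    return CoxFitResult(
        terms=terms,
        log_partial_likelihood=float(cph.log_likelihood_),
        n=int(len(frame)),
        events=int(frame["_event"].sum()),
    )


def group_survival_analysis(cohort: Cohort, mode: str = "one_vs_rest",
                            include_msi: bool = False,
                            covariates=CLINPATH_COVARIATES,
                            truncate: float = 5.0):
    """Survival models for the molecular groups.

    ``categorical`` fits one model with indicator terms for groups 2-7
    (group 1 reference); ``one_vs_rest`` fits one model per group 1-6
    (group 7, the miscellaneous group, is not tested).  Every fit is
    conditioned on the clinico-pathological covariates; ``include_msi``
    adds an MSI term.  Per-fit failures are collected, not fatal.
    """
    df = cohort.df
    if df["group"].isna().all():
        raise ValueError("cohort must be classified first")
    extra = ["msi"] if include_msi else []
    results: dict[str, CoxFitResult | str] = {}
    if mode == "categorical":
        work = cohort.copy()
        terms = []
        for g in "234567":
            col = f"grp{g}"
            work.df[col] = (df["group"] == g).astype(int)
            terms.append(col)
        # indicator columns live outside the schema; bypass binary_factor
        X = _covariate_frame(cohort, list(covariates) + extra)
        for g, col in zip("234567", terms):
            X[col] = (df["group"] == g).astype(float)
        t, e = truncate_followup(df["dfs_years"], df["dfs_event"].astype(float), truncate)
        X["_time"], X["_event"] = t, e
        X = X.dropna()
        cph = CoxPHFitter()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(X, duration_col="_time", event_col="_event")
        s = cph.summary
        results["categorical"] = CoxFitResult(
            terms=pd.DataFrame({
                "coef": s["coef"], "se": s["se(coef)"], "hr": s["exp(coef)"],
                "ci_low": s["exp(coef) lower 95%"],
                "ci_high": s["exp(coef) upper 95%"], "p": s["p"],
            }),
            log_partial_likelihood=float(cph.log_likelihood_),
            n=int(len(X)), events=int(X["_event"].sum()))
        return results
    if mode != "one_vs_rest":
        raise ValueError(f"unknown mode {mode!r}")
    for g in "123456":
        name = f"group{g}"
        try:
            results[name] = cox_fit(cohort, [name] + list(covariates) + extra,
                                    truncate=truncate)
        except (ValueError, KeyError) as exc:
            results[name] = f"failed: {exc}"
    return results
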