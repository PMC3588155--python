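"""Contingency-table association testing, FDR control, reverse stepwise
logistic regression, and fixed-effect meta-analysis.

Conventions: Fisher's exact two-sided test (small cells make exact testing
the safe default); sample odds ratio a·d/(b·c) with the Haldane–Anscombe 0.5
correction whenever a cell is zero; Woolf (log-OR) 95% interval on the
corrected table; Benjamini–Hochberg q-values; Mantel–Haenszel fixed-effect
pooling with the Robins–Breslow–Greenland variance.
"""

from __future__ import annotations

import dataclasses
import itertools
import math
import warnings

import numpy as np
import pandas as pd
import scipy.stats as st
import statsmodels.api as sm
from statsmodels.stats.contingency_tables import StratifiedTable
from statsmodels.stats.multitest import multipletests
from statsmodels.tools.sm_exceptions import PerfectSeparationError

from .cohort import CATEGORICAL_LEVELS, GRADE_ORDER, MARKERS, Cohort

__all__ = [
    "ContingencyTable2x2", "AssociationResult", "StepwiseFit",
    "crosstab", "test_association", "fdr_adjust", "pairwise_screen",
    "stepwise_logistic", "meta_analysis", "binary_factor",
]


@dataclasses.dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts (a, b; c, d): rows = factor-1 altered/wild-type, columns =
    factor-2 altered/wild-type."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("counts must be non-negative")
        if self.total < 1:
            raise ValueError("table must contain at least one observation")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=float)

    def has_zero_margin(self) -> bool:
        return (self.a + self.b == 0 or self.c + self.d == 0
                or self.a + self.c == 0 or self.b + self.d == 0)


@dataclasses.dataclass
class AssociationResult:
    factors: tuple[str, str]
    odds_ratio: float | None
    ci_low: float | None
    ci_high: float | None
    p: float
    q: float | None = None
    sign: str = "none"          # positive / negative / none
    table: ContingencyTable2x2 | None = None
    note: str = ""


@dataclasses.dataclass
class StepwiseFit:
    outcome: str
    retained: pd.DataFrame          # coef, odds_ratio, ci_low, ci_high, p
    dropped: list[tuple[str, str]]  # (predictor, reason)
    n_used: int
    path: list[str]                 # elimination narrative


def binary_factor(cohort: Cohort, name: str) -> pd.Series:
    """Binary (0/1/NA) coding of a marker or covariate column.

    Covariates are coded: female=1, proximal=1, stage III=1, poor grade=1,
    rofecoxib=1; molecular markers keep their altered=1 coding; group
    columns may be addressed as e.g. ``group1`` (membership vs rest).
    """
    df = cohort.df
    if name in MARKERS:
        return df[name].astype("Int64")
    if name.startswith("group") and name[5:] in "1234567":
        g = df["group"]
        out = (g == name[5:]).astype("Int64")
        out[g.isna() | (g == "unclassifiable")] = pd.NA
        return out
    codings = {
        "sex": ("female", CATEGORICAL_LEVELS["sex"]),
        "site": ("proximal", CATEGORICAL_LEVELS["site"]),
        "stage": ("III", CATEGORICAL_LEVELS["stage"]),
        "grade": ("poor", CATEGORICAL_LEVELS["grade"]),
        "arm": ("rofecoxib", CATEGORICAL_LEVELS["arm"]),
    }
    if name in codings:
        positive, _levels = codings[name]
        col = df[name]
        out = (col == positive).astype("Int64")
        out[col.isna()] = pd.NA
        return out
    if name in ("chemo", "radio", "dfs_event"):
        return df[name].astype("Int64")
    raise ValueError(f"factor {name!r} is not binary-codable")


def crosstab(cohort: Cohort, f1: str, f2: str) -> ContingencyTable2x2:
    """2×2 cross-classification over complete-case rows."""
    x = binary_factor(cohort, f1)
    y = binary_factor(cohort, f2)
    ok = x.notna() & y.notna()
    if not ok.any():
        raise ValueError(f"no complete cases for {f1} × {f2}")
    x, y = x[ok].astype(int), y[ok].astype(int)
    return ContingencyTable2x2(
        a=int(((x == 1) & (y == 1)).sum()),
        b=int(((x == 1) & (y == 0)).sum()),
        c=int(((x == 0) & (y == 1)).sum()),
        d=int(((x == 0) & (y == 0)).sum()),
    )


def test_association(table: ContingencyTable2x2,
                     factors: tuple[str, str] = ("f1", "f2"),
                     method: str = "fisher") -> AssociationResult:
    """Two-sided association test on a 2×2 table.

    ``method`` is ``"fisher"`` (exact, default) or ``"chi2"`` (Pearson with
    continuity correction).  The odds ratio is the cross-product ratio with
    the Haldane–Anscombe 0.5 correction when any cell is zero; its 95% CI is
    the Woolf log-OR interval on the (corrected) table.
    """
    arr = table.as_array()
    if table.has_zero_margin():
        return AssociationResult(factors, None, None, None, p=1.0,
                                 table=table, note="zero margin; OR undefined")
    if method == "fisher":
        p = float(st.fisher_exact(arr, alternative="two-sided")[1])
    elif method == "chi2":
        p = float(st.chi2_contingency(arr, correction=True)[1])
    else:
        raise ValueError(f"unknown method {method!r}")
    a, b, c, d = arr.ravel()
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    or_ = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    lo, hi = math.exp(math.log(or_) - 1.96 * se), math.exp(math.log(or_) + 1.96 * se)
    return AssociationResult(factors, or_, lo, hi, p=min(1.0, p), table=table)


def fdr_adjust(pvalues) -> np.ndarray:
    """Benjamini–Hochberg q-values; monotone in p, q ≥ p, order-invariant."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def pairwise_screen(cohort: Cohort, factors: list[str],
                    q_threshold: float = 0.05,
                    method: str = "fisher") -> list[AssociationResult]:
    """All-pairs association screen with screen-wide FDR adjustment.

    Per-pair failures (e.g. no complete cases) are returned as flagged rows
    with p = 1 rather than aborting the screen.  Results are sorted by q.
    """
    if len(factors) < 2:
        raise ValueError("need at least two factors")
    results: list[AssociationResult] = []
    for f1, f2 in itertools.combinations(factors, 2):
        try:
            results.append(test_association(crosstab(cohort, f1, f2),
                                            (f1, f2), method=method))
        except ValueError as exc:
            results.append(AssociationResult((f1, f2), None, None, None,
                                             p=1.0, note=f"failed: {exc}"))
    qs = fdr_adjust([r.p for r in results])
    for r, q in zip(results, qs):
        r.q = float(q)
        if r.odds_ratio is not None and q < q_threshold:
            r.sign = "positive" if r.odds_ratio > 1 else "negative"
        else:
            r.sign = "none"
    return sorted(results, key=lambda r: (r.q, r.p, r.factors))


def _design_matrix(cohort: Cohort, outcome: str, predictors: list[str]):
    """Complete-case outcome vector and design frame; grade enters as the
    ordered score well=0 < moderate=1 < poor=2, age as continuous years."""
    df = cohort.df
    y = binary_factor(cohort, outcome)
    cols = {}
    for p in predictors:
        if p == "age":
            cols[p] = df["age"]
        elif p == "grade":
            cols[p] = df["grade"].map(GRADE_ORDER)
        else:
            cols[p] = binary_factor(cohort, p)
    X = pd.DataFrame(cols)
    ok = y.notna() & X.notna().all(axis=1)
    return y[ok].astype(int), X[ok].astype(float)


def stepwise_logistic(cohort: Cohort, outcome: str, predictors: list[str],
                      p_exit: float = 0.05) -> StepwiseFit:
    """Reverse (backward) stepwise unconditional logistic regression.

    Starts from the full model and repeatedly removes the highest-p
    predictor above ``p_exit`` until all retained predictors are
    significant.  Predictors that break the fit — perfect collinearity
    (rank deficiency) or separation (unbounded coefficients) — are dropped
    first, with the reason recorded.
    """
    y, X = _design_matrix(cohort, outcome, predictors)
    if y.nunique() < 2:
        raise ValueError(f"outcome {outcome!r} is constant on complete cases")
    n_used = len(y)
    if n_used < 10 * max(1, len(predictors)):
        warnings.warn(f"only {n_used} complete cases for {len(predictors)} predictors")
    dropped: list[tuple[str, str]] = []
    path: list[str] = []
    current = list(predictors)

    # drop exactly collinear columns (rank guard) before fitting
    while len(current) > 1:
        M = sm.add_constant(X[current]).to_numpy()
        if np.linalg.matrix_rank(M) == M.shape[1] and np.linalg.cond(M) < 1e10:
            break
        victim = current[-1]
        current.remove(victim)
        dropped.append((victim, "collinearity"))
        path.append(f"dropped {victim}: excessive co-variation")

    def fit(cols):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = sm.Logit(y, sm.add_constant(X[cols]))
            return model.fit(disp=0, maxiter=200)

    while True:
        try:
            res = fit(current)
            separated = (np.abs(res.params.drop("const")) > 15).any() or not res.mle_retvals["converged"]
        except (PerfectSeparationError, np.linalg.LinAlgError):
            separated = True
        if separated:
            # drop the most extreme offender
            try:
                worst = res.params.drop("const").abs().idxmax()
            except Exception:
                worst = current[-1]
            current.remove(worst)
            dropped.append((worst, "collinearity"))
            path.append(f"dropped {worst}: separation / unstable fit")
            if not current:
                raise ValueError("no predictor yields a stable fit; path: " + "; ".join(path))
            continue
        pvals = res.pvalues.drop("const")
        worst_p = pvals.max()
        if worst_p > p_exit and len(current) > 0:
            victim = pvals.idxmax()
            current.remove(victim)
            dropped.append((victim, "p-threshold"))
            path.append(f"dropped {victim}: p = {worst_p:.3g} > {p_exit}")
            if not current:
                break
            continue
        break

    if current:
        res = fit(current)
        coefs = res.params.drop("const")
        ses = res.bse.drop("const")
        retained = pd.DataFrame({
            "coef": coefs,
            "odds_ratio": np.exp(coefs),
            "ci_low": np.exp(coefs - 1.96 * ses),
            "ci_high": np.exp(coefs + 1.96 * ses),
            "p": res.pvalues.drop("const"),
        })
    else:
        retained = pd.DataFrame(columns=["coef", "odds_ratio", "ci_low", "ci_high", "p"])
    return StepwiseFit(outcome=outcome, retained=retained, dropped=dropped,
                       n_used=n_used, path=path)


def meta_analysis(tables: list[ContingencyTable2x2],
                  labels: list[str] | None = None) -> AssociationResult:
    """Mantel–Haenszel fixed-effect pooled odds ratio across studies.

    All-zero (zero-margin) studies are excluded with a warning; the pooled
    CI uses the Robins–Breslow–Greenland variance.  Per-study ORs are
    attached in ``note``.
    """
    if not tables:
        raise ValueError("need at least one study table")
    labels = labels or [f"study{i + 1}" for i in range(len(tables))]
    keep, kept_labels = [], []
    for t, lab in zip(tables, labels):
        if t.has_zero_margin():
            warnings.warn(f"{lab}: zero margin, excluded from pooling")
            continue
        keep.append(t)
        kept_labels.append(lab)
    if not keep:
        raise ValueError("no poolable studies (all have a zero margin)")
    strata = [t.as_array() for t in keep]
    pooled = StratifiedTable(strata)
    or_ = float(pooled.oddsratio_pooled)
    lo, hi = (float(v) for v in pooled.oddsratio_pooled_confint())
    per_study = {lab: test_association(t).odds_ratio for lab, t in zip(kept_labels, keep)}
    p = float(pooled.test_null_odds().pvalue)
    return AssociationResult(("pooled", "MH"), or_, lo, hi, p=p,
                             note=f"per-study OR: {per_study}")
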