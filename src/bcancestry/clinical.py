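"""The clinical regression battery, deprivation tests and screening windows.

All models treat genetic ancestry as an unordered factor with the EUR
group as reference level:

* ages (at diagnosis, at death): ordinary least squares, effects in
  years;
* categorical outcomes (receptor status, grade, stage, nodal
  involvement, deprivation quintile): logistic regression on a
  dichotomised outcome, with the positive receptor state as reference
  and small upper ordinal levels merged;
* tumour mutational burden: negative-binomial regression on retained
  mutation counts with a log exome-size offset, so exponentiated
  coefficients are TMB rate ratios.

Deprivation (IMD) enters twice: a nested likelihood-ratio test of
ancestry-only vs ancestry+IMD models, and within-group association
tests of IMD against the other clinical variables.  Screening windows
are the central 60% of a group's age-at-diagnosis distribution (20th
to 80th percentile).
"""

from __future__ import annotations

import math
import warnings
from typing import Callable, Dict, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm

from bcancestry.records import LRTResult, RegressionRecord, ScreeningWindow

GROUP_COL = "gAncestry"
REFERENCE = "EUR"


class SingleGroupError(ValueError):
    """Fewer than two usable ancestry levels: no contrast to fit."""


# ---------------------------------------------------------------------------
# design-matrix helpers

def _group_design(
    groups: pd.Series, reference: str
) -> Tuple[pd.DataFrame, List[str]]:
    levels = [l for l in pd.unique(groups) if l != reference]
    if reference not in set(groups):
        raise SingleGroupError(f"reference level {reference!r} absent")
    if not levels:
        raise SingleGroupError("only the reference level is present")
    dummies = pd.get_dummies(groups)[levels].astype(float)
    return dummies, levels


def _records_from_fit(
    fit, outcome: str, levels: Sequence[str], model_kind: str, n_used: int,
    exp_scale: bool,
) -> List[RegressionRecord]:
    ci = fit.conf_int()
    records = []
    for lvl in levels:
        est, lo, hi = fit.params[lvl], ci.loc[lvl, 0], ci.loc[lvl, 1]
        if exp_scale:
            est, lo, hi = math.exp(est), math.exp(lo), math.exp(hi)
        records.append(
            RegressionRecord(
                outcome=outcome, term=lvl, estimate=float(est),
                ci_low=float(lo), ci_high=float(hi), p=float(fit.pvalues[lvl]),
                model_kind=model_kind, n_used=n_used,
            )
        )
    return records


def _flagged(outcome: str, term: str, model_kind: str, n_used: int) -> RegressionRecord:
    return RegressionRecord(
        outcome=outcome, term=term, estimate=float("nan"), ci_low=float("nan"),
        ci_high=float("nan"), p=float("nan"), model_kind=model_kind,
        n_used=n_used, converged=False,
    )


# ---------------------------------------------------------------------------
# linear age models

def fit_age_model(
    table: pd.DataFrame,
    outcome: str = "age_at_diagnosis",
    group_col: str = GROUP_COL,
    reference: str = REFERENCE,
) -> List[RegressionRecord]:
    """OLS of an age outcome on the ancestry factor (EUR reference).

    Complete-case analysis; levels with fewer than two observations are
    flagged rather than fitted.  Returns one record per non-reference
    level.
    """
    data = table[[outcome, group_col]].dropna()
    counts = data[group_col].value_counts()
    small = [l for l in counts.index if counts[l] < 2]
    data = data[~data[group_col].isin(small)]
    if data[group_col].nunique() < 2 or reference not in set(data[group_col]):
        raise SingleGroupError(
            f"need the reference and at least one other level with >= 2 "
            f"observations for {outcome} (usable levels: {sorted(set(data[group_col]))})"
        )
    dummies, levels = _group_design(data[group_col], reference)
    X = sm.add_constant(dummies)
    fit = sm.OLS(data[outcome].astype(float), X).fit()
    records = _records_from_fit(fit, outcome, levels, "linear", len(data), exp_scale=False)
    records += [_flagged(outcome, l, "linear", 0) for l in small]
    return records


# ---------------------------------------------------------------------------
# logistic models for categorical outcomes

#: Built-in dichotomisation rules.  Receptor statuses code the negative
#: state as the event (positive is the reference level); ordinal
#: grade/stage code the upper levels as the event; IMD codes the two
#: most deprived quintiles.
DichotomyRule = Union[Mapping[object, int], Tuple[str, float], Callable[[pd.Series], pd.Series]]

DEFAULT_RULES: Dict[str, DichotomyRule] = {
    "ER": {"negative": 1, "positive": 0},
    "PR": {"negative": 1, "positive": 0},
    "HER2": {"negative": 1, "positive": 0},
    "lymph_node": {"involved": 1, "not": 0},
    "grade": ("ge", 3),
    "stage": ("ge", 3),
    "IMD_quintile": ("le", 2),
}


def merge_small_upper_levels(
    counts: pd.Series, min_count: int = 5
) -> int:
    """Lowest cutpoint whose upper tail holds >= ``min_count`` observations.

    ``counts`` maps ordinal level -> count.  Starting from the top
    level, adjacent upper levels are merged until the pooled upper cell
    reaches ``min_count``; returns the resulting cutpoint (events are
    levels >= cutpoint).
    """
    levels = sorted(counts.index)
    if len(levels) < 2:
        raise ValueError("need at least two ordinal levels")
    for cut in reversed(levels[1:]):
        if sum(counts.get(l, 0) for l in levels if l >= cut) >= min_count:
            return cut
    return levels[1]


def dichotomise(
    series: pd.Series, rule: DichotomyRule, min_upper: int = 5
) -> pd.Series:
    """Map an outcome column to 0/1 per a rule; unmapped values become NaN."""
    if callable(rule):
        return rule(series)
    if isinstance(rule, tuple):
        op, cut = rule
        numeric = pd.to_numeric(series, errors="coerce")
        counts = numeric.value_counts()
        if op == "ge":
            if counts[counts.index >= cut].sum() < min_upper and len(counts) >= 2:
                cut = merge_small_upper_levels(counts, min_upper)
            return (numeric >= cut).astype(float).where(numeric.notna())
        if op == "le":
            return (numeric <= cut).astype(float).where(numeric.notna())
        raise ValueError(f"unknown dichotomy operator {op!r}")
    return series.map(dict(rule)).astype(float)


def fit_categorical_model(
    table: pd.DataFrame,
    outcome: str,
    rule: Optional[DichotomyRule] = None,
    group_col: str = GROUP_COL,
    reference: str = REFERENCE,
) -> List[RegressionRecord]:
    """Logistic regression of a dichotomised outcome on the ancestry factor.

    Odds ratios are reported per non-reference level.  Levels whose
    outcome is constant (complete separation for that dummy) are
    flagged non-converged and left out of the fit; a constant outcome
    overall flags every level.
    """
    if rule is None:
        if outcome not in DEFAULT_RULES:
            raise ValueError(f"no built-in dichotomy for {outcome!r}; pass a rule")
        rule = DEFAULT_RULES[outcome]
    y = dichotomise(table[outcome], rule)
    data = pd.DataFrame({"y": y, group_col: table[group_col]}).dropna()
    if data[group_col].nunique() < 2 or reference not in set(data[group_col]):
        raise SingleGroupError(f"need >= 2 ancestry levels for {outcome}")
    levels_all = [l for l in pd.unique(data[group_col]) if l != reference]
    # per-level separation check: constant outcome within the level
    tab = data.groupby(group_col)["y"].agg(["sum", "count"])
    separated = [
        l for l in levels_all if tab.loc[l, "sum"] in (0, tab.loc[l, "count"])
    ]
    if tab.loc[reference, "sum"] in (0, tab.loc[reference, "count"]) or (
        len(separated) == len(levels_all)
    ):
        return [_flagged(outcome, l, "logistic", int(tab.loc[l, "count"])) for l in levels_all]
    fit_data = data[~data[group_col].isin(separated)]
    dummies, levels = _group_design(fit_data[group_col], reference)
    X = sm.add_constant(dummies)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = sm.Logit(fit_data["y"], X).fit(disp=0, maxiter=200)
    if not fit.mle_retvals.get("converged", False):
        return [_flagged(outcome, l, "logistic", len(fit_data)) for l in levels_all]
    records = _records_from_fit(fit, outcome, levels, "logistic", len(fit_data), exp_scale=True)
    records += [_flagged(outcome, l, "logistic", int(tab.loc[l, "count"])) for l in separated]
    return records


# ---------------------------------------------------------------------------
# negative-binomial TMB model

def fit_tmb_model(
    table: pd.DataFrame,
    counts_col: str = "retained_count",
    group_col: str = GROUP_COL,
    reference: str = REFERENCE,
    exome_mb: float = 35.4,
    use_offset: bool = True,
) -> List[RegressionRecord]:
    """Negative-binomial regression of retained mutation counts on ancestry.

    With ``use_offset`` the exome size enters as a log exposure so the
    exponentiated coefficients are TMB (per-Mb) rate ratios; with a
    shared exome size the offset only moves the intercept, and the
    no-offset variant is provided for completeness.
    """
    data = table[[counts_col, group_col]].dropna()
    y = data[counts_col].astype(float)
    if (y < 0).any():
        raise ValueError("mutation counts must be >= 0")
    if (y == 0).all():
        raise ValueError("all retained counts are zero; TMB model is undefined")
    dummies, levels = _group_design(data[group_col], reference)
    X = sm.add_constant(dummies)
    exposure = np.full(len(data), exome_mb) if use_offset else None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.NegativeBinomial(y, X, exposure=exposure)
        fit = model.fit(disp=0, maxiter=200)
    converged = bool(fit.mle_retvals.get("converged", False))
    if not converged:
        return [_flagged("TMB", l, "negbin", len(data)) for l in levels]
    return _records_from_fit(fit, "TMB", levels, "negbin", len(data), exp_scale=True)


# ---------------------------------------------------------------------------
# IMD confounding tests

def lrt_imd(
    table: pd.DataFrame,
    outcome: str,
    outcome_kind: str = "linear",
    rule: Optional[DichotomyRule] = None,
    group_col: str = GROUP_COL,
    reference: str = REFERENCE,
    imd_col: str = "IMD_quintile",
) -> LRTResult:
    """Nested LRT: (outcome ~ ancestry) vs (outcome ~ ancestry + IMD).

    IMD enters as an unordered 5-level factor, so a full quintile
    spread tests on 4 degrees of freedom.  Both models are fitted on
    the same complete-case rows.
    """
    y = table[outcome]
    if outcome_kind == "logistic":
        y = dichotomise(y, rule if rule is not None else DEFAULT_RULES[outcome])
    data = pd.DataFrame(
        {"y": y, group_col: table[group_col], imd_col: table[imd_col]}
    ).dropna()
    if data[imd_col].nunique() < 2:
        return LRTResult(outcome=outcome, statistic=None, df=0, p=None,
                         n_used=len(data), tested=False, note="IMD constant")
    dummies, _ = _group_design(data[group_col], reference)
    imd_levels = sorted(data[imd_col].unique())
    imd_dummies = pd.get_dummies(data[imd_col])[imd_levels[1:]].astype(float)
    imd_dummies.columns = [f"IMD_{int(c)}" for c in imd_dummies.columns]
    X_red = sm.add_constant(dummies)
    X_full = sm.add_constant(pd.concat([dummies, imd_dummies], axis=1))
    yv = data["y"].astype(float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if outcome_kind == "linear":
            ll_red = sm.OLS(yv, X_red).fit().llf
            ll_full = sm.OLS(yv, X_full).fit().llf
        elif outcome_kind == "logistic":
            ll_red = sm.Logit(yv, X_red).fit(disp=0).llf
            ll_full = sm.Logit(yv, X_full).fit(disp=0).llf
        else:
            raise ValueError(f"unknown outcome kind {outcome_kind!r}")
    stat = max(0.0, 2.0 * (ll_full - ll_red))
    df = imd_dummies.shape[1]
    p = float(stats.chi2.sf(stat, df))
    return LRTResult(outcome=outcome, statistic=float(stat), df=df, p=p, n_used=len(data))


def imd_association_tests(
    table: pd.DataFrame,
    numeric_vars: Sequence[str] = ("age_at_diagnosis",),
    categorical_vars: Sequence[str] = ("ER", "PR", "HER2", "grade", "stage", "lymph_node"),
    imd_col: str = "IMD_quintile",
    group_col: str = GROUP_COL,
) -> pd.DataFrame:
    """Association of IMD with clinical variables inside one ancestry group.

    Numeric variables: one-way ANOVA across quintiles (group means
    returned for direction).  Categorical variables: chi-square test of
    the quintile x category table; 2x2 tables with an expected cell
    below one switch to Fisher's exact test, flagged.
    """
    if group_col in table.columns and table[group_col].nunique() > 1:
        raise ValueError("imd_association_tests expects a single-ancestry table")
    rows = []
    for var in numeric_vars:
        sub = table[[var, imd_col]].dropna()
        quintiles = sorted(sub[imd_col].unique())
        if len(quintiles) < 2:
            rows.append({"variable": var, "test": "anova", "statistic": np.nan,
                         "df": 0, "p": np.nan, "flag": "single quintile"})
            continue
        samples = [sub.loc[sub[imd_col] == q, var].to_numpy() for q in quintiles]
        stat, p = stats.f_oneway(*samples)
        rows.append({
            "variable": var, "test": "anova", "statistic": float(stat),
            "df": len(quintiles) - 1, "p": float(p), "flag": "",
            "group_means": {int(q): float(np.mean(s)) for q, s in zip(quintiles, samples)},
        })
    for var in categorical_vars:
        sub = table[[var, imd_col]].dropna()
        if sub.empty or sub[imd_col].nunique() < 2 or sub[var].nunique() < 2:
            rows.append({"variable": var, "test": "chi2", "statistic": np.nan,
                         "df": 0, "p": np.nan, "flag": "degenerate table"})
            continue
        tab = pd.crosstab(sub[imd_col], sub[var])
        chi2, p, df, expected = stats.chi2_contingency(tab)
        flag = ""
        if (expected < 1).any():
            if tab.shape == (2, 2):
                _, p = stats.fisher_exact(tab.to_numpy())
                chi2, df, flag = np.nan, 0, "exact"
            else:
                flag = "low expected counts"
        rows.append({"variable": var, "test": "chi2", "statistic": float(chi2) if chi2 == chi2 else np.nan,
                     "df": int(df), "p": float(p), "flag": flag})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# screening windows

def derive_screening_window(
    ages: Sequence[float],
    lower_pct: float = 20.0,
    upper_pct: float = 80.0,
    ancestry: str = "",
    coverage_ages: Optional[Sequence[float]] = None,
) -> ScreeningWindow:
    """Screening window from the central band of an age distribution.

    Bounds are the ``lower_pct`` and ``upper_pct`` percentiles (linear
    interpolation between order statistics), rounded outward to whole
    years — the lower bound down, the upper bound up — which biases
    toward inclusiveness.  Coverage is evaluated on ``coverage_ages``
    (default: the same ages).
    """
    arr = np.asarray(list(ages), dtype=float)
    arr = arr[~np.isnan(arr)]
    if len(arr) < 10:
        raise ValueError(f"need >= 10 ages to place a window, got {len(arr)}")
    if np.ptp(arr) == 0:
        raise ValueError("degenerate age distribution (all ages identical)")
    lower = int(math.floor(np.percentile(arr, lower_pct)))
    upper = int(math.ceil(np.percentile(arr, upper_pct)))
    if lower >= upper:
        raise ValueError(f"window collapsed to [{lower}, {upper}]")
    target = arr if coverage_ages is None else np.asarray(list(coverage_ages), dtype=float)
    covered, total, _ = window_coverage(target, (lower, upper))
    return ScreeningWindow(ancestry=ancestry, lower=lower, upper=upper,
                           covered=covered, total=total)


def window_coverage(
    ages: Sequence[float], window: Union[Tuple[float, float], ScreeningWindow]
) -> Tuple[int, int, float]:
    """Count ages inside a window (inclusive ends).

    Returns ``(covered, total, percentage)`` with the percentage
    rounded to one decimal place.
    """
    if isinstance(window, ScreeningWindow):
        lower, upper = window.lower, window.upper
    else:
        lower, upper = window
    if lower >= upper:
        raise ValueError(f"invalid window [{lower}, {upper}]")
    arr = np.asarray(list(ages), dtype=float)
    arr = arr[~np.isnan(arr)]
    if len(arr) == 0:
        raise ValueError("empty age list")
    covered = int(((arr >= lower) & (arr <= upper)).sum())
    return covered, len(arr), round(100.0 * covered / len(arr), 1)
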