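"""Differential somatic mutation between ancestry groups.

Two complementary routes over a binary participant x feature mutation
matrix (features are genes or individual variants):

1. a per-feature logistic model ``mutated ~ ancestry + age at
   diagnosis`` with EUR as reference, Benjamini-Hochberg adjustment
   across features, and significance at adjusted p < 0.1; features the
   model cannot estimate (a feature absent, or universal, in a group)
   are flagged and routed to
2. a strict >2% presence threshold per group: a feature is "present"
   in a cohort of size n when its carrier count exceeds 2% of n
   strictly, i.e. count >= floor(0.02 n) + 1 (47/2343, 3/138, 3/123 at
   the study's sizes); present features fall in one of the seven
   non-empty intersection sets of the three groups.

A confounder-adjusted variant of the logistic model adds germline BRCA
status and deprivation quintile.  Per-patient counts of the somatic
variant classes (substitutions, double substitutions, indels,
rearrangements) are compared against EUR with two-sided Wilcoxon
rank-sum tests.
"""

from __future__ import annotations

import warnings
from fractions import Fraction
from math import floor
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

from bcancestry.tmb import rank_sum_p

ANALYTIC_GROUPS = ("EUR", "AFR", "SAS")
DEFAULT_THRESHOLD = 0.02
DEFAULT_ALPHA = 0.1


def build_mutation_matrix(
    classified: pd.DataFrame,
    participants: Sequence[str],
    feature_kind: str = "gene",
) -> pd.DataFrame:
    """Binary participant x feature matrix from retained somatic calls.

    ``feature_kind='gene'`` collapses to genes; ``'variant'`` keys on
    ``variant_id`` (or chrom:pos:ref:alt when absent).
    """
    retained = classified[classified["retained"]] if "retained" in classified.columns else classified
    if feature_kind == "gene":
        feat = retained["gene"]
    elif feature_kind == "variant":
        if "variant_id" in retained.columns:
            feat = retained["variant_id"]
        else:
            feat = (
                retained["chrom"].astype(str) + ":" + retained["pos"].astype(str)
                + ":" + retained["ref"] + ":" + retained["alt"]
            )
    else:
        raise ValueError(f"feature_kind must be 'gene' or 'variant', got {feature_kind!r}")
    pairs = pd.DataFrame({"participant_id": retained["sample_id"], "feature": feat})
    mat = (
        pairs.groupby(["participant_id", "feature"]).size().gt(0).unstack(fill_value=False)
        if len(pairs)
        else pd.DataFrame()
    )
    mat = mat.reindex(index=participants, fill_value=False).fillna(False).astype(bool)
    mat.index.name = "participant_id"
    mat.attrs["feature_kind"] = feature_kind
    return mat


# ---------------------------------------------------------------------------
# threshold route

def threshold_count(n: int, threshold: float = DEFAULT_THRESHOLD) -> int:
    """Smallest carrier count strictly exceeding ``threshold`` of ``n``.

    Exact rational arithmetic avoids float-rounding artefacts at
    integer multiples of the threshold.
    """
    if n <= 0:
        raise ValueError(f"cohort size must be >= 1, got {n}")
    frac = Fraction(str(threshold))
    return int(floor(n * frac)) + 1


def threshold_classifier(
    matrix: pd.DataFrame,
    ancestry: pd.Series,
    groups: Sequence[str] = ANALYTIC_GROUPS,
    threshold: float = DEFAULT_THRESHOLD,
) -> pd.DataFrame:
    """Presence/absence of each feature per ancestry cohort, with
    intersection labels.

    Returns one row per feature with per-group frequencies, presence
    flags, and the intersection set it belongs to (``None`` when absent
    everywhere).  The headline outputs are the features present in one
    minority group only.
    """
    ancestry = ancestry.reindex(matrix.index)
    sizes = {g: int((ancestry == g).sum()) for g in groups}
    empty = [g for g in groups if sizes[g] == 0]
    if empty:
        raise ValueError(f"empty ancestry cohorts: {empty}")
    mins = {g: threshold_count(sizes[g], threshold) for g in groups}
    rows = []
    for feature in matrix.columns:
        col = matrix[feature]
        row: Dict[str, object] = {"feature": feature}
        present = []
        for g in groups:
            cnt = int(col[ancestry == g].sum())
            row[f"count_{g}"] = cnt
            row[f"freq_{g}"] = cnt / sizes[g]
            flag = cnt >= mins[g]
            row[f"present_{g}"] = flag
            if flag:
                present.append(g)
        row["intersection"] = "+".join(present) if present else None
        rows.append(row)
    out = pd.DataFrame(rows)
    out.attrs["sizes"] = sizes
    out.attrs["min_counts"] = mins
    return out


def intersection_sets(classified: pd.DataFrame, groups: Sequence[str] = ANALYTIC_GROUPS) -> Dict[str, List[str]]:
    """Features per intersection category (the seven non-empty sets)."""
    labels = []
    for k in range(1, len(groups) + 1):
        from itertools import combinations
        labels += ["+".join(c) for c in combinations(groups, k)]
    out = {lab: [] for lab in labels}
    for _, row in classified.iterrows():
        if row["intersection"] is not None:
            out[row["intersection"]].append(row["feature"])
    return out


# ---------------------------------------------------------------------------
# logistic route

def _feature_logistic(
    y: pd.Series,
    X: pd.DataFrame,
    levels: Sequence[str],
) -> Optional[object]:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            fit = sm.Logit(y.astype(float), X).fit(disp=0, maxiter=100)
        except Exception:
            return None
    if not fit.mle_retvals.get("converged", False):
        return None
    # runaway coefficients betray quasi-separation the iteration cap missed
    if any(abs(fit.params[l]) > 15 for l in levels):
        return None
    return fit


def per_feature_logistic(
    matrix: pd.DataFrame,
    ancestry: pd.Series,
    age: pd.Series,
    reference: str = "EUR",
    alpha: float = DEFAULT_ALPHA,
    adjust: str = "bh",
    groups: Sequence[str] = ANALYTIC_GROUPS,
) -> pd.DataFrame:
    """Per-feature logistic fits ``feature ~ ancestry + age`` with BH
    adjustment across features.

    Features with a zero or full cell in any group are flagged
    non-converged up front (the fit would separate) and are the ones
    the threshold classifier should handle.  Adjusted p-values are
    computed within each ancestry contrast, across the converged
    features only; ``significant`` is adjusted p < ``alpha``.
    """
    nonbinary = [
        f for f in matrix.columns
        if set(matrix[f].unique()) - {True, False, 0, 1}
    ]
    if nonbinary:
        raise ValueError(f"non-binary feature columns: {nonbinary[:5]}")
    ancestry = ancestry.reindex(matrix.index)
    age = age.reindex(matrix.index)
    keep = ancestry.isin(groups) & age.notna()
    mat = matrix.loc[keep]
    anc = ancestry.loc[keep]
    levels = [g for g in groups if g != reference]
    dummies = pd.get_dummies(anc)[levels].astype(float)
    X = sm.add_constant(pd.concat([dummies, age.loc[keep].rename("age")], axis=1))
    counts = mat.groupby(anc.values).sum()
    sizes = mat.groupby(anc.values).size()
    rows: List[dict] = []
    for feature in mat.columns:
        cnt = counts[feature]
        separated = any(cnt[g] in (0, sizes[g]) for g in groups)
        if separated:
            for lvl in levels:
                rows.append({"feature": feature, "term": lvl, "odds_ratio": np.nan,
                             "ci_low": np.nan, "ci_high": np.nan, "p": np.nan,
                             "converged": False})
            continue
        fit = _feature_logistic(mat[feature], X, levels)
        if fit is None:
            for lvl in levels:
                rows.append({"feature": feature, "term": lvl, "odds_ratio": np.nan,
                             "ci_low": np.nan, "ci_high": np.nan, "p": np.nan,
                             "converged": False})
            continue
        ci = fit.conf_int()
        for lvl in levels:
            rows.append({
                "feature": feature, "term": lvl,
                "odds_ratio": float(np.exp(fit.params[lvl])),
                "ci_low": float(np.exp(ci.loc[lvl, 0])),
                "ci_high": float(np.exp(ci.loc[lvl, 1])),
                "p": float(fit.pvalues[lvl]),
                "converged": True,
            })
    out = pd.DataFrame(rows)
    out["p_adj"] = np.nan
    method = {"bh": "fdr_bh", "bonferroni": "bonferroni"}[adjust]
    for lvl in levels:
        mask = (out["term"] == lvl) & out["converged"]
        if mask.any():
            out.loc[mask, "p_adj"] = multipletests(out.loc[mask, "p"], method=method)[1]
    out["significant"] = out["p_adj"] < alpha
    return out


def confounder_model(
    matrix: pd.DataFrame,
    ancestry: pd.Series,
    age: pd.Series,
    brca_status: pd.Series,
    imd: pd.Series,
    reference: str = "EUR",
    alpha: float = DEFAULT_ALPHA,
    adjust: str = "bh",
    groups: Sequence[str] = ANALYTIC_GROUPS,
) -> pd.DataFrame:
    """Logistic route with germline BRCA status and IMD as extra terms.

    Restricted to participants with every covariate present, for
    comparison of ancestry odds ratios against the unadjusted model.
    """
    for name, cov in (("brca_status", brca_status), ("IMD", imd)):
        cov = cov.reindex(matrix.index)
        if cov.isna().all():
            raise ValueError(f"covariate {name} is missing for every participant")
    ancestry = ancestry.reindex(matrix.index)
    age = age.reindex(matrix.index)
    brca = brca_status.reindex(matrix.index)
    imd = imd.reindex(matrix.index)
    keep = ancestry.isin(groups) & age.notna() & brca.notna() & imd.notna()
    mat = matrix.loc[keep]
    anc = ancestry.loc[keep]
    levels = [g for g in groups if g != reference]
    dummies = pd.get_dummies(anc)[levels].astype(float)
    imd_levels = sorted(imd.loc[keep].unique())
    extra = pd.DataFrame({
        "age": age.loc[keep].astype(float),
        "brca": brca.loc[keep].astype(float),
    })
    flags = []
    if extra["brca"].nunique() < 2:
        flags.append("brca constant after restriction")
    if len(imd_levels) >= 2:
        imd_d = pd.get_dummies(imd.loc[keep])[imd_levels[1:]].astype(float)
        imd_d.columns = [f"IMD_{int(c)}" for c in imd_d.columns]
        extra = pd.concat([extra, imd_d], axis=1)
    else:
        flags.append("IMD constant after restriction")
    X = sm.add_constant(pd.concat([dummies, extra], axis=1))
    counts = mat.groupby(anc.values).sum()
    sizes = mat.groupby(anc.values).size()
    rows: List[dict] = []
    for feature in mat.columns:
        cnt = counts[feature]
        if any(cnt[g] in (0, sizes[g]) for g in groups):
            fit = None
        else:
            fit = _feature_logistic(mat[feature], X, levels)
        if fit is None:
            for lvl in levels:
                rows.append({"feature": feature, "term": lvl, "odds_ratio": np.nan,
                             "ci_low": np.nan, "ci_high": np.nan, "p": np.nan,
                             "converged": False})
            continue
        ci = fit.conf_int()
        for lvl in levels:
            rows.append({
                "feature": feature, "term": lvl,
                "odds_ratio": float(np.exp(fit.params[lvl])),
                "ci_low": float(np.exp(ci.loc[lvl, 0])),
                "ci_high": float(np.exp(ci.loc[lvl, 1])),
                "p": float(fit.pvalues[lvl]),
                "converged": True,
            })
    out = pd.DataFrame(rows)
    out["p_adj"] = np.nan
    method = {"bh": "fdr_bh", "bonferroni": "bonferroni"}[adjust]
    for lvl in levels:
        mask = (out["term"] == lvl) & out["converged"]
        if mask.any():
            out.loc[mask, "p_adj"] = multipletests(out.loc[mask, "p"], method=method)[1]
    out["significant"] = out["p_adj"] < alpha
    out.attrs["flags"] = flags
    out.attrs["n_used"] = int(keep.sum())
    return out


# ---------------------------------------------------------------------------
# per-patient variant-class comparisons

def variant_class_rates(
    counts: pd.DataFrame,
    ancestry: pd.Series,
    classes: Sequence[str] = ("substitutions", "double_substitutions", "indels", "rearrangements"),
    reference: str = "EUR",
    groups: Sequence[str] = ANALYTIC_GROUPS,
) -> pd.DataFrame:
    """Per-group totals and per-patient rates of the somatic variant
    classes, with rank-sum comparisons against the reference group.

    ``counts`` holds one row per participant with a column per class;
    per-patient rates are group totals over group size, reported to one
    decimal place alongside the exact value.
    """
    ancestry = ancestry.reindex(counts.index)
    rows = []
    for cls in classes:
        if cls not in counts.columns:
            raise ValueError(f"missing variant-class column {cls!r}")
        if (counts[cls].dropna() < 0).any():
            raise ValueError(f"negative counts in {cls!r}")
        ref_vals = counts.loc[ancestry == reference, cls].dropna().to_numpy()
        for g in groups:
            vals = counts.loc[ancestry == g, cls].dropna().to_numpy()
            if len(vals) == 0:
                rows.append({"class": cls, "group": g, "n": 0, "total": 0,
                             "per_patient": np.nan, "per_patient_1dp": np.nan,
                             "p_vs_ref": np.nan, "flag": "group absent"})
                continue
            total = int(vals.sum())
            rate = total / len(vals)
            p = np.nan
            if g != reference and len(ref_vals):
                p = rank_sum_p(vals, ref_vals)
            rows.append({"class": cls, "group": g, "n": len(vals), "total": total,
                         "per_patient": rate, "per_patient_1dp": round(rate, 1),
                         "p_vs_ref": p, "flag": ""})
    return pd.DataFrame(rows)
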