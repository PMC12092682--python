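"""Germline pathogenicity filtering, burden summaries and enrichment.

Germline calls are filtered to a cancer-susceptibility gene panel and
to the canonical transcript, then resolved by ClinVar classification:
``pathogenic_confident`` requires pathogenic/likely-pathogenic at a
review confidence of two stars or more; ``vus`` is any
uncertain-significance call (no star requirement); everything else is
excluded.  Per-gene carrier status feeds a logistic enrichment model
(``carrier ~ factor``) with either ancestry (EUR reference) or
case/control status as the factor, with Benjamini-Hochberg adjustment
across genes.
"""

from __future__ import annotations

from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from scipy.stats.contingency import odds_ratio as _conditional_or
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

from bcancestry.records import RegressionRecord

PATHOGENIC = "pathogenic_confident"
VUS = "vus"
EXCLUDED = "excluded"

PATHOGENIC_CLASSES = {"pathogenic", "likely_pathogenic"}
KNOWN_CLASSES = PATHOGENIC_CLASSES | {"uncertain", "benign", "likely_benign", "other"}
MIN_STARS = 2


def load_panel(*sources: Iterable[str]) -> Set[str]:
    """De-duplicated union of one or more gene lists.

    A source may be a path to a plain-text file (one gene per line,
    ``#`` comments allowed) or any iterable of gene symbols.
    """
    genes: Set[str] = set()
    for src in sources:
        if isinstance(src, str):
            with open(src) as fh:
                entries = [ln.strip() for ln in fh]
        else:
            entries = [str(g).strip() for g in src]
        genes.update(g for g in entries if g and not g.startswith("#"))
    if not genes:
        raise ValueError("panel union is empty")
    return genes


def classify_germline(
    gene: str,
    canonical: bool,
    clinvar_class: str,
    clinvar_stars: int,
    in_panel: bool,
) -> str:
    """Resolve one germline call to pathogenic_confident / vus / excluded."""
    if clinvar_class not in KNOWN_CLASSES:
        raise ValueError(f"unknown ClinVar classification {clinvar_class!r}")
    if not 0 <= int(clinvar_stars) <= 4:
        raise ValueError(f"ClinVar star rating must be 0-4, got {clinvar_stars}")
    if not in_panel or not canonical:
        return EXCLUDED
    if clinvar_class in PATHOGENIC_CLASSES and clinvar_stars >= MIN_STARS:
        return PATHOGENIC
    if clinvar_class == "uncertain":
        return VUS
    return EXCLUDED


def classify_calls(calls: pd.DataFrame, panel: Optional[Set[str]] = None) -> pd.DataFrame:
    """Vectorised classification of a germline call table.

    Requires columns ``participant_id``, ``gene``, ``canonical``,
    ``clinvar_class``, ``clinvar_stars`` and either an ``in_panel``
    column or a ``panel`` gene set.  Returns a copy with a ``fate``
    column.
    """
    required = {"participant_id", "gene", "canonical", "clinvar_class", "clinvar_stars"}
    missing = required - set(calls.columns)
    if missing:
        raise ValueError(f"germline table missing columns: {sorted(missing)}")
    bad = set(calls["clinvar_class"].unique()) - KNOWN_CLASSES
    if bad:
        raise ValueError(f"unknown ClinVar classifications: {sorted(bad)}")
    stars = calls["clinvar_stars"].to_numpy()
    if ((stars < 0) | (stars > 4)).any():
        raise ValueError("ClinVar star ratings must be 0-4")
    if "in_panel" in calls.columns:
        in_panel = calls["in_panel"].astype(bool).to_numpy()
    elif panel is not None:
        in_panel = calls["gene"].isin(panel).to_numpy()
    else:
        raise ValueError("need an in_panel column or an explicit panel gene set")
    canonical = calls["canonical"].astype(bool).to_numpy()
    is_path = calls["clinvar_class"].isin(PATHOGENIC_CLASSES).to_numpy() & (stars >= MIN_STARS)
    is_vus = (calls["clinvar_class"] == "uncertain").to_numpy()
    fate = np.where(
        in_panel & canonical,
        np.where(is_path, PATHOGENIC, np.where(is_vus, VUS, EXCLUDED)),
        EXCLUDED,
    )
    out = calls.copy()
    out["fate"] = fate
    return out


def burden_summary(
    classified: pd.DataFrame,
    group_by_participant: Mapping[str, str],
) -> pd.DataFrame:
    """Per-group mean pathogenic and VUS calls per participant.

    Every participant in ``group_by_participant`` contributes to the
    denominator, including those with zero qualifying calls.
    """
    if "fate" not in classified.columns:
        raise ValueError("classify_calls must be applied first (no 'fate' column)")
    groups = pd.Series(dict(group_by_participant), name="group")
    counts = (
        classified[classified["fate"].isin([PATHOGENIC, VUS])]
        .groupby(["participant_id", "fate"])
        .size()
        .unstack(fill_value=0)
        .reindex(groups.index, fill_value=0)
        .reindex(columns=[PATHOGENIC, VUS], fill_value=0)
    )
    counts["group"] = groups
    rows = []
    for g, sub in counts.groupby("group"):
        rows.append(
            {
                "group": g,
                "n_participants": len(sub),
                "mean_pathogenic": float(sub[PATHOGENIC].mean()),
                "mean_vus": float(sub[VUS].mean()),
                "total_pathogenic": int(sub[PATHOGENIC].sum()),
                "total_vus": int(sub[VUS].sum()),
            }
        )
    return pd.DataFrame(rows)


def carrier_matrix(classified: pd.DataFrame, participants: Sequence[str]) -> pd.DataFrame:
    """Participant x gene matrix of confident-pathogenic carrier flags.

    Multiple qualifying variants in the same gene collapse to one flag
    (standard burden coding).
    """
    path = classified[classified["fate"] == PATHOGENIC]
    mat = (
        path.groupby(["participant_id", "gene"]).size().gt(0).unstack(fill_value=False)
        if len(path)
        else pd.DataFrame(index=pd.Index([], name="participant_id"))
    )
    mat = mat.reindex(index=participants, fill_value=False).fillna(False).astype(bool)
    mat.index.name = "participant_id"
    return mat


def gene_enrichment(
    carriers: pd.DataFrame,
    factor: pd.Series,
    reference: str = "EUR",
    adjust: str = "bh",
    exclude_chrx: bool = False,
    chrx_genes: Optional[Set[str]] = None,
) -> pd.DataFrame:
    """Per-gene logistic enrichment of carrier status on a factor.

    ``carriers`` is the participant x gene boolean matrix; ``factor``
    is ancestry (with ``reference='EUR'``) or case/control status
    (with ``reference='control'``).  Genes where carriers appear in
    only one factor level (perfect separation) are reported as
    inestimable with ``converged=False``.  ``exclude_chrx`` drops the
    given X-linked genes, mirroring call sets without chromosome-X
    coverage.
    """
    factor = factor.reindex(carriers.index)
    if factor.isna().any():
        raise ValueError("factor missing for some participants in the carrier matrix")
    levels = [l for l in pd.unique(factor) if l != reference]
    if reference not in set(factor):
        raise ValueError(f"reference level {reference!r} absent from factor")
    genes = list(carriers.columns)
    if exclude_chrx:
        if chrx_genes is None:
            raise ValueError("exclude_chrx requires the set of X-linked genes")
        genes = [g for g in genes if g not in chrx_genes]
    dummies = pd.get_dummies(factor).reindex(columns=[reference] + levels, fill_value=0)
    X = sm.add_constant(dummies[levels].astype(float))
    rows: List[dict] = []
    for gene in genes:
        y = carriers[gene].astype(float)
        total = y.sum()
        if total == 0:
            rows.append(
                {"gene": gene, "term": None, "odds_ratio": np.nan, "ci_low": np.nan,
                 "ci_high": np.nan, "p": np.nan, "converged": False, "note": "no carriers"}
            )
            continue
        # separation pre-check: a level with zero or all carriers
        by_level = y.groupby(factor).agg(["sum", "count"])
        separated = ((by_level["sum"] == 0) | (by_level["sum"] == by_level["count"])).any()
        if separated:
            for lvl in levels:
                rows.append(
                    {"gene": gene, "term": lvl, "odds_ratio": np.nan, "ci_low": np.nan,
                     "ci_high": np.nan, "p": np.nan, "converged": False,
                     "note": "carriers confined to a subset of levels"}
                )
            continue
        try:
            fit = sm.Logit(y, X).fit(disp=0, maxiter=100)
            ok = bool(fit.mle_retvals.get("converged", False))
        except Exception:  # numerical failure counts as non-convergence
            ok = False
        if not ok:
            for lvl in levels:
                rows.append(
                    {"gene": gene, "term": lvl, "odds_ratio": np.nan, "ci_low": np.nan,
                     "ci_high": np.nan, "p": np.nan, "converged": False, "note": "no convergence"}
                )
            continue
        ci = fit.conf_int()
        for lvl in levels:
            rows.append(
                {
                    "gene": gene,
                    "term": lvl,
                    "odds_ratio": float(np.exp(fit.params[lvl])),
                    "ci_low": float(np.exp(ci.loc[lvl, 0])),
                    "ci_high": float(np.exp(ci.loc[lvl, 1])),
                    "p": float(fit.pvalues[lvl]),
                    "converged": True,
                    "note": "",
                }
            )
    out = pd.DataFrame(rows)
    # BH adjustment across genes, within each factor contrast
    out["p_adj"] = np.nan
    method = {"bh": "fdr_bh", "bonferroni": "bonferroni"}[adjust]
    for lvl in levels:
        mask = (out["term"] == lvl) & out["converged"] & out["p"].notna()
        if mask.any():
            out.loc[mask, "p_adj"] = multipletests(out.loc[mask, "p"], method=method)[1]
    return out


def fisher_2x2(a: int, b: int, c: int, d: int) -> Tuple[float, float]:
    """Two-sided Fisher exact test on [[a, b], [c, d]].

    Returns ``(p, conditional MLE odds ratio)``.  The p-value sums the
    hypergeometric probabilities of all tables (with the observed
    margins) no more probable than the observed one.
    """
    table = np.array([[a, b], [c, d]], dtype=int)
    if (table < 0).any():
        raise ValueError("Fisher table entries must be non-negative integers")
    if table.sum(axis=0).min() == 0 or table.sum(axis=1).min() == 0:
        raise ValueError("Fisher test undefined for an all-zero margin")
    _, p = stats.fisher_exact(table, alternative="two-sided")
    or_cmle = _conditional_or(table, kind="conditional").statistic
    return float(p), float(or_cmle)
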