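"""Ancestry-matched somatic variant retention and tumour mutational burden.

Somatic variants enter a decision tree that first gates on biology
(non-synonymous, exonic) and then on population databases, using the
gnomAD population matched to the sample's genetic ancestry (AFR for
AFR, SAS for SAS, NFE for EUR):

* rule (i):  gnomAD frequency <= 0.1% ("rare") and VAF >= 3%;
* rule (i'): gnomAD frequency <= 0.1%, VAF < 3%, but at least two
  COSMIC identifiers;
* rule (ii): gnomAD frequency > 0.1% and <= 10% with at least two
  COSMIC identifiers;
* override: anything seen in TOPMED at frequency > 0.1% is discarded
  regardless of the rules above.

A frequency absent from gnomAD or TOPMED is treated as 0 (the variant
was not observed in the reference panel).  TMB is the retained count
divided by the exome size in Mb (default 35.4).
"""

from __future__ import annotations

from typing import Dict, Iterable, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

#: gnomAD population used for each analysable ancestry group.
POPULATION_BY_ANCESTRY: Dict[str, str] = {"AFR": "AFR", "SAS": "SAS", "EUR": "NFE"}

RARE_FREQ = 0.001  # 0.1%
COMMON_FREQ_CAP = 0.10  # "<= 10", read as 10%
MIN_VAF = 0.03  # 3%
MIN_COSMIC = 2
TOPMED_MAX = 0.001  # discarded above 0.1%
DEFAULT_EXOME_MB = 35.4

# branch labels, in evaluation order
NOT_ELIGIBLE = "not_eligible"
TOPMED_EXCLUDED = "topmed_excluded"
RARE_VAF = "rare_vaf"
RARE_COSMIC = "rare_cosmic"
COMMON_COSMIC = "common_cosmic"
NOT_RETAINED = "not_retained"


def select_population(ancestry: str) -> str:
    """gnomAD population key for an ancestry label (AFR/SAS/EUR only)."""
    try:
        return POPULATION_BY_ANCESTRY[ancestry]
    except KeyError:
        raise ValueError(
            f"no gnomAD reference population defined for ancestry {ancestry!r}; "
            f"supported: {sorted(POPULATION_BY_ANCESTRY)}"
        ) from None


def _check_fraction(name: str, value: float) -> float:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return 0.0  # absent from the reference panel
    value = float(value)
    if not 0.0 <= value <= 1.0:
        raise ValueError(f"{name} must be a fraction in [0, 1], got {value}")
    return value


def classify_variant(
    consequence: str,
    exonic: bool,
    vaf: float,
    gnomad_freq: Mapping[str, float],
    cosmic_id_count: int,
    topmed_freq: Optional[float],
    ancestry: str,
) -> Tuple[bool, str]:
    """Retain/discard fate of one somatic variant, with the branch applied.

    Returns ``(retained, reason)`` where ``reason`` names the first
    matching branch of the decision tree.
    """
    if consequence != "non-synonymous" or not exonic:
        return False, NOT_ELIGIBLE
    pop = select_population(ancestry)
    freq = _check_fraction(f"gnomAD {pop} frequency", gnomad_freq.get(pop))
    vaf = _check_fraction("VAF", vaf)
    tm = _check_fraction("TOPMED frequency", topmed_freq)
    if cosmic_id_count < 0:
        raise ValueError(f"COSMIC identifier count must be >= 0, got {cosmic_id_count}")

    if freq <= RARE_FREQ and vaf >= MIN_VAF:
        retained, reason = True, RARE_VAF
    elif freq <= RARE_FREQ and cosmic_id_count >= MIN_COSMIC:
        retained, reason = True, RARE_COSMIC
    elif RARE_FREQ < freq <= COMMON_FREQ_CAP and cosmic_id_count >= MIN_COSMIC:
        retained, reason = True, COMMON_COSMIC
    else:
        retained, reason = False, NOT_RETAINED
    # the TOPMED exclusion overrides any retention decision
    if retained and tm > TOPMED_MAX:
        return False, TOPMED_EXCLUDED
    return retained, reason


def classify_table(
    variants: pd.DataFrame,
    ancestry_by_sample: Mapping[str, str],
) -> pd.DataFrame:
    """Apply the decision tree to a somatic variant table.

    ``variants`` needs columns ``sample_id``, ``consequence``,
    ``exonic``, ``vaf``, ``gnomad_afr``, ``gnomad_sas``, ``gnomad_nfe``,
    ``cosmic_count`` and ``topmed_freq``.  The gnomAD column consulted
    per row follows the sample's ancestry.  Returns a copy with
    ``retained`` and ``branch`` columns appended.
    """
    required = {
        "sample_id", "consequence", "exonic", "vaf",
        "gnomad_afr", "gnomad_sas", "gnomad_nfe", "cosmic_count", "topmed_freq",
    }
    missing = required - set(variants.columns)
    if missing:
        raise ValueError(f"variant table missing columns: {sorted(missing)}")

    anc = variants["sample_id"].map(dict(ancestry_by_sample))
    if anc.isna().any():
        orphans = variants.loc[anc.isna(), "sample_id"].unique()
        raise ValueError(f"samples without an ancestry label: {list(orphans)[:5]}")
    unsupported = set(anc.unique()) - set(POPULATION_BY_ANCESTRY)
    if unsupported:
        raise ValueError(
            f"ancestry labels without a gnomAD population: {sorted(unsupported)}"
        )
    pop_col = anc.map(lambda a: f"gnomad_{POPULATION_BY_ANCESTRY[a].lower()}")

    freq = np.empty(len(variants))
    for col in pop_col.unique():
        mask = (pop_col == col).to_numpy()
        freq[mask] = variants.loc[mask, col].to_numpy(dtype=float)
    freq = np.nan_to_num(freq, nan=0.0)
    if ((freq < 0) | (freq > 1)).any():
        raise ValueError("gnomAD frequencies must be fractions in [0, 1]")
    vaf = variants["vaf"].to_numpy(dtype=float)
    if np.isnan(vaf).any() or ((vaf < 0) | (vaf > 1)).any():
        raise ValueError("VAF must be a fraction in [0, 1]")
    tm = np.nan_to_num(variants["topmed_freq"].to_numpy(dtype=float), nan=0.0)
    if ((tm < 0) | (tm > 1)).any():
        raise ValueError("TOPMED frequencies must be fractions in [0, 1]")
    cosmic = variants["cosmic_count"].to_numpy()
    if (cosmic < 0).any():
        raise ValueError("COSMIC identifier counts must be >= 0")

    eligible = (
        (variants["consequence"] == "non-synonymous").to_numpy()
        & variants["exonic"].astype(bool).to_numpy()
    )
    rare = freq <= RARE_FREQ
    cosmic_ok = cosmic >= MIN_COSMIC
    rule_i = rare & (vaf >= MIN_VAF)
    rule_i2 = rare & ~rule_i & cosmic_ok
    rule_ii = (freq > RARE_FREQ) & (freq <= COMMON_FREQ_CAP) & cosmic_ok
    would_retain = eligible & (rule_i | rule_i2 | rule_ii)
    topmed_bad = tm > TOPMED_MAX
    retained = would_retain & ~topmed_bad

    branch = np.full(len(variants), NOT_RETAINED, dtype=object)
    branch[eligible & rule_ii] = COMMON_COSMIC
    branch[eligible & rule_i2] = RARE_COSMIC
    branch[eligible & rule_i] = RARE_VAF
    branch[would_retain & topmed_bad] = TOPMED_EXCLUDED
    branch[~eligible] = NOT_ELIGIBLE

    out = variants.copy()
    out["retained"] = retained
    out["branch"] = branch
    return out


def compute_tmb(retained_count: int, exome_mb: float = DEFAULT_EXOME_MB) -> float:
    """Mutations per Mb: retained count over the exome size in Mb."""
    if retained_count < 0:
        raise ValueError(f"retained count must be >= 0, got {retained_count}")
    if exome_mb <= 0:
        raise ValueError(f"exome size must be > 0 Mb, got {exome_mb}")
    return retained_count / exome_mb


def tmb_per_sample(
    classified: pd.DataFrame,
    ancestry_by_sample: Mapping[str, str],
    exome_mb: float = DEFAULT_EXOME_MB,
    samples: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Per-sample retained counts and TMB from a classified variant table.

    ``samples`` lets callers include samples with zero retained
    variants (they otherwise drop out of the grouped count).
    """
    counts = (
        classified.loc[classified["retained"], "sample_id"].value_counts().to_dict()
    )
    if samples is None:
        samples = sorted(set(classified["sample_id"]))
    rows = []
    for s in samples:
        c = int(counts.get(s, 0))
        rows.append(
            {
                "sample_id": s,
                "ancestry": ancestry_by_sample[s],
                "retained_count": c,
                "tmb": compute_tmb(c, exome_mb),
            }
        )
    return pd.DataFrame(rows, columns=["sample_id", "ancestry", "retained_count", "tmb"])


def tmb_by_group(
    values: pd.Series,
    groups: pd.Series,
) -> pd.DataFrame:
    """Group medians plus two-sided Wilcoxon rank-sum tests vs the largest group.

    ``values`` are per-sample TMB (or any per-sample statistic);
    ``groups`` is an aligned grouping factor (e.g. ER status or
    ancestry).  The reference group for the pairwise tests is the
    largest one.  The rank-sum p uses the exact distribution for small
    untied samples and the tie-corrected normal approximation
    otherwise.
    """
    values = pd.Series(values).reset_index(drop=True)
    groups = pd.Series(groups).reset_index(drop=True)
    keep = values.notna() & groups.notna()
    values, groups = values[keep], groups[keep]
    sizes = groups.value_counts()
    if len(sizes) < 2:
        raise ValueError("tmb_by_group needs at least two groups")
    if (sizes == 0).any():
        raise ValueError("empty group in tmb_by_group")
    ref = sizes.index[0]
    ref_vals = values[groups == ref].to_numpy()
    rows = []
    for g, n in sizes.items():
        gv = values[groups == g].to_numpy()
        row = {"group": g, "n": int(n), "median": float(np.median(gv))}
        if g != ref:
            row["p_vs_ref"] = rank_sum_p(gv, ref_vals)
        else:
            row["p_vs_ref"] = np.nan
        rows.append(row)
    out = pd.DataFrame(rows)
    out.attrs["reference"] = ref
    return out


def rank_sum_p(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided Wilcoxon rank-sum p-value.

    Exact null distribution when both samples are small (n <= 50) and
    untied; otherwise the normal approximation with tie correction
    (no continuity correction, so equal samples give p = 1 exactly).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("rank-sum test needs non-empty samples")
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < len(pooled)
    if max(len(x), len(y)) <= 50 and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(
        x, y, alternative="two-sided", method=method, use_continuity=False
    )
    return float(res.pvalue)
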