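"""Seeded synthetic cohorts with the structure the analyses assume.

The generator emulates a harmonised breast-cancer analytic cohort at
the called-variant level (no reads, no alignment): a clinical table
with ancestry proportions and covariates, a somatic variant table with
gnomAD/COSMIC/TOPMED/VAF annotation columns, a germline call table
with ClinVar classes and star ratings, and the susceptibility gene
panel.  Every injected effect — per-group age shifts, receptor-status
odds ratios, TMB multipliers, per-gene somatic frequencies and
germline carrier rates — is recorded in a truth ledger so downstream
fits can be checked for parameter recovery.

All randomness flows from the single config seed through named
sub-streams, so the clinical table is bit-identical whether or not the
variant tables are generated.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd
from scipy import optimize, stats

from bcancestry import io as bcio
from bcancestry.ancestry import assign_labels
from bcancestry.config import GROUPS, SUPERPOPS, CohortConfig, ConfigError

# real susceptibility genes seed the panel; filler entries pad it to size
_CORE_PANEL = [
    "BRCA1", "BRCA2", "PALB2", "ATM", "CHEK2", "TP53", "PTEN", "STK11",
    "CDH1", "RAD51C", "RAD51D", "BARD1", "BRIP1", "MLH1", "MSH2", "MSH6",
    "PMS2", "EPCAM", "NBN", "NF1", "MUTYH", "APC", "CDKN2A", "SMAD4",
    "BMPR1A", "VHL", "RET", "RB1", "FANCA", "FANCC", "FANCM", "XRCC2",
    "ERCC2", "ERCC3", "XPA", "XPC", "POLD1", "POLE", "AXIN2", "HOXB13",
]

_SRE_CATEGORIES = ("White", "Black or Black British", "Asian or Asian British", "Mixed")

_BASES = np.array(["A", "C", "G", "T"])


@dataclass
class SyntheticBundle:
    """One generated cohort: tables, panel and the injected-effect ledger."""

    clinical: pd.DataFrame
    somatic: pd.DataFrame
    germline: pd.DataFrame
    panel: List[str]
    truth: Dict[str, object]

    def participants(self) -> List[str]:
        return list(self.clinical["participant_id"])


# ---------------------------------------------------------------------------
# helpers

def _streams(seed: int) -> Dict[str, np.random.Generator]:
    names = ["proportions", "ages", "clinical", "sre", "somatic", "germline", "missing"]
    children = np.random.SeedSequence(seed).spawn(len(names))
    return {n: np.random.default_rng(c) for n, c in zip(names, children)}


def _dirichlet_alpha_main(threshold: float, assign_fraction: float, alpha_rest: float = 2.0) -> float:
    """Main-component Dirichlet concentration giving
    P(main proportion >= threshold) = assign_fraction.

    The marginal of the main component is Beta(a, alpha_rest).
    """
    def gap(a: float) -> float:
        return stats.beta.sf(threshold, a, alpha_rest) - assign_fraction

    if assign_fraction >= 1.0:
        return 500.0
    return float(optimize.brentq(gap, 0.1, 5000.0))


def _odds_prob(base_prob: float, odds_ratio: float) -> float:
    odds = base_prob / (1.0 - base_prob) * odds_ratio
    return odds / (1.0 + odds)


def _truncnorm(rng: np.random.Generator, mean: float, sd: float, lo: float, hi: float, size: int) -> np.ndarray:
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def retention_probability(config: CohortConfig) -> float:
    """Expected fraction of background somatic variants the retention
    filter keeps, under the configured annotation model.

    Used to scale the pre-filter variant intensity so the post-filter
    mean hits the configured TMB level.
    """
    am = config.annotation_model
    cp = am["consequence_probs"]
    p_elig = cp.get("non-synonymous", 0.0) * am["exonic_frac"]
    lo, hi = am["gnomad_lo"], am["gnomad_hi"]
    span = np.log(hi / lo) if hi > lo else None
    rare_cut, common_cut = 0.001, 0.10

    def logfrac(a: float, b: float) -> float:
        a, b = max(a, lo), min(b, hi)
        if span is None or b <= a:
            return 0.0
        return float(np.log(b / a) / span)

    present = 1.0 - am["gnomad_absent_frac"]
    p_rare = am["gnomad_absent_frac"] + present * logfrac(lo, rare_cut)
    p_mid = present * logfrac(rare_cut, common_cut)
    p_cosmic2 = (1.0 - am["cosmic_zero_frac"]) * (1.0 - np.exp(-am["cosmic_extra_mean"]))
    p_vaf = float(stats.beta.sf(0.03, am["vaf_beta_a"], am["vaf_beta_b"]))
    p_pass = p_rare * (p_vaf + (1.0 - p_vaf) * p_cosmic2) + p_mid * p_cosmic2
    return p_elig * p_pass * (1.0 - am["topmed_common_frac"])


# ---------------------------------------------------------------------------
# clinical table

def generate_clinical(config: CohortConfig, rngs: Optional[Dict[str, np.random.Generator]] = None) -> Tuple[pd.DataFrame, Dict[str, object]]:
    """Clinical table plus its slice of the truth ledger.

    Exposed separately from :func:`generate_cohort` because the
    regression battery only needs this table; the variant tables are
    generated on top without disturbing the clinical sub-streams.

    The ``germline_brca`` flag here is drawn from the configured
    clinical carrier rate; :func:`generate_cohort` replaces it with the
    flag implied by the generated germline calls so the two tables
    cohere.
    """
    config.validate()
    if rngs is None:
        rngs = _streams(config.seed)
    em = config.effect_model
    am = config.age_model
    order = [g for g in GROUPS if config.n_per_group.get(g, 0) >= 0]
    rows_n = sum(config.n_per_group.get(g, 0) for g in order)

    ids, intended = [], []
    for g in order:
        n = config.n_per_group.get(g, 0)
        ids += [f"P{len(ids) + i + 1:05d}" for i in range(n)]
        intended += [g] * n
    intended = np.array(intended, dtype=object)

    # ancestry proportions
    rng = rngs["proportions"]
    props = np.zeros((rows_n, len(SUPERPOPS)))
    pop_index = {p: i for i, p in enumerate(SUPERPOPS)}
    alpha_rest = 0.5
    a_main = _dirichlet_alpha_main(config.ancestry_threshold, config.assign_fraction,
                                   alpha_rest * (len(SUPERPOPS) - 1))
    for g in order:
        mask = intended == g
        n = int(mask.sum())
        if n == 0:
            continue
        if g == "Admix":
            alpha = np.full(len(SUPERPOPS), 2.0)
        else:
            alpha = np.full(len(SUPERPOPS), alpha_rest)
            alpha[pop_index[g]] = a_main
        props[mask] = rng.dirichlet(alpha, size=n)

    clinical = pd.DataFrame({"participant_id": ids, "intended_group": intended})
    for p in SUPERPOPS:
        clinical[f"prop_{p}"] = props[:, pop_index[p]]
    clinical["gAncestry"] = assign_labels(clinical, threshold=config.ancestry_threshold).to_numpy()

    # self-reported ethnicity
    rng = rngs["sre"]
    cat_by_group = config.sre_model["category_by_group"]
    sre = np.array([cat_by_group[g] for g in intended], dtype=object)
    flip = rng.random(rows_n) < config.sre_model["discordant_frac"]
    if flip.any():
        others = [
            rng.choice([c for c in _SRE_CATEGORIES if c != s]) for s in sre[flip]
        ]
        sre[flip] = others
    missing = rng.random(rows_n) < config.sre_model["missing_frac"]
    sre = pd.Series(sre, dtype=object)
    sre[missing] = np.nan
    clinical["sre"] = sre.to_numpy()

    # ages
    rng = rngs["ages"]
    age = np.zeros(rows_n)
    death = np.full(rows_n, np.nan)
    shift = em["age_shift_years"]
    dshift = em["death_shift_years"]
    for g in order:
        mask = intended == g
        n = int(mask.sum())
        if n == 0:
            continue
        mean = am["base_mean"] + shift.get(g, 0.0)
        age[mask] = _truncnorm(rng, mean, am["sd"][g], am["min_age"], am["max_age"], n)
        dmean = am["death_base_mean"] + dshift.get(g, 0.0)
        d = _truncnorm(rng, dmean, am["death_sd"], am["min_age"], am["max_age"], n)
        observed = rng.random(n) < am["death_fraction"]
        d[~observed] = np.nan
        death[mask] = d
    death = np.where(np.isnan(death), np.nan, np.maximum(death, age + 0.1))
    clinical["age_at_diagnosis"] = age
    clinical["age_at_death"] = death

    # categorical covariates
    rng = rngs["clinical"]
    for rec in ("ER", "PR", "HER2"):
        base = em["receptor_neg_base"][rec]
        ors = em["receptor_neg_or"][rec]
        pneg = np.array([_odds_prob(base, ors.get(g, 1.0)) if g != "EUR" else base for g in intended])
        clinical[rec] = np.where(rng.random(rows_n) < pneg, "negative", "positive")
    p3 = np.array([_odds_prob(em["grade_high_base"], em["grade_high_or"].get(g, 1.0))
                   if g != "EUR" else em["grade_high_base"] for g in intended])
    high = rng.random(rows_n) < p3
    low_split = rng.random(rows_n) < 0.35
    clinical["grade"] = np.where(high, 3, np.where(low_split, 1, 2))
    ps = np.array([_odds_prob(em["stage_high_base"], em["stage_high_or"].get(g, 1.0))
                   if g != "EUR" else em["stage_high_base"] for g in intended])
    s_high = rng.random(rows_n) < ps
    s4 = rng.random(rows_n) < 0.3
    s2 = rng.random(rows_n) < 0.55
    clinical["stage"] = np.where(s_high, np.where(s4, 4, 3), np.where(s2, 2, 1))
    pl = np.array([_odds_prob(em["lymph_involved_base"], em["lymph_involved_or"].get(g, 1.0))
                   if g != "EUR" else em["lymph_involved_base"] for g in intended])
    clinical["lymph_node"] = np.where(rng.random(rows_n) < pl, "involved", "not")
    imd = np.zeros(rows_n, dtype=int)
    for g in order:
        mask = intended == g
        n = int(mask.sum())
        if n:
            imd[mask] = rng.choice(np.arange(1, 6), size=n, p=em["imd_probs"][g])
    clinical["IMD_quintile"] = imd
    pbrca = np.array([em["brca_clinical_rate"][g] for g in intended])
    clinical["germline_brca"] = (rng.random(rows_n) < pbrca).astype(int)

    # injectable missingness
    rng = rngs["missing"]
    for col, frac in config.missingness.items():
        if col not in clinical.columns:
            raise ConfigError(f"missingness[{col}]: no such clinical column")
        mask = rng.random(rows_n) < frac
        clinical.loc[mask, col] = np.nan

    truth = {
        "seed": config.seed,
        "n_per_group": dict(config.n_per_group),
        "age_shift_years": dict(shift),
        "death_shift_years": dict(dshift),
        "receptor_neg_base": dict(em["receptor_neg_base"]),
        "receptor_neg_or": {k: dict(v) for k, v in em["receptor_neg_or"].items()},
        "grade_high_or": dict(em["grade_high_or"]),
        "stage_high_or": dict(em["stage_high_or"]),
        "lymph_involved_or": dict(em["lymph_involved_or"]),
        "imd_probs": {k: list(v) for k, v in em["imd_probs"].items()},
        "assign_fraction": config.assign_fraction,
    }
    return clinical, truth


# ---------------------------------------------------------------------------
# annotation resources

def generate_annotation_resources(
    config: CohortConfig,
    n_variants: int,
    rng: Optional[np.random.Generator] = None,
) -> pd.DataFrame:
    """Annotation columns for ``n_variants`` somatic variants.

    Emulates lookups against gnomAD (per-population frequencies with
    correlated jitter), COSMIC (identifier counts) and TOPMED, plus a
    VAF and consequence/exonic flags.
    """
    config.validate()
    am = config.annotation_model
    if rng is None:
        rng = _streams(config.seed)["somatic"]
    n = int(n_variants)
    cp = am["consequence_probs"]
    cons = rng.choice(list(cp.keys()), size=n, p=list(cp.values()))
    exonic = rng.random(n) < am["exonic_frac"]
    vaf = rng.beta(am["vaf_beta_a"], am["vaf_beta_b"], size=n)
    absent = rng.random(n) < am["gnomad_absent_frac"]
    lo, hi = am["gnomad_lo"], am["gnomad_hi"]
    base = np.exp(rng.uniform(np.log(lo), np.log(hi), size=n))
    base[absent] = 0.0
    freqs = {}
    for pop in ("afr", "sas", "nfe"):
        jitter = np.exp(rng.normal(0.0, am["pop_jitter_sd"], size=n))
        freqs[pop] = np.clip(base * jitter, 0.0, 1.0)
        freqs[pop][absent] = 0.0
    cosmic = np.where(
        rng.random(n) < am["cosmic_zero_frac"],
        0,
        1 + rng.poisson(am["cosmic_extra_mean"], size=n),
    )
    tm_common = rng.random(n) < am["topmed_common_frac"]
    topmed = np.where(
        tm_common,
        rng.uniform(am["topmed_common_lo"], am["topmed_common_hi"], size=n),
        0.0,
    )
    return pd.DataFrame({
        "consequence": cons,
        "exonic": exonic,
        "vaf": vaf,
        "gnomad_afr": freqs["afr"],
        "gnomad_sas": freqs["sas"],
        "gnomad_nfe": freqs["nfe"],
        "cosmic_count": cosmic.astype(int),
        "topmed_freq": topmed,
    })


# ---------------------------------------------------------------------------
# variant tables

def _gene_locus(rng: np.random.Generator) -> Tuple[str, int, str, str]:
    chrom = f"chr{rng.integers(1, 23)}"
    pos = int(rng.integers(10_000, 50_000_000))
    ref, alt = rng.choice(_BASES, size=2, replace=False)
    return chrom, pos, str(ref), str(alt)


def _generate_somatic(config: CohortConfig, clinical: pd.DataFrame,
                      rng: np.random.Generator) -> Tuple[pd.DataFrame, Dict[str, object]]:
    em = config.effect_model
    retention = retention_probability(config)
    groups = clinical["intended_group"].to_numpy()
    n_part = len(clinical)
    ids = clinical["participant_id"].to_numpy()

    driver_freq = em["somatic_gene_freq"]
    bg_genes = [f"SOMBG_{i:03d}" for i in range(1, em["somatic_background_genes"] + 1)]
    gene_loci = {g: _gene_locus(rng) for g in list(driver_freq) + bg_genes}

    rows: List[dict] = []
    # recurrent driver variants: COSMIC-heavy, rare in gnomAD, clonal VAF
    for gene, freqs in driver_freq.items():
        p = np.array([freqs.get(g, freqs.get("EUR", 0.0)) for g in groups])
        hit = rng.random(n_part) < p
        chrom, pos, ref, alt = gene_loci[gene]
        vafs = rng.beta(5, 5, size=int(hit.sum()))
        for pid, v in zip(ids[hit], vafs):
            rows.append({
                "sample_id": pid, "chrom": chrom, "pos": pos, "ref": ref, "alt": alt,
                "gene": gene, "consequence": "non-synonymous", "exonic": True,
                "vaf": float(v), "gnomad_afr": 0.0, "gnomad_sas": 0.0, "gnomad_nfe": 0.0,
                "cosmic_count": 5, "topmed_freq": 0.0,
            })
    driver_df = pd.DataFrame(rows)

    # background passengers drive the TMB signal
    mult = em["tmb_multiplier"]
    mu = np.array([
        em["tmb_mean_retained"] * (mult.get(g, 1.0) if g != "EUR" else 1.0) / retention
        for g in groups
    ])
    alpha = em["tmb_dispersion"]
    if alpha > 0:
        lam = rng.gamma(shape=1.0 / alpha, scale=alpha * mu)
    else:
        lam = mu
    n_bg = rng.poisson(lam)
    total_bg = int(n_bg.sum())
    ann = generate_annotation_resources(config, total_bg, rng=rng)
    # Zipf-weighted gene usage: a few recurrently hit passenger genes, a
    # long tail below the 2% presence boundary
    ranks = np.arange(1, len(bg_genes) + 1, dtype=float)
    gene_p = (1.0 / ranks) / (1.0 / ranks).sum()
    bg = pd.DataFrame({
        "sample_id": np.repeat(ids, n_bg),
        "gene": rng.choice(bg_genes, size=total_bg, p=gene_p),
    })
    bg["chrom"] = [gene_loci[g][0] for g in bg["gene"]]
    # passengers get unique positions: variant-level recurrence stays rare
    bg["pos"] = rng.integers(10_000, 50_000_000, size=total_bg)
    refalt = rng.integers(0, 4, size=(total_bg, 2))
    refalt[:, 1] = (refalt[:, 0] + 1 + refalt[:, 1] % 3) % 4
    bg["ref"] = _BASES[refalt[:, 0]]
    bg["alt"] = _BASES[refalt[:, 1]]
    bg = pd.concat([bg.reset_index(drop=True), ann.reset_index(drop=True)], axis=1)

    somatic = pd.concat([driver_df, bg], ignore_index=True) if len(driver_df) else bg
    somatic["variant_id"] = (
        somatic["chrom"].astype(str) + ":" + somatic["pos"].astype(str)
        + ":" + somatic["ref"] + ":" + somatic["alt"]
    )
    cols = ["sample_id", "variant_id", "chrom", "pos", "ref", "alt", "gene",
            "consequence", "exonic", "vaf", "gnomad_afr", "gnomad_sas", "gnomad_nfe",
            "cosmic_count", "topmed_freq"]
    somatic = somatic[cols].sort_values(["sample_id", "chrom", "pos"]).reset_index(drop=True)
    truth = {
        "somatic_gene_freq": {k: dict(v) for k, v in driver_freq.items()},
        "tmb_multiplier": dict(mult),
        "tmb_mean_retained": em["tmb_mean_retained"],
        "tmb_dispersion": alpha,
        "retention_probability": retention,
    }
    return somatic, truth


def _generate_germline(config: CohortConfig, clinical: pd.DataFrame,
                       panel: List[str], rng: np.random.Generator) -> Tuple[pd.DataFrame, Dict[str, object]]:
    em = config.effect_model
    groups = clinical["intended_group"].to_numpy()
    ids = clinical["participant_id"].to_numpy()
    n_part = len(clinical)
    carrier_rates = em["germline_carrier_rates"]
    filler = [g for g in panel if g not in carrier_rates]

    rows: List[dict] = []

    def qualifying(pid: str, gene: str) -> dict:
        return {
            "participant_id": pid, "gene": gene, "canonical": True,
            "clinvar_class": "pathogenic" if rng.random() < 0.6 else "likely_pathogenic",
            "clinvar_stars": int(rng.choice([2, 3, 4], p=[0.5, 0.35, 0.15])),
            "in_panel": True,
        }

    for gene, rates in carrier_rates.items():
        p = np.array([rates.get(g, rates.get("EUR", 0.0)) for g in groups])
        hit = rng.random(n_part) < p
        rows += [qualifying(pid, gene) for pid in ids[hit]]

    extra_mean = em["germline_extra_pathogenic_mean"]
    n_extra = rng.poisson([extra_mean[g] for g in groups])
    for pid, k in zip(ids, n_extra):
        for gene in rng.choice(filler, size=k):
            rows.append(qualifying(pid, str(gene)))

    vus_mean = em["germline_vus_mean"]
    n_vus = rng.poisson([vus_mean[g] for g in groups])
    for pid, k in zip(ids, n_vus):
        for gene in rng.choice(panel, size=k):
            rows.append({
                "participant_id": pid, "gene": str(gene), "canonical": True,
                "clinvar_class": "uncertain",
                "clinvar_stars": int(rng.integers(0, 5)),
                "in_panel": True,
            })

    # noise the classifier must reject: benign calls, low-star pathogenic,
    # non-canonical transcripts and off-panel genes
    n_noise = rng.poisson(4.0, size=n_part)
    noise_classes = np.array(["benign", "likely_benign", "other", "pathogenic"])
    for pid, k in zip(ids, n_noise):
        for _ in range(int(k)):
            kind = rng.random()
            if kind < 0.5:
                rows.append({
                    "participant_id": pid, "gene": str(rng.choice(panel)),
                    "canonical": True,
                    "clinvar_class": str(rng.choice(noise_classes[:3])),
                    "clinvar_stars": int(rng.integers(0, 5)), "in_panel": True,
                })
            elif kind < 0.75:
                rows.append({  # pathogenic but below the star threshold
                    "participant_id": pid, "gene": str(rng.choice(panel)),
                    "canonical": True, "clinvar_class": "pathogenic",
                    "clinvar_stars": int(rng.integers(0, 2)), "in_panel": True,
                })
            elif kind < 0.9:
                rows.append({  # non-canonical transcript
                    "participant_id": pid, "gene": str(rng.choice(panel)),
                    "canonical": False, "clinvar_class": "pathogenic",
                    "clinvar_stars": 3, "in_panel": True,
                })
            else:
                rows.append({  # off-panel gene
                    "participant_id": pid, "gene": f"OFFPANEL_{int(rng.integers(1, 50)):03d}",
                    "canonical": True, "clinvar_class": "pathogenic",
                    "clinvar_stars": 3, "in_panel": False,
                })

    germline = pd.DataFrame(
        rows, columns=["participant_id", "gene", "canonical", "clinvar_class",
                       "clinvar_stars", "in_panel"],
    ).sort_values(["participant_id", "gene"]).reset_index(drop=True)
    truth = {
        "germline_carrier_rates": {k: dict(v) for k, v in carrier_rates.items()},
        "germline_extra_pathogenic_mean": dict(extra_mean),
        "germline_vus_mean": dict(vus_mean),
    }
    return germline, truth


def generate_retained_counts(
    config: CohortConfig, groups: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Post-filter mutation counts drawn directly from the configured model.

    Binomial thinning of a gamma-Poisson mixture stays gamma-Poisson
    with a scaled mean, so drawing negative-binomial counts at the
    configured retained-mean (per-group multiplier applied) is
    distributionally identical to generating the full variant table and
    running the retention filter — minus the small driver-gene
    contribution.  Used where only the TMB outcome is needed.
    """
    em = config.effect_model
    mult = em["tmb_multiplier"]
    mu = np.array([
        em["tmb_mean_retained"] * (mult.get(g, 1.0) if g != "EUR" else 1.0)
        for g in groups
    ])
    alpha = em["tmb_dispersion"]
    lam = rng.gamma(shape=1.0 / alpha, scale=alpha * mu) if alpha > 0 else mu
    return rng.poisson(lam)


# ---------------------------------------------------------------------------
# top level

def make_panel(config: CohortConfig) -> List[str]:
    """Gene panel: core susceptibility genes padded to the configured size."""
    filler = [f"PANEL_{i:03d}" for i in range(1, max(0, config.panel_size - len(_CORE_PANEL)) + 1)]
    return (_CORE_PANEL + filler)[: config.panel_size]


def generate_cohort(config: CohortConfig) -> SyntheticBundle:
    """Generate a full cohort bundle from a validated config.

    Deterministic given the seed; group sizes are exactly as
    configured; every somatic and germline row references a clinical
    participant.
    """
    config.validate()
    rngs = _streams(config.seed)
    clinical, truth = generate_clinical(config, rngs)
    panel = make_panel(config)
    if len(clinical):
        somatic, struth = _generate_somatic(config, clinical, rngs["somatic"])
        germline, gtruth = _generate_germline(config, clinical, panel, rngs["germline"])
    else:
        somatic = pd.DataFrame(columns=["sample_id", "variant_id", "chrom", "pos", "ref",
                                        "alt", "gene", "consequence", "exonic", "vaf",
                                        "gnomad_afr", "gnomad_sas", "gnomad_nfe",
                                        "cosmic_count", "topmed_freq"])
        germline = pd.DataFrame(columns=["participant_id", "gene", "canonical",
                                         "clinvar_class", "clinvar_stars", "in_panel"])
        struth, gtruth = {}, {}
    truth.update(struth)
    truth.update(gtruth)

    # clinical BRCA flag coheres with the generated germline calls
    if len(germline):
        from bcancestry.germline import PATHOGENIC, classify_calls
        classified = classify_calls(germline)
        carriers = set(
            classified.loc[
                (classified["fate"] == PATHOGENIC)
                & classified["gene"].isin(["BRCA1", "BRCA2"]),
                "participant_id",
            ]
        )
        clinical["germline_brca"] = clinical["participant_id"].isin(carriers).astype(int)
    return SyntheticBundle(clinical=clinical, somatic=somatic, germline=germline,
                           panel=panel, truth=truth)


def write_fixtures(bundle: SyntheticBundle, directory: str) -> Dict[str, str]:
    """Write a bundle as TSV / VCF / plain-text / JSON fixture files.

    Returns the mapping of logical names to paths.  Tables round-trip
    losslessly through the readers in :mod:`bcancestry.io`.
    """
    os.makedirs(directory, exist_ok=True)
    paths = {
        "clinical": os.path.join(directory, "clinical.tsv"),
        "somatic_tsv": os.path.join(directory, "somatic.tsv"),
        "somatic_vcf": os.path.join(directory, "somatic.vcf"),
        "germline": os.path.join(directory, "germline.tsv"),
        "panel": os.path.join(directory, "panel.txt"),
        "truth": os.path.join(directory, "truth.json"),
    }
    bcio.write_clinical(bundle.clinical, paths["clinical"])
    bcio.write_somatic_tsv(bundle.somatic, paths["somatic_tsv"])
    bcio.write_somatic_vcf(bundle.somatic, paths["somatic_vcf"])
    bcio.write_germline(bundle.germline, paths["germline"])
    bcio.write_panel(bundle.panel, paths["panel"])
    with open(paths["truth"], "w") as fh:
        json.dump(bundle.truth, fh, indent=1, sort_keys=True)
    return paths
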