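"""Cohort configuration for the synthetic-cohort generator.

The configuration pins down the *study conditions*: group sizes,
age-at-diagnosis distributions, the clinical effect sizes injected for
each non-reference ancestry group, per-gene somatic mutation
frequencies, germline carrier rates, and the distributions of the
annotation columns (gnomAD / COSMIC / TOPMED / VAF) that the somatic
retention filter consumes.  Defaults mirror the analytic cohort the
analyses were designed around: 2,343 EUR, 138 AFR, 123 SAS and 177
admixed participants, AFR diagnosed 5.28 years earlier than EUR, an
ER-negativity odds ratio of 2.06 in AFR, a multiplicative TMB effect of
0.845 in SAS, and so on.
"""

from __future__ import annotations

import copy
import dataclasses
from dataclasses import dataclass, field
from typing import Any, Dict, List, Mapping, Optional

import yaml

GROUPS = ("EUR", "AFR", "SAS", "Admix")
SUPERPOPS = ("AFR", "EUR", "EAS", "SAS", "AMR")


class ConfigError(ValueError):
    """Raised when a configuration field violates its invariants."""


def _default_age_model() -> Dict[str, Any]:
    # Means/SDs chosen so the 20th-80th percentile bands of the groups
    # reproduce realistic screening windows (EUR ~50-75, AFR ~47-69,
    # SAS ~45-68 after the injected shifts below).
    return {
        "base_mean": 62.5,
        "sd": {"EUR": 14.9, "AFR": 13.1, "SAS": 13.7, "Admix": 14.0},
        "min_age": 18.0,
        "max_age": 100.0,
        "death_base_mean": 72.0,
        "death_sd": 13.0,
        "death_fraction": 0.30,
    }


def _default_effect_model() -> Dict[str, Any]:
    return {
        # years earlier (negative) relative to EUR
        "age_shift_years": {"AFR": -5.28, "SAS": -6.91, "Admix": -2.0},
        "death_shift_years": {"AFR": -8.94, "SAS": -13.20, "Admix": -3.0},
        # probability of the *negative* receptor state in EUR
        "receptor_neg_base": {"ER": 0.15, "PR": 0.25, "HER2": 0.85},
        # odds ratios for receptor negativity vs EUR
        "receptor_neg_or": {
            "ER": {"AFR": 2.06, "SAS": 1.20, "Admix": 1.10},
            "PR": {"AFR": 2.07, "SAS": 1.20, "Admix": 1.10},
            "HER2": {"AFR": 1.00, "SAS": 1.00, "Admix": 1.00},
        },
        "grade_high_base": 0.45,
        "grade_high_or": {"AFR": 1.88, "SAS": 1.00, "Admix": 1.10},
        "stage_high_base": 0.20,
        "stage_high_or": {"AFR": 1.20, "SAS": 1.10, "Admix": 1.05},
        "lymph_involved_base": 0.35,
        "lymph_involved_or": {"AFR": 1.30, "SAS": 1.30, "Admix": 1.10},
        # IMD quintile distributions; quintile 1 = most deprived
        "imd_probs": {
            "EUR": [0.15, 0.18, 0.20, 0.22, 0.25],
            "AFR": [0.35, 0.25, 0.18, 0.12, 0.10],
            "SAS": [0.32, 0.26, 0.18, 0.14, 0.10],
            "Admix": [0.25, 0.22, 0.20, 0.17, 0.16],
        },
        # germline BRCA1/2 carrier flag on the clinical table
        "brca_clinical_rate": {"EUR": 0.072, "AFR": 0.10, "SAS": 0.09, "Admix": 0.08},
        # mean retained (post-filter) somatic mutations per EUR sample;
        # ~53 retained over a 35.4 Mb exome gives a TMB near 1.5/Mb
        "tmb_mean_retained": 53.0,
        "tmb_dispersion": 0.4,  # NB2 alpha
        "tmb_multiplier": {"AFR": 0.95, "SAS": 0.845, "Admix": 1.0},
        # driver genes with per-group somatic mutation frequencies
        "somatic_gene_freq": {
            "TP53": {"EUR": 0.35, "AFR": 0.45, "SAS": 0.33, "Admix": 0.36},
            "PIK3CA": {"EUR": 0.32, "AFR": 0.22, "SAS": 0.30, "Admix": 0.31},
            "GATA3": {"EUR": 0.15, "AFR": 0.10, "SAS": 0.14, "Admix": 0.14},
            "KMT2C": {"EUR": 0.10, "AFR": 0.18, "SAS": 0.11, "Admix": 0.11},
            "MAP3K1": {"EUR": 0.09, "AFR": 0.05, "SAS": 0.08, "Admix": 0.08},
            "CDH1": {"EUR": 0.11, "AFR": 0.08, "SAS": 0.10, "Admix": 0.10},
        },
        # passenger gene universe; usage is Zipf-weighted so per-gene
        # mutation frequencies span the 2% presence boundary
        "somatic_background_genes": 600,
        # germline qualifying-call rates (pathogenic/likely pathogenic,
        # >=2 stars, canonical, in panel) per gene per group
        "germline_carrier_rates": {
            "BRCA1": {"EUR": 0.010, "AFR": 0.059, "SAS": 0.041, "Admix": 0.020},
            "BRCA2": {"EUR": 0.040, "AFR": 0.085, "SAS": 0.050, "Admix": 0.045},
            "PALB2": {"EUR": 0.020, "AFR": 0.056, "SAS": 0.025, "Admix": 0.022},
        },
        # extra qualifying pathogenic calls spread over the rest of the panel
        "germline_extra_pathogenic_mean": {"EUR": 5.2, "AFR": 6.3, "SAS": 5.8, "Admix": 5.5},
        "germline_vus_mean": {"EUR": 19.54, "AFR": 21.23, "SAS": 20.5, "Admix": 20.0},
    }


def _default_annotation_model() -> Dict[str, Any]:
    return {
        "gnomad_absent_frac": 0.55,
        "gnomad_lo": 1e-4,
        "gnomad_hi": 0.2,
        "pop_jitter_sd": 0.3,  # lognormal sigma between populations
        "cosmic_zero_frac": 0.5,
        "cosmic_extra_mean": 1.5,  # non-zero counts are 1 + Poisson(mean)
        "topmed_common_frac": 0.08,
        "topmed_common_lo": 0.002,
        "topmed_common_hi": 0.05,
        "vaf_beta_a": 2.0,
        "vaf_beta_b": 3.0,
        "vaf_min": 0.0,
        "consequence_probs": {"non-synonymous": 0.75, "synonymous": 0.20, "other": 0.05},
        "exonic_frac": 0.9,
        # mean total variants per sample before filtering; scaled per
        # group so the post-filter mean hits tmb_mean_retained
        "background_mu_total": None,  # derived when None
    }


def _default_sre_model() -> Dict[str, Any]:
    return {
        # intended ancestry -> self-reported category
        "category_by_group": {
            "EUR": "White",
            "AFR": "Black or Black British",
            "SAS": "Asian or Asian British",
            "Admix": "Mixed",
        },
        "discordant_frac": 0.02,
        "missing_frac": 0.05,
    }


@dataclass
class CohortConfig:
    """Parameters of one synthetic cohort draw.

    ``n_per_group`` counts participants per intended ancestry group;
    ``assign_fraction`` is the probability that a non-admixed
    participant's simulated ancestry proportions actually clear the
    0.8 assignment threshold (the remainder present as Admix).
    """

    n_per_group: Dict[str, int] = field(
        default_factory=lambda: {"EUR": 2343, "AFR": 138, "SAS": 123, "Admix": 177}
    )
    age_model: Dict[str, Any] = field(default_factory=_default_age_model)
    effect_model: Dict[str, Any] = field(default_factory=_default_effect_model)
    annotation_model: Dict[str, Any] = field(default_factory=_default_annotation_model)
    sre_model: Dict[str, Any] = field(default_factory=_default_sre_model)
    panel_size: int = 180
    assign_fraction: float = 0.95
    ancestry_threshold: float = 0.8
    missingness: Dict[str, float] = field(default_factory=dict)
    exome_mb: float = 35.4
    seed: int = 0

    def __post_init__(self) -> None:
        # partial model dicts merge over the defaults, so callers can
        # override a single entry without restating the whole block
        def deep_merge(dst: Dict[str, Any], src: Mapping[str, Any]) -> Dict[str, Any]:
            for k, v in src.items():
                if isinstance(dst.get(k), dict) and isinstance(v, Mapping):
                    deep_merge(dst[k], v)
                else:
                    dst[k] = copy.deepcopy(v)
            return dst

        for attr, factory in (
            ("age_model", _default_age_model),
            ("effect_model", _default_effect_model),
            ("annotation_model", _default_annotation_model),
            ("sre_model", _default_sre_model),
        ):
            setattr(self, attr, deep_merge(factory(), getattr(self, attr)))

    # ------------------------------------------------------------------
    def validate(self) -> "CohortConfig":
        for g, n in self.n_per_group.items():
            if g not in GROUPS:
                raise ConfigError(f"n_per_group: unknown group {g!r}")
            if not isinstance(n, (int,)) or n < 0:
                raise ConfigError(f"n_per_group[{g}]: count must be a non-negative integer, got {n!r}")
        for g, sd in self.age_model["sd"].items():
            if sd <= 0:
                raise ConfigError(f"age_model.sd[{g}]: s.d. must be > 0, got {sd}")
        if self.age_model["death_sd"] <= 0:
            raise ConfigError("age_model.death_sd: s.d. must be > 0")
        if not 0.0 <= self.age_model["death_fraction"] <= 1.0:
            raise ConfigError("age_model.death_fraction: must be in [0, 1]")
        em = self.effect_model
        for name in ("receptor_neg_base",):
            for k, v in em[name].items():
                if not 0.0 <= v <= 1.0:
                    raise ConfigError(f"effect_model.{name}[{k}]: probability outside [0, 1]")
        for rec, ors in em["receptor_neg_or"].items():
            for g, v in ors.items():
                if v <= 0:
                    raise ConfigError(f"effect_model.receptor_neg_or[{rec}][{g}]: odds ratio must be > 0")
        for name in ("grade_high_or", "stage_high_or", "lymph_involved_or", "tmb_multiplier"):
            for g, v in em[name].items():
                if v <= 0:
                    raise ConfigError(f"effect_model.{name}[{g}]: must be > 0")
        for name in ("grade_high_base", "stage_high_base", "lymph_involved_base"):
            if not 0.0 <= em[name] <= 1.0:
                raise ConfigError(f"effect_model.{name}: probability outside [0, 1]")
        for g, probs in em["imd_probs"].items():
            if len(probs) != 5 or any(p < 0 for p in probs) or abs(sum(probs) - 1.0) > 1e-8:
                raise ConfigError(f"effect_model.imd_probs[{g}]: must be 5 non-negative values summing to 1")
        for gene, freqs in em["somatic_gene_freq"].items():
            for g, f in freqs.items():
                if not 0.0 <= f <= 1.0:
                    raise ConfigError(f"effect_model.somatic_gene_freq[{gene}][{g}]: frequency outside [0, 1]")
        for gene, rates in em["germline_carrier_rates"].items():
            for g, r in rates.items():
                if not 0.0 <= r <= 1.0:
                    raise ConfigError(f"effect_model.germline_carrier_rates[{gene}][{g}]: rate outside [0, 1]")
        for g, r in em["brca_clinical_rate"].items():
            if not 0.0 <= r <= 1.0:
                raise ConfigError(f"effect_model.brca_clinical_rate[{g}]: rate outside [0, 1]")
        if em["tmb_mean_retained"] <= 0:
            raise ConfigError("effect_model.tmb_mean_retained: must be > 0")
        if em["tmb_dispersion"] < 0:
            raise ConfigError("effect_model.tmb_dispersion: must be >= 0")
        am = self.annotation_model
        for name in ("gnomad_absent_frac", "cosmic_zero_frac", "topmed_common_frac", "exonic_frac"):
            if not 0.0 <= am[name] <= 1.0:
                raise ConfigError(f"annotation_model.{name}: fraction outside [0, 1]")
        if not 0 <= am["gnomad_lo"] <= am["gnomad_hi"] <= 1:
            raise ConfigError("annotation_model.gnomad_lo/hi: need 0 <= lo <= hi <= 1")
        cp = am["consequence_probs"]
        if abs(sum(cp.values()) - 1.0) > 1e-8 or any(v < 0 for v in cp.values()):
            raise ConfigError("annotation_model.consequence_probs: must be non-negative and sum to 1")
        if not 0.0 < self.assign_fraction <= 1.0:
            raise ConfigError("assign_fraction: must be in (0, 1]")
        if not 0.5 < self.ancestry_threshold <= 1.0:
            raise ConfigError("ancestry_threshold: must be in (0.5, 1]")
        for col, frac in self.missingness.items():
            if not 0.0 <= frac <= 1.0:
                raise ConfigError(f"missingness[{col}]: fraction outside [0, 1]")
        if self.exome_mb <= 0:
            raise ConfigError("exome_mb: must be > 0")
        if self.panel_size < len(self.effect_model["germline_carrier_rates"]):
            raise ConfigError("panel_size: smaller than the number of genes with injected carrier rates")
        return self

    # ------------------------------------------------------------------
    def to_dict(self) -> Dict[str, Any]:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: Mapping[str, Any]) -> "CohortConfig":
        """Build a config from a (possibly partial) mapping.

        Nested mappings are merged over the defaults so a YAML file can
        override a single field without restating the whole block.
        """
        base = cls()
        out: Dict[str, Any] = base.to_dict()

        def merge(dst: Dict[str, Any], src: Mapping[str, Any], path: str, check: bool) -> None:
            for k, v in src.items():
                if check and k not in dst:
                    raise ConfigError(f"unknown configuration field {path}{k!r}")
                if isinstance(dst.get(k), dict) and isinstance(v, Mapping):
                    # deeper levels may introduce new keys (e.g. extra genes)
                    merge(dst[k], v, f"{path}{k}.", check=False)
                else:
                    dst[k] = copy.deepcopy(v)

        merge(out, data, "", check=True)
        return cls(**out).validate()


def load_config(path: str) -> CohortConfig:
    """Load a :class:`CohortConfig` from a YAML file."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, Mapping):
        raise ConfigError(f"config file {path} does not contain a mapping")
    return CohortConfig.from_dict(data)
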