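"""Synthetic-cohort generator: determinism, injected structure, fixtures."""

import numpy as np
import pandas as pd
import pytest

from bcancestry import io as bcio, tmb as tmb_mod
from bcancestry.config import CohortConfig, ConfigError
from bcancestry.synthetic import (
    SyntheticBundle,
    generate_annotation_resources,
    generate_clinical,
    generate_cohort,
    retention_probability,
    write_fixtures,
)


class TestConfig:
    @pytest.mark.parametrize(
        "patch,field",
        [
            ({"n_per_group": {"EUR": -1}}, "n_per_group"),
            ({"assign_fraction": 0.0}, "assign_fraction"),
            ({"exome_mb": 0.0}, "exome_mb"),
            ({"effect_model": {"tmb_multiplier": {"SAS": -2}}}, "tmb_multiplier"),
            ({"annotation_model": {"gnomad_absent_frac": 1.5}}, "gnomad_absent_frac"),
            ({"effect_model": {"imd_probs": {"EUR": [1, 0, 0, 0]}}}, "imd_probs"),
        ],
    )
    def test_invalid_configs_name_the_field(self, patch, field):
        with pytest.raises(ConfigError, match=field):
            CohortConfig.from_dict(patch)

    def test_unknown_top_level_field_rejected(self):
        with pytest.raises(ConfigError, match="banana"):
            CohortConfig.from_dict({"banana": 1})

    def test_partial_override_merges_over_defaults(self):
        cfg = CohortConfig.from_dict({"effect_model": {"age_shift_years": {"AFR": -3.0}}})
        assert cfg.effect_model["age_shift_years"]["AFR"] == -3.0
        assert cfg.effect_model["age_shift_years"]["SAS"] == -6.91

    def test_yaml_round_trip(self, tmp_path):
        import yaml

        from bcancestry.config import load_config

        path = tmp_path / "c.yaml"
        path.write_text(yaml.safe_dump({"seed": 42, "n_per_group": {"EUR": 10, "AFR": 5}}))
        cfg = load_config(path.as_posix())
        assert cfg.seed == 42 and cfg.n_per_group["AFR"] == 5


class TestDeterminism:
    def test_same_seed_identical_bundles(self):
        cfg = {"n_per_group": {"EUR": 60, "AFR": 25, "SAS": 25, "Admix": 10}, "seed": 1}
        b1 = generate_cohort(CohortConfig(**cfg))
        b2 = generate_cohort(CohortConfig(**cfg))
        pd.testing.assert_frame_equal(b1.clinical, b2.clinical)
        pd.testing.assert_frame_equal(b1.somatic, b2.somatic)
        pd.testing.assert_frame_equal(b1.germline, b2.germline)
        assert b1.truth == b2.truth

    def test_different_seeds_differ_but_share_schema(self):
        cfg1 = CohortConfig(n_per_group={"EUR": 40, "AFR": 20}, seed=1)
        cfg2 = CohortConfig(n_per_group={"EUR": 40, "AFR": 20}, seed=2)
        b1, b2 = generate_cohort(cfg1), generate_cohort(cfg2)
        assert list(b1.somatic.columns) == list(b2.somatic.columns)
        assert not b1.somatic.equals(b2.somatic)

    def test_clinical_table_independent_of_variant_generation(self):
        cfg = CohortConfig(n_per_group={"EUR": 50, "AFR": 20}, seed=3)
        alone, _ = generate_clinical(cfg)
        full = generate_cohort(cfg).clinical
        pd.testing.assert_frame_equal(
            alone.drop(columns=["germline_brca"]), full.drop(columns=["germline_brca"])
        )


class TestStructure:
    def test_empty_config_gives_empty_tables(self):
        cfg = CohortConfig(n_per_group={"EUR": 0, "AFR": 0, "SAS": 0, "Admix": 0})
        bundle = generate_cohort(cfg)
        assert len(bundle.clinical) == 0
        assert len(bundle.somatic) == 0
        assert len(bundle.germline) == 0

    def test_group_sizes_exact(self, bundle, small_config):
        sizes = bundle.clinical["intended_group"].value_counts().to_dict()
        assert sizes == small_config.n_per_group

    def test_referential_integrity(self, bundle):
        pids = set(bundle.clinical["participant_id"])
        assert set(bundle.somatic["sample_id"]) <= pids
        assert set(bundle.germline["participant_id"]) <= pids

    def test_assignment_fraction_honoured(self):
        cfg = CohortConfig(n_per_group={"EUR": 2000}, seed=4)
        clinical, _ = generate_clinical(cfg)
        frac = (clinical["gAncestry"] == "EUR").mean()
        se = np.sqrt(0.95 * 0.05 / 2000)
        assert abs(frac - cfg.assign_fraction) < 4 * se

    def test_age_shift_within_three_se(self):
        """Law-of-large-numbers check on the generated age columns."""
        cfg = CohortConfig(
            n_per_group={"EUR": 2000, "AFR": 2000},
            effect_model={"age_shift_years": {"AFR": -5.0, "SAS": 0.0, "Admix": 0.0}},
            seed=6,
        )
        clinical, _ = generate_clinical(cfg)
        by = clinical.groupby("intended_group")["age_at_diagnosis"]
        diff = by.mean()["AFR"] - by.mean()["EUR"]
        se = np.sqrt((by.var() / by.count()).sum())
        assert abs(diff - (-5.0)) < 3 * se


class TestAnnotationModel:
    def test_schema_and_ranges(self, small_config, rng):
        ann = generate_annotation_resources(small_config, 5000, rng=rng)
        assert ((ann["vaf"] >= 0) & (ann["vaf"] <= 1)).all()
        assert (ann["cosmic_count"] >= 0).all()
        for col in ("gnomad_afr", "gnomad_sas", "gnomad_nfe", "topmed_freq"):
            assert ((ann[col] >= 0) & (ann[col] <= 1)).all()

    def test_all_absent_gnomad_forces_rare_branch(self):
        cfg = CohortConfig(
            n_per_group={"EUR": 60, "AFR": 20, "SAS": 20},
            annotation_model={"gnomad_absent_frac": 1.0},
            seed=7,
        )
        bundle = generate_cohort(cfg)
        anc = dict(zip(bundle.clinical["participant_id"], bundle.clinical["gAncestry"]))
        analysable = {s: a for s, a in anc.items() if a in tmb_mod.POPULATION_BY_ANCESTRY}
        out = tmb_mod.classify_table(
            bundle.somatic[bundle.somatic["sample_id"].isin(analysable)], analysable
        )
        assert (out["branch"] != tmb_mod.COMMON_COSMIC).all()

    def test_topmed_fraction_discards_downstream(self):
        """~30% of otherwise-retained variants fall to the TOPMED rule when
        30% of variants carry a common TOPMED frequency."""
        cfg = CohortConfig(
            n_per_group={"EUR": 150},
            annotation_model={"topmed_common_frac": 0.30},
            seed=8,
        )
        bundle = generate_cohort(cfg)
        anc = dict(zip(bundle.clinical["participant_id"], bundle.clinical["gAncestry"]))
        analysable = {s: a for s, a in anc.items() if a in tmb_mod.POPULATION_BY_ANCESTRY}
        out = tmb_mod.classify_table(
            bundle.somatic[bundle.somatic["sample_id"].isin(analysable)], analysable
        )
        # drivers are TOPMED-free by construction; restrict to passengers
        passengers = out[out["gene"].str.startswith("SOMBG_")]
        dropped = (passengers["branch"] == tmb_mod.TOPMED_EXCLUDED).sum()
        would_retain = dropped + passengers["retained"].sum()
        assert would_retain > 500
        assert abs(dropped / would_retain - 0.30) < 0.03

    def test_retention_probability_predicts_observed_rate(self, bundle, small_config):
        anc = dict(zip(bundle.clinical["participant_id"], bundle.clinical["gAncestry"]))
        analysable = {s: a for s, a in anc.items() if a in tmb_mod.POPULATION_BY_ANCESTRY}
        passengers = bundle.somatic[
            bundle.somatic["sample_id"].isin(analysable)
            & bundle.somatic["gene"].str.startswith("SOMBG_")
        ]
        out = tmb_mod.classify_table(passengers, analysable)
        predicted = retention_probability(small_config)
        assert out["retained"].mean() == pytest.approx(predicted, abs=0.03)


class TestMissingness:
    def test_injected_missingness(self):
        cfg = CohortConfig(
            n_per_group={"EUR": 800},
            missingness={"ER": 0.2},
            seed=9,
        )
        clinical, _ = generate_clinical(cfg)
        assert clinical["ER"].isna().mean() == pytest.approx(0.2, abs=0.05)

    def test_unknown_column_rejected(self):
        cfg = CohortConfig(n_per_group={"EUR": 10}, missingness={"nope": 0.5})
        with pytest.raises(ConfigError, match="nope"):
            generate_clinical(cfg)


class TestFixtures:
    def test_tsv_round_trip_is_lossless(self, bundle, tmp_path):
        paths = write_fixtures(bundle, tmp_path.as_posix())
        pd.testing.assert_frame_equal(
            bcio.read_clinical(paths["clinical"]), bundle.clinical
        )
        pd.testing.assert_frame_equal(
            bcio.read_somatic_tsv(paths["somatic_tsv"]), bundle.somatic
        )
        pd.testing.assert_frame_equal(
            bcio.read_germline(paths["germline"]), bundle.germline
        )
        assert bcio.read_panel(paths["panel"]) == bundle.panel

    def test_vcf_validates_through_independent_parser(self, bundle, tmp_path):
        """The VCF output parses under cyvcf2 and reproduces the table
        (floats to the precision written)."""
        paths = write_fixtures(bundle, tmp_path.as_posix())
        back = bcio.read_somatic_vcf(paths["somatic_vcf"])
        assert len(back) == len(bundle.somatic)
        orig = bundle.somatic.sort_values(["sample_id", "variant_id"]).reset_index(drop=True)
        got = back.sort_values(["sample_id", "variant_id"]).reset_index(drop=True)
        pd.testing.assert_series_equal(orig["gene"], got["gene"])
        assert np.allclose(orig["vaf"], got["vaf"], atol=1e-4)
        assert np.allclose(orig["gnomad_nfe"], got["gnomad_nfe"], atol=1e-4)
        assert (orig["cosmic_count"] == got["cosmic_count"]).all()

    def test_empty_bundle_writes_valid_headers(self, tmp_path):
        cfg = CohortConfig(n_per_group={"EUR": 0})
        bundle = generate_cohort(cfg)
        paths = write_fixtures(bundle, tmp_path.as_posix())
        assert bcio.read_clinical(paths["clinical"]).empty
        assert bcio.read_somatic_tsv(paths["somatic_tsv"]).empty
        with open(paths["somatic_vcf"]) as fh:
            assert fh.readline().startswith("##fileformat=VCFv4.2")
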