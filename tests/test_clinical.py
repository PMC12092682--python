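"""Clinical regression battery, deprivation tests and screening windows."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from bcancestry import clinical
from bcancestry.config import CohortConfig
from bcancestry.synthetic import generate_clinical


def _clinical_table(n_per_group, seed):
    cfg = CohortConfig(n_per_group=n_per_group, seed=seed)
    table, truth = generate_clinical(cfg)
    return table, truth


class TestAgeModel:
    def test_estimates_equal_group_mean_differences(self, bundle):
        """With a factor-only design, OLS coefficients are exactly the
        group-mean differences from the reference (closed-form oracle)."""
        table = bundle.clinical
        records = clinical.fit_age_model(table)
        means = table.groupby("gAncestry")["age_at_diagnosis"].mean()
        for rec in records:
            if rec.converged:
                assert rec.estimate == pytest.approx(means[rec.term] - means["EUR"], abs=1e-8)

    def test_recovers_injected_shift(self):
        table, truth = _clinical_table({"EUR": 2000, "AFR": 2000}, seed=0)
        records = {r.term: r for r in clinical.fit_age_model(table)}
        afr = records["AFR"]
        assert afr.converged
        assert afr.covers(truth["age_shift_years"]["AFR"])

    def test_null_groups_cover_zero(self):
        """Identical age distributions: 95% CIs cover zero at roughly the
        nominal rate over seeds."""
        covered = 0
        for seed in range(20):
            cfg = CohortConfig(
                n_per_group={"EUR": 300, "AFR": 300},
                effect_model={"age_shift_years": {"AFR": 0.0, "SAS": 0.0, "Admix": 0.0}},
                seed=seed,
            )
            table, _ = generate_clinical(cfg)
            rec = {r.term: r for r in clinical.fit_age_model(table)}["AFR"]
            covered += rec.covers(0.0)
        assert covered >= 17

    def test_single_group_raises(self, bundle):
        table = bundle.clinical[bundle.clinical["gAncestry"] == "EUR"]
        with pytest.raises(clinical.SingleGroupError):
            clinical.fit_age_model(table)

    def test_tiny_level_flagged_not_fitted(self, bundle):
        table = bundle.clinical.copy()
        extra = table.iloc[[0]].assign(gAncestry="EAS")
        records = clinical.fit_age_model(pd.concat([table, extra]))
        flagged = {r.term: r for r in records}["EAS"]
        assert not flagged.converged

    def test_row_order_invariance(self, bundle):
        table = bundle.clinical
        a = clinical.fit_age_model(table)
        b = clinical.fit_age_model(table.sample(frac=1.0, random_state=5))
        for ra, rb in zip(sorted(a, key=lambda r: r.term), sorted(b, key=lambda r: r.term)):
            assert ra.estimate == pytest.approx(rb.estimate, abs=1e-10)


class TestCategoricalModel:
    def test_two_group_or_equals_sample_odds_ratio(self):
        """Logistic MLE for a factor-only model equals the 2x2 sample OR."""
        table = pd.DataFrame({
            "gAncestry": ["EUR"] * 200 + ["AFR"] * 100,
            "ER": ["negative"] * 30 + ["positive"] * 170 + ["negative"] * 35 + ["positive"] * 65,
        })
        rec = clinical.fit_categorical_model(table, "ER")[0]
        sample_or = (35 / 65) / (30 / 170)
        assert rec.estimate == pytest.approx(sample_or, rel=1e-6)

    def test_recovers_injected_er_odds_ratio(self):
        table, truth = _clinical_table({"EUR": 2000, "AFR": 2000}, seed=1)
        rec = {r.term: r for r in clinical.fit_categorical_model(table, "ER")}["AFR"]
        assert rec.converged
        assert rec.covers(truth["receptor_neg_or"]["ER"]["AFR"])

    def test_constant_outcome_flagged(self):
        table = pd.DataFrame({
            "gAncestry": ["EUR"] * 50 + ["AFR"] * 50,
            "ER": ["positive"] * 100,
        })
        records = clinical.fit_categorical_model(table, "ER")
        assert all(not r.converged for r in records)

    def test_separated_level_flagged_others_fitted(self):
        table = pd.DataFrame({
            "gAncestry": ["EUR"] * 100 + ["AFR"] * 80 + ["SAS"] * 40,
            "ER": (["negative"] * 20 + ["positive"] * 80
                   + ["negative"] * 30 + ["positive"] * 50
                   + ["positive"] * 40),  # SAS all positive: separation
        })
        records = {r.term: r for r in clinical.fit_categorical_model(table, "ER")}
        assert records["SAS"].converged is False
        assert records["AFR"].converged is True

    def test_ordinal_outcome_uses_merged_upper_levels(self, bundle):
        records = clinical.fit_categorical_model(bundle.clinical, "grade")
        assert any(r.converged for r in records)


class TestTMBModel:
    def test_poisson_limit(self, rng):
        """On Poisson-distributed counts the NB fit collapses to the
        Poisson regression estimates."""
        n = 1500
        group = np.repeat(["EUR", "SAS"], n)
        mu = np.where(group == "EUR", 50.0, 42.0)
        counts = rng.poisson(mu)
        table = pd.DataFrame({"gAncestry": group, "retained_count": counts})
        rec = clinical.fit_tmb_model(table)[0]
        X = sm.add_constant((group == "SAS").astype(float))
        pois = sm.GLM(counts, X, family=sm.families.Poisson(),
                      exposure=np.full(2 * n, 35.4)).fit()
        assert np.log(rec.estimate) == pytest.approx(pois.params[1], abs=1e-3)

    def test_null_ratio_covers_one(self, rng):
        counts = rng.negative_binomial(5, 0.1, size=1000)
        table = pd.DataFrame({
            "gAncestry": np.repeat(["EUR", "SAS"], 500),
            "retained_count": counts,
        })
        rec = clinical.fit_tmb_model(table)[0]
        assert rec.ci_low <= 1.0 <= rec.ci_high

    def test_all_zero_counts_rejected(self):
        table = pd.DataFrame({
            "gAncestry": ["EUR"] * 10 + ["AFR"] * 10,
            "retained_count": [0] * 20,
        })
        with pytest.raises(ValueError):
            clinical.fit_tmb_model(table)

    def test_offset_only_moves_intercept(self, rng):
        counts = rng.poisson(40, size=600)
        table = pd.DataFrame({
            "gAncestry": np.repeat(["EUR", "AFR"], 300),
            "retained_count": counts,
        })
        with_offset = clinical.fit_tmb_model(table, use_offset=True)[0]
        without = clinical.fit_tmb_model(table, use_offset=False)[0]
        assert with_offset.estimate == pytest.approx(without.estimate, rel=1e-4)


class TestIMD:
    def test_lrt_df_is_four_with_five_quintiles(self, bundle):
        res = clinical.lrt_imd(bundle.clinical, "age_at_diagnosis")
        assert res.tested and res.df == 4
        assert res.statistic >= 0.0

    def test_lrt_null_pvalues_uniform(self):
        """IMD independent of age by construction: LRT p-values pass a KS
        test against uniform at the 1% level."""
        from scipy import stats

        pvals = []
        rng = np.random.default_rng(7)
        for _ in range(150):
            n = 200
            table = pd.DataFrame({
                "gAncestry": rng.choice(["EUR", "AFR"], size=n, p=[0.7, 0.3]),
                "age_at_diagnosis": rng.normal(60, 10, size=n),
                "IMD_quintile": rng.integers(1, 6, size=n),
            })
            pvals.append(clinical.lrt_imd(table, "age_at_diagnosis").p)
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_lrt_detects_strong_imd_effect(self):
        rng = np.random.default_rng(8)
        hits = 0
        for _ in range(20):
            n = 400
            imd = rng.integers(1, 6, size=n)
            table = pd.DataFrame({
                "gAncestry": rng.choice(["EUR", "AFR"], size=n),
                "age_at_diagnosis": rng.normal(60, 5, size=n) - 6.0 * (imd == 5),
                "IMD_quintile": imd,
            })
            if clinical.lrt_imd(table, "age_at_diagnosis").p < 0.01:
                hits += 1
        assert hits >= 19

    def test_constant_imd_flagged_untested(self, bundle):
        table = bundle.clinical.copy()
        table["IMD_quintile"] = 3
        res = clinical.lrt_imd(table, "age_at_diagnosis")
        assert not res.tested and res.df == 0

    def test_association_direction(self):
        """Age shifted down only in quintile 5: ANOVA flags it and the
        quintile-5 mean is lowest."""
        rng = np.random.default_rng(9)
        n = 1000
        imd = rng.integers(1, 6, size=n)
        table = pd.DataFrame({
            "age_at_diagnosis": rng.normal(62, 8, size=n) - 3.0 * (imd == 5),
            "IMD_quintile": imd,
            "ER": rng.choice(["positive", "negative"], size=n),
        })
        res = clinical.imd_association_tests(table, categorical_vars=["ER"])
        age_row = res[res["variable"] == "age_at_diagnosis"].iloc[0]
        assert age_row["p"] < 0.01
        means = age_row["group_means"]
        assert min(means, key=means.get) == 5

    def test_single_quintile_flagged(self):
        table = pd.DataFrame({
            "age_at_diagnosis": [60.0] * 20,
            "IMD_quintile": [2] * 20,
            "ER": ["positive"] * 20,
        })
        res = clinical.imd_association_tests(table, categorical_vars=["ER"])
        assert (res["flag"] != "").all()


class TestScreeningWindows:
    def test_uniform_grid_gives_20_80(self):
        w = clinical.derive_screening_window(np.arange(0, 101, dtype=float))
        assert (w.lower, w.upper) == (20, 80)

    def test_central_band_coverage(self, rng):
        """Any continuous sample: the 20-80 window covers 55-65% once
        n >= 500 (central 60% plus outward rounding)."""
        samples = [
            rng.normal(60, 12, 800),
            rng.uniform(25, 95, 600),
            18 + rng.gamma(5, 8, 1000),
        ]
        for ages in samples:
            w = clinical.derive_screening_window(ages)
            assert 0.55 <= w.coverage <= 0.65

    def test_too_few_ages_rejected(self):
        with pytest.raises(ValueError):
            clinical.derive_screening_window([50.0] * 9)

    def test_degenerate_distribution_rejected(self):
        with pytest.raises(ValueError):
            clinical.derive_screening_window([50.0] * 30)

    def test_coverage_arithmetic(self):
        ages = [60.0] * 215 + [20.0] * 100 + [90.0] * 48
        covered, total, pct = clinical.window_coverage(ages, (50, 70))
        assert (covered, total, pct) == (215, 363, 59.2)

    def test_full_range_window_covers_everything(self, rng):
        ages = rng.uniform(20, 90, 100)
        _, _, pct = clinical.window_coverage(ages, (0, 120))
        assert pct == 100.0

    def test_inclusive_bounds(self):
        covered, total, _ = clinical.window_coverage([50.0, 70.0, 71.0], (50, 70))
        assert (covered, total) == (2, 3)

    def test_empty_ages_rejected(self):
        with pytest.raises(ValueError):
            clinical.window_coverage([], (50, 70))

    def test_widening_never_loses_coverage(self, rng):
        ages = rng.normal(60, 12, 400)
        prev = 0
        for width in range(5, 40, 5):
            covered, _, _ = clinical.window_coverage(ages, (60 - width, 60 + width))
            assert covered >= prev
            prev = covered
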