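"""Differential somatic mutation: logistic and threshold routes."""

from fractions import Fraction

import numpy as np
import pandas as pd
import pytest

from bcancestry import somatic


def brute_force_threshold(n: int, threshold=Fraction(2, 100)) -> int:
    m = 1
    while not Fraction(m, n) > threshold:
        m += 1
    return m


class TestThresholdCount:
    @pytest.mark.parametrize("n,expected", [(2343, 47), (123, 3), (138, 3), (50, 2), (1, 1)])
    def test_study_sizes(self, n, expected):
        assert somatic.threshold_count(n) == expected

    def test_nonpositive_size_rejected(self):
        with pytest.raises(ValueError):
            somatic.threshold_count(0)

    def test_matches_brute_force_up_to_10000(self):
        for n in range(1, 10001):
            assert somatic.threshold_count(n) == brute_force_threshold(n)


def _matrix_with_counts(counts_by_group, sizes):
    """Single-feature matrix with exact per-group carrier counts."""
    ancestry, flags, idx = [], [], []
    for g, n in sizes.items():
        k = counts_by_group.get(g, 0)
        ancestry += [g] * n
        flags += [True] * k + [False] * (n - k)
        idx += [f"{g}{i}" for i in range(n)]
    matrix = pd.DataFrame({"FEAT": flags}, index=idx)
    return matrix, pd.Series(ancestry, index=idx)


class TestThresholdClassifier:
    SIZES = {"EUR": 2343, "AFR": 138, "SAS": 123}

    def test_afr_only_feature(self):
        """4/138 AFR, 10/2343 EUR, 1/123 SAS is present only in AFR under
        the 47/3/3 minimal counts."""
        matrix, anc = _matrix_with_counts({"AFR": 4, "EUR": 10, "SAS": 1}, self.SIZES)
        out = somatic.threshold_classifier(matrix, anc)
        assert out.loc[0, "intersection"] == "AFR"

    def test_everywhere_present(self):
        matrix, anc = _matrix_with_counts({"AFR": 10, "EUR": 100, "SAS": 10}, self.SIZES)
        out = somatic.threshold_classifier(matrix, anc)
        assert out.loc[0, "intersection"] == "EUR+AFR+SAS"

    def test_below_threshold_everywhere(self):
        matrix, anc = _matrix_with_counts({"AFR": 2, "EUR": 46, "SAS": 2}, self.SIZES)
        out = somatic.threshold_classifier(matrix, anc)
        assert out.loc[0, "intersection"] is None

    def test_empty_cohort_rejected(self):
        matrix, anc = _matrix_with_counts({"EUR": 1}, {"EUR": 10, "AFR": 5})
        with pytest.raises(ValueError, match="SAS"):
            somatic.threshold_classifier(matrix, anc)

    def test_intersections_partition_present_features(self, rng):
        n = {"EUR": 400, "AFR": 60, "SAS": 50}
        idx = [f"p{i}" for i in range(sum(n.values()))]
        anc = pd.Series(np.repeat(list(n), list(n.values())), index=idx)
        matrix = pd.DataFrame(
            rng.random((len(idx), 30)) < rng.uniform(0.0, 0.2, 30),
            index=idx, columns=[f"G{i}" for i in range(30)],
        )
        out = somatic.threshold_classifier(matrix, anc)
        sets = somatic.intersection_sets(out)
        assert sum(len(v) for v in sets.values()) == out["intersection"].notna().sum()
        assert len(sets) == 7


def _simulated_matrix(rng, n_per_group, freqs, n_null=0, null_freq=0.1):
    groups = list(n_per_group)
    idx, anc = [], []
    for g in groups:
        idx += [f"{g}{i}" for i in range(n_per_group[g])]
        anc += [g] * n_per_group[g]
    anc = pd.Series(anc, index=idx)
    cols = {}
    for feat, by_group in freqs.items():
        cols[feat] = np.concatenate([
            rng.random(n_per_group[g]) < by_group[g] for g in groups
        ])
    for j in range(n_null):
        cols[f"NULL{j}"] = rng.random(len(idx)) < null_freq
    matrix = pd.DataFrame(cols, index=idx)
    age = pd.Series(rng.normal(60, 10, len(idx)), index=idx)
    return matrix, anc, age


class TestLogisticRoute:
    def test_recovers_simulated_odds_ratio(self, rng):
        freqs = {"DRIVER": {"EUR": 0.05, "AFR": 0.25, "SAS": 0.05}}
        matrix, anc, age = _simulated_matrix(
            rng, {"EUR": 800, "AFR": 800, "SAS": 200}, freqs
        )
        out = somatic.per_feature_logistic(matrix, anc, age)
        row = out[(out["feature"] == "DRIVER") & (out["term"] == "AFR")].iloc[0]
        true_or = (0.25 / 0.75) / (0.05 / 0.95)
        assert row["converged"]
        assert row["ci_low"] <= true_or <= row["ci_high"]
        assert row["significant"]

    def test_absent_feature_routed_to_threshold(self, rng):
        freqs = {"GONE": {"EUR": 0.10, "AFR": 0.0, "SAS": 0.10}}
        matrix, anc, age = _simulated_matrix(rng, {"EUR": 200, "AFR": 100, "SAS": 100}, freqs)
        out = somatic.per_feature_logistic(matrix, anc, age)
        assert not out[out["feature"] == "GONE"]["converged"].any()
        assert out[out["feature"] == "GONE"]["p_adj"].isna().all()

    def test_null_features_rarely_rejected(self):
        """Under the global null the BH-adjusted rejection fraction at the
        0.1 threshold stays at or below 0.1 on average."""
        fracs = []
        for seed in range(5):
            rng = np.random.default_rng(100 + seed)
            matrix, anc, age = _simulated_matrix(
                rng, {"EUR": 300, "AFR": 150, "SAS": 150}, {}, n_null=40
            )
            out = somatic.per_feature_logistic(matrix, anc, age)
            conv = out[out["converged"]]
            fracs.append(conv["significant"].mean() if len(conv) else 0.0)
        assert np.mean(fracs) <= 0.1

    def test_bh_monotone_and_order_invariant(self, rng):
        matrix, anc, age = _simulated_matrix(
            rng, {"EUR": 300, "AFR": 100, "SAS": 100}, {}, n_null=25
        )
        out = somatic.per_feature_logistic(matrix, anc, age)
        for lvl in ("AFR", "SAS"):
            sub = out[(out["term"] == lvl) & out["converged"]].sort_values("p")
            assert sub["p_adj"].is_monotonic_increasing
            assert (sub["p_adj"] >= sub["p"] - 1e-12).all()
        shuffled = somatic.per_feature_logistic(
            matrix[matrix.columns[::-1]], anc, age
        )
        merged = out.merge(shuffled, on=["feature", "term"], suffixes=("_a", "_b"))
        assert np.allclose(merged["p_adj_a"].fillna(-1), merged["p_adj_b"].fillna(-1))

    def test_non_binary_feature_rejected(self, rng):
        matrix, anc, age = _simulated_matrix(rng, {"EUR": 50, "AFR": 50, "SAS": 50}, {}, 1)
        matrix["NULL0"] = 2
        with pytest.raises(ValueError, match="non-binary"):
            somatic.per_feature_logistic(matrix, anc, age)


class TestConfounderModel:
    def _base(self, rng, n=800, feature_from_brca=False):
        groups = {"EUR": n, "AFR": n, "SAS": n // 4}
        idx, anc = [], []
        for g, k in groups.items():
            idx += [f"{g}{i}" for i in range(k)]
            anc += [g] * k
        anc = pd.Series(anc, index=idx)
        age = pd.Series(rng.normal(60, 10, len(idx)), index=idx)
        # BRCA more frequent in AFR: a genuine potential confounder
        brca = pd.Series(
            rng.random(len(idx)) < np.where(anc == "AFR", 0.3, 0.05), index=idx
        ).astype(int)
        imd = pd.Series(rng.integers(1, 6, len(idx)), index=idx)
        if feature_from_brca:
            p = np.where(brca == 1, 0.5, 0.05)
        else:
            p = np.where(anc == "AFR", 0.25, 0.08)
        matrix = pd.DataFrame({"FEAT": rng.random(len(idx)) < p}, index=idx)
        return matrix, anc, age, brca, imd

    def test_null_confounding_leaves_or_unchanged(self, rng):
        matrix, anc, age, brca, imd = self._base(rng)
        # make BRCA independent of the feature AND of ancestry
        brca = pd.Series(np.random.default_rng(4).random(len(brca)) < 0.1,
                         index=brca.index).astype(int)
        eq1 = somatic.per_feature_logistic(matrix, anc, age)
        eq2 = somatic.confounder_model(matrix, anc, age, brca, imd)
        a = eq1[(eq1["term"] == "AFR")].iloc[0]["odds_ratio"]
        b = eq2[(eq2["term"] == "AFR")].iloc[0]["odds_ratio"]
        assert b == pytest.approx(a, rel=0.10)

    def test_brca_driven_feature_attenuates(self, rng):
        matrix, anc, age, brca, imd = self._base(rng, feature_from_brca=True)
        eq1 = somatic.per_feature_logistic(matrix, anc, age)
        eq2 = somatic.confounder_model(matrix, anc, age, brca, imd)
        a = eq1[(eq1["term"] == "AFR")].iloc[0]["odds_ratio"]
        b = eq2[(eq2["term"] == "AFR")].iloc[0]["odds_ratio"]
        assert abs(np.log(b)) < abs(np.log(a))

    def test_all_missing_covariate_named(self, rng):
        matrix, anc, age, brca, imd = self._base(rng, n=100)
        imd[:] = np.nan
        with pytest.raises(ValueError, match="IMD"):
            somatic.confounder_model(matrix, anc, age, brca, imd)


class TestVariantClassRates:
    def _counts(self, total, n):
        base = total // n
        vals = [base] * (n - 1) + [total - base * (n - 1)]
        return vals

    def test_published_style_per_patient_rates(self):
        eur = self._counts(29_262_814, 2343)
        afr = self._counts(1_927_230, 138)
        counts = pd.DataFrame({
            "substitutions": eur + afr,
        }, index=[f"p{i}" for i in range(2343 + 138)])
        anc = pd.Series(["EUR"] * 2343 + ["AFR"] * 138, index=counts.index)
        out = somatic.variant_class_rates(counts, anc, classes=("substitutions",),
                                          groups=("EUR", "AFR"))
        rates = dict(zip(out["group"], out["per_patient_1dp"]))
        assert rates["AFR"] == 13965.4
        assert rates["EUR"] == 12489.5

    def test_absent_group_flagged(self, rng):
        counts = pd.DataFrame({"substitutions": rng.poisson(100, 50)},
                              index=[f"p{i}" for i in range(50)])
        anc = pd.Series(["EUR"] * 50, index=counts.index)
        out = somatic.variant_class_rates(counts, anc, classes=("substitutions",))
        assert (out.loc[out["group"] == "SAS", "flag"] == "group absent").all()

    def test_negative_counts_rejected(self):
        counts = pd.DataFrame({"substitutions": [-1, 5]}, index=["a", "b"])
        anc = pd.Series(["EUR", "AFR"], index=counts.index)
        with pytest.raises(ValueError):
            somatic.variant_class_rates(counts, anc, classes=("substitutions",))


class TestMutationMatrix:
    def test_built_from_retained_calls(self, bundle):
        anc = dict(zip(bundle.clinical["participant_id"], bundle.clinical["gAncestry"]))
        from bcancestry import tmb as tmb_mod

        analysable = {s: a for s, a in anc.items() if a in tmb_mod.POPULATION_BY_ANCESTRY}
        classified = tmb_mod.classify_table(
            bundle.somatic[bundle.somatic["sample_id"].isin(analysable)], analysable
        )
        matrix = somatic.build_mutation_matrix(classified, sorted(analysable))
        assert matrix.dtypes.eq(bool).all()
        assert set(matrix.index) == set(analysable)
        # every flagged cell corresponds to at least one retained call
        sample = matrix.columns[0]
        flagged = matrix.index[matrix[sample]]
        retained = classified[classified["retained"] & (classified["gene"] == sample)]
        assert set(flagged) == set(retained["sample_id"])
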