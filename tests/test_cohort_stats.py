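"""Assumption checks, ANCOVA, chi-square, burden stratification."""

import numpy as np
import pandas as pd
import pytest

from gliovasc.cohort_stats import (ancova_group_roi, bonferroni,
                                   burden_analysis, check_and_transform,
                                   chi_square_test, demographics_table,
                                   stratify_burden)
from gliovasc.imaging_io import SubjectRecord
from gliovasc.synthetic_cohort import (CohortSpec, sample_outcome_table,
                                       scaled_effects)


class TestCheckAndTransform:
    def test_normal_data_untransformed(self, rng):
        values = np.concatenate([rng.normal(0, 1, 50), rng.normal(0, 1, 50)])
        groups = np.array(["a"] * 50 + ["b"] * 50)
        _, applied = check_and_transform(values, groups)
        assert applied is False

    def test_lognormal_data_usually_transformed(self):
        hits = 0
        reps = 200
        for i in range(reps):
            rng = np.random.default_rng(100 + i)
            values = np.concatenate([rng.lognormal(0, 1, 30),
                                     rng.lognormal(0, 1, 30)])
            groups = np.array(["a"] * 30 + ["b"] * 30)
            out, applied = check_and_transform(values, groups)
            hits += applied
        assert hits / reps >= 0.90

    def test_log_applied_to_positive_values(self):
        rng = np.random.default_rng(0)
        values = np.concatenate([rng.lognormal(0, 1.5, 30),
                                 rng.lognormal(1, 1.5, 30)])
        groups = np.array(["a"] * 30 + ["b"] * 30)
        out, applied = check_and_transform(values, groups)
        if applied:
            np.testing.assert_allclose(out, np.log(values))

    def test_shifted_log_for_nonpositive(self):
        rng = np.random.default_rng(0)
        values = np.concatenate([rng.lognormal(0, 2, 30) - 5,
                                 rng.lognormal(0, 2, 30)])
        groups = np.array(["a"] * 30 + ["b"] * 30)
        out, applied = check_and_transform(values, groups)
        assert np.all(np.isfinite(out))

    def test_constant_values_degenerate_no_crash(self):
        values = np.full(20, 3.0)
        groups = np.array(["a"] * 10 + ["b"] * 10)
        out, applied = check_and_transform(values, groups)
        assert applied is False

    def test_too_few_per_group(self):
        with pytest.raises(ValueError):
            check_and_transform(np.arange(4.0), np.array(["a", "a", "b", "b"]))


def _toy_table(rng, n_per_cell=8, group_delta=0.0, seed_cov=True):
    rows = []
    i = 0
    for group in ("control", "hypertension"):
        for _ in range(n_per_cell):
            age = float(rng.normal(80, 5))
            sex = "F" if rng.random() < 0.5 else "M"
            fix = float(rng.normal(11, 3))
            for roi in ("NAWM", "WMH"):
                value = (10.0 + group_delta * (group == "hypertension")
                         + 1.0 * (roi == "WMH") + rng.normal(0, 1))
                rows.append({"subject_id": f"S{i}", "group": group,
                             "roi_name": roi, "age": age, "sex": sex,
                             "fixation_interval_months": fix, "value": value,
                             "outcome_name": "toy", "fazekas": int(rng.integers(0, 4))})
            i += 1
    return pd.DataFrame(rows)


class TestAncova:
    def test_group_f_matches_nested_model_oracle(self, rng):
        """Group F equals the partial F computed from scratch by least squares."""
        df = _toy_table(rng, group_delta=1.2)
        res = ancova_group_roi(df, "toy")
        group_res = [r for r in res if r.effect == "group"][0]

        y = df["value"].to_numpy()
        X_full = np.column_stack([
            np.ones(len(df)),
            (df["group"] == "hypertension").astype(float),
            (df["roi_name"] == "WMH").astype(float),
            (df["sex"] == "M").astype(float),
            df["age"].to_numpy(),
            df["fixation_interval_months"].to_numpy(),
        ])
        X_red = np.delete(X_full, 1, axis=1)

        def rss(X):
            beta, *_ = np.linalg.lstsq(X, y, rcond=None)
            r = y - X @ beta
            return float(r @ r)

        df_den = len(df) - X_full.shape[1]
        f_oracle = (rss(X_red) - rss(X_full)) / (rss(X_full) / df_den)
        assert group_res.statistic == pytest.approx(f_oracle, rel=1e-6)
        assert group_res.df == (1, df_den)

    def test_degenerate_covariate_dropped_matches_plain_anova(self, rng):
        """With a constant sex column the model reduces to the two-factor
        ANOVA with the remaining covariates, rather than failing."""
        df = _toy_table(rng)
        df["sex"] = "F"
        res = ancova_group_roi(df, "toy")
        assert len(res) == 2 and all(np.isfinite(r.statistic) for r in res)

    def test_requires_both_factors(self, rng):
        df = _toy_table(rng)
        with pytest.raises(ValueError):
            ancova_group_roi(df[df.roi_name == "NAWM"], "toy")

    def test_scale_equivariance(self, rng):
        """Multiplying the outcome by a positive constant leaves F unchanged."""
        df = _toy_table(rng)
        f1 = {r.effect: r.statistic for r in ancova_group_roi(df, "toy")}
        df2 = df.assign(value=df["value"] * 37.5)
        f2 = {r.effect: r.statistic for r in ancova_group_roi(df2, "toy")}
        for k in f1:
            assert f1[k] == pytest.approx(f2[k], rel=1e-9)

    def test_bonferroni_property(self, rng):
        df = _toy_table(rng)
        for r in ancova_group_roi(df, "toy", family_size=5):
            assert r.p_bonferroni == pytest.approx(min(1.0, 5 * r.p_raw))
            assert r.p_bonferroni >= r.p_raw

    def test_permutation_cross_check(self, rng):
        """ANCOVA group p agrees with a Freedman-Lane permutation p."""
        df = _toy_table(rng, group_delta=0.8)
        res = [r for r in ancova_group_roi(df, "toy") if r.effect == "group"][0]

        y = df["value"].to_numpy()
        g = (df["group"] == "hypertension").astype(float).to_numpy()
        Z = np.column_stack([np.ones(len(df)),
                             (df["roi_name"] == "WMH").astype(float),
                             (df["sex"] == "M").astype(float),
                             df["age"].to_numpy(),
                             df["fixation_interval_months"].to_numpy()])
        X = np.column_stack([Z, g])

        def f_stat(yv):
            b_full, *_ = np.linalg.lstsq(X, yv, rcond=None)
            r_full = yv - X @ b_full
            b_red, *_ = np.linalg.lstsq(Z, yv, rcond=None)
            r_red = yv - Z @ b_red
            dfden = len(yv) - X.shape[1]
            return (r_red @ r_red - r_full @ r_full) / (r_full @ r_full / dfden)

        b_red, *_ = np.linalg.lstsq(Z, y, rcond=None)
        fitted, resid = Z @ b_red, y - Z @ b_red
        f_obs = f_stat(y)
        n_perm = 10000
        perm_rng = np.random.default_rng(99)
        hits = 0
        for _ in range(n_perm):
            y_star = fitted + perm_rng.permutation(resid)
            hits += f_stat(y_star) >= f_obs
        p_perm = (hits + 1) / (n_perm + 1)
        assert abs(p_perm - res.p_raw) < 0.03


class TestChiSquare:
    def test_balanced_table_zero_statistic(self):
        r = chi_square_test([[10, 10], [10, 10]])
        assert r.statistic == pytest.approx(0.0)
        assert r.p_raw == pytest.approx(1.0)

    def test_hand_computed_statistic(self):
        """[[20,5],[5,20]]: all expected counts 12.5, chi2 = 4*(7.5^2)/12.5 = 18."""
        r = chi_square_test([[20, 5], [5, 20]])
        assert r.statistic == pytest.approx(18.0)

    def test_one_dimensional_rejected(self):
        with pytest.raises(ValueError):
            chi_square_test([[5, 10]])

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError):
            chi_square_test([[0, 0], [3, 4]])


class TestBurden:
    @pytest.mark.parametrize("fazekas,stratum", [
        (0, "mild"), (1, "mild"), (2, "moderate_severe"), (3, "moderate_severe"),
    ])
    def test_stratification_rule(self, fazekas, stratum):
        rec = SubjectRecord("S0", "control", 80.0, "F", 10.0, fazekas)
        assert stratify_burden([rec])["S0"] == stratum

    def test_single_stratum_rejected(self, rng):
        df = _toy_table(rng)
        df["fazekas"] = 0
        with pytest.raises(ValueError):
            burden_analysis(df, "toy")

    def test_burden_effect_recovered_on_truth(self):
        """A microglia-burden link in the generator is detected, and a null
        generator yields rejection near alpha."""
        eff = scaled_effects(0.0)
        eff["iba1_stain_od"]["burden_delta"] = 3 * eff["iba1_stain_od"]["sd"]
        spec = CohortSpec(effects=eff)
        hits_effect = 0
        for i in range(30):
            df = sample_outcome_table(spec, np.random.default_rng([40, i]))
            r = burden_analysis(df, "iba1_stain_od")[0]
            hits_effect += r.p_raw <= 0.05
        assert hits_effect / 30 > 0.5

        null = CohortSpec(effects=scaled_effects(0.0))
        hits_null = 0
        for i in range(60):
            df = sample_outcome_table(null, np.random.default_rng([41, i]))
            r = burden_analysis(df, "iba1_stain_od")[0]
            hits_null += r.p_raw <= 0.05
        assert hits_null / 60 <= 0.20


class TestDemographics:
    def _records(self, ages_a, ages_b, bmis=None):
        recs = []
        for i, a in enumerate(ages_a):
            extra = {} if bmis is None or i >= len(bmis) else {"bmi": bmis[i]}
            recs.append(SubjectRecord(f"A{i}", "control", a, "F", 10.0, 1,
                                      extra=extra))
        for i, a in enumerate(ages_b):
            recs.append(SubjectRecord(f"B{i}", "hypertension", a, "M", 10.0, 2))
        return recs

    def test_identical_groups_p_near_one(self):
        recs = self._records([70, 80, 90], [70, 80, 90])
        table = demographics_table(recs, continuous=("age",), categorical=())
        assert table.iloc[0]["p"] > 0.99

    def test_hand_computed_means_and_sds(self):
        recs = self._records([70.0, 80.0, 90.0], [60.0, 70.0, 95.0])
        table = demographics_table(recs, continuous=("age",), categorical=())
        row = table.iloc[0]
        assert row["control_mean"] == pytest.approx(80.0)
        assert row["control_sd"] == pytest.approx(10.0)
        assert row["hypertension_mean"] == pytest.approx(75.0)
        assert row["hypertension_sd"] == pytest.approx(np.std([60, 70, 95], ddof=1))

    def test_missing_values_reported_on_available_n(self):
        recs = self._records([70, 80, 90, 85], [75, 85],
                             bmis=[22.0, 25.0])  # BMI missing for 2 controls
        table = demographics_table(recs, continuous=("age", "bmi"),
                                   categorical=())
        bmi_row = table[table.variable == "bmi"].iloc[0]
        assert bmi_row["n"] == 2
        assert bmi_row["control_mean"] == pytest.approx(23.5)

    def test_wmh_volume_row_added(self):
        recs = self._records([70, 80, 90], [75, 85, 95])
        vols = {r.subject_id: 1.0 + 0.1 * i for i, r in enumerate(recs)}
        table = demographics_table(recs, wmh_volumes=vols,
                                   continuous=("age",), categorical=())
        assert "wmh_volume_ml" in set(table.variable)

    def test_minimum_cohort_size(self):
        with pytest.raises(ValueError):
            demographics_table(self._records([80.0], []))


def test_bonferroni_exact():
    assert bonferroni(0.01, 5) == pytest.approx(0.05)
    assert bonferroni(0.5, 5) == 1.0
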