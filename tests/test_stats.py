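"""Confound statistics: standardized regression, Model-1/2 comparison,
percent change, quality determinants and interpretation helpers."""

import numpy as np
import pandas as pd
import pytest

from connqc import (ConfoundModel, exclude_high_motion, fit_model1_model2,
                    motion_age_equivalence, percent_change,
                    quality_cross_correlations, quality_determinants,
                    standardized_regression)

# Published Model-1/Model-2 standardized-coefficient pairs with their printed
# percent-change cells (structural and functional connectivity outcomes).
# Each row: (beta_model1, beta_model2, printed_delta_pct).
PRINTED_DELTA_CELLS = [
    # structural: overall, node degree, clustering, efficiency
    (-0.179, -0.074, -59), (0.284, 0.213, -25), (-0.044, -0.045, +2),
    (0.096, 0.109, +14), (0.041, 0.048, +17),
    (-0.222, -0.110, -50), (0.058, -0.081, -240), (0.009, 0.035, +289),
    (-0.103, -0.082, -20), (-0.034, -0.027, -21), (-0.053, -0.036, -32),
    (0.179, 0.059, -67), (-0.207, -0.096, -54), (-0.037, -0.054, +46),
    (0.074, 0.046, -38), (0.093, 0.077, -17),
    (0.171, 0.180, +5), (-0.018, -0.076, +322),
    # structural R^2 rows
    (0.131, 0.204, +56), (0.097, 0.197, +103), (0.121, 0.199, +64),
    (0.031, 0.065, +110),
    # functional outcomes
    (-0.054, -0.062, +15), (-0.129, -0.119, -8), (0.039, 0.036, -8),
    (-0.030, -0.005, -83), (-0.065, -0.060, -8), (-0.040, -0.041, +3),
    (-0.058, -0.057, -2), (0.050, 0.042, -16), (-0.045, -0.042, -7),
    (0.060, 0.054, -10), (0.063, 0.050, -21), (-0.113, -0.095, -16),
    (0.094, 0.049, -48),
    # functional R^2 rows
    (0.007, 0.012, +71), (0.046, 0.049, +7), (0.013, 0.017, +31),
    (0.033, 0.048, +45),
]


class TestStandardizedRegression:
    def test_identity_fit(self, rng):
        x = rng.standard_normal(200)
        X = pd.DataFrame({"x": x, "z": rng.standard_normal(200)})
        r = standardized_regression(x, X)
        assert r.params["x"] == pytest.approx(1.0, abs=1e-10)
        assert r.rsquared == pytest.approx(1.0, abs=1e-10)

    def test_pure_noise_outcome(self, rng):
        n = 10_000
        X = pd.DataFrame(rng.standard_normal((n, 4)), columns=list("abcd"))
        r = standardized_regression(rng.standard_normal(n), X)
        assert (r.params.abs() < 0.05).all()
        assert r.rsquared < 0.01

    def test_affine_invariance(self, rng):
        n = 300
        X = pd.DataFrame(rng.standard_normal((n, 3)), columns=list("abc"))
        y = X["a"].to_numpy() * 0.5 + rng.standard_normal(n)
        r1 = standardized_regression(y, X)
        r2 = standardized_regression(100 + 42 * y, X * 7 - 3)
        pd.testing.assert_series_equal(r1.params, r2.params, atol=1e-10)

    def test_perfect_collinearity_names_offender(self, rng):
        X = pd.DataFrame({"a": rng.standard_normal(50)})
        X["b"] = 2 * X["a"]
        with pytest.raises(ValueError, match="b"):
            standardized_regression(rng.standard_normal(50), X)

    def test_constant_predictor_rejected(self, rng):
        X = pd.DataFrame({"a": np.ones(50)})
        with pytest.raises(ValueError, match="constant"):
            standardized_regression(rng.standard_normal(50), X)


class TestPercentChange:
    @pytest.mark.parametrize("b1, b2, printed", PRINTED_DELTA_CELLS)
    def test_reproduces_every_printed_delta_cell(self, b1, b2, printed):
        assert round(percent_change(b1, b2)) == printed

    def test_no_change_and_zero_baseline(self):
        assert percent_change(0.2, 0.2) == 0.0
        with pytest.raises(ZeroDivisionError):
            percent_change(0.0, 0.1)


class TestMotionAgeEquivalence:
    def test_published_inputs_give_18_point_3_years(self):
        yrs = motion_age_equivalence(beta_motion=-0.249, beta_age=-0.074,
                                     sd_motion=0.16, sd_age=8.7, delta_motion=0.1)
        assert round(yrs, 1) == 18.3

    def test_unit_equivalence(self):
        assert motion_age_equivalence(-0.2, -0.2, 0.5, 8.7, 0.5) == pytest.approx(8.7)

    def test_zero_increment_and_zero_age_effect(self):
        assert motion_age_equivalence(-0.2, -0.1, 0.5, 8.7, 0.0) == 0.0
        with pytest.raises(ZeroDivisionError):
            motion_age_equivalence(-0.2, 0.0, 0.5, 8.7, 0.1)

    def test_positive_sds_required(self):
        with pytest.raises(ValueError):
            motion_age_equivalence(-0.2, -0.1, 0.0, 8.7, 0.1)


def _simulated_confound_tables(rng, n=4000):
    """Outcome confounded by motion: age drives motion, motion drives y."""
    age = rng.standard_normal(n)
    motion = 0.6 * age + 0.8 * rng.standard_normal(n)
    isnr = rng.standard_normal(n)
    mism = rng.standard_normal(n)
    y = -0.05 * age - 0.5 * motion + 0.3 * rng.standard_normal(n)
    pid = [f"P{i}" for i in range(n)]
    cohort = pd.DataFrame({
        "participant_id": pid, "age": 59 + 8 * age,
        "sex": rng.integers(0, 2, n), "education": rng.integers(1, 4, n),
        "bmi": 26 + 4 * rng.standard_normal(n),
        "diabetes": rng.integers(0, 3, n), "cvd": rng.integers(0, 2, n),
        "wmh_rel": np.exp(rng.standard_normal(n)),
    })
    quality = pd.DataFrame({
        "participant_id": pid,
        "dmri_isnr": isnr, "dmri_motion": 0.64 + 0.16 * motion, "dmri_mismatch": mism,
        "fmri_isnr": isnr, "fmri_motion": motion, "fmri_mismatch": mism,
    })
    conn = pd.DataFrame({"participant_id": pid, "overall": y})
    return cohort, quality, conn


class TestModel1Model2:
    def test_confounded_association_is_attenuated_and_flagged(self, rng):
        cohort, quality, conn = _simulated_confound_tables(rng)
        res = ConfoundModel(conn, cohort, quality, "SC").fit()
        row = res.ledger.query("outcome == 'overall' and covariate == 'age'").iloc[0]
        # Model 1 absorbs the motion path; Model 2 adjusts it away
        assert row.beta_model1 < -0.2
        assert abs(row.beta_model2) < abs(row.beta_model1) / 2
        assert row.relevant
        assert row.delta_pct < -10

    def test_unconfounded_covariate_not_flagged(self, rng):
        cohort, quality, conn = _simulated_confound_tables(rng)
        res = fit_model1_model2(conn, cohort, quality, "SC")
        row = res.ledger.query("outcome == 'overall' and covariate == 'bmi'").iloc[0]
        assert not row.relevant

    def test_r2_row_uses_same_formula(self, rng):
        cohort, quality, conn = _simulated_confound_tables(rng, n=800)
        res = fit_model1_model2(conn, cohort, quality, "SC")
        row = res.ledger.query("covariate == 'R2'").iloc[0]
        assert row.delta_pct == pytest.approx(
            percent_change(res.model1["overall"].rsquared,
                           res.model2["overall"].rsquared))

    def test_modality_mismatch_detected(self, rng):
        cohort, quality, conn = _simulated_confound_tables(rng, n=200)
        quality = quality.drop(columns=["fmri_isnr"])
        with pytest.raises(ValueError, match="fmri_isnr"):
            ConfoundModel(conn, cohort, quality, "FC")

    def test_summary_renders(self, rng):
        cohort, quality, conn = _simulated_confound_tables(rng, n=300)
        s = fit_model1_model2(conn, cohort, quality, "SC").summary()
        assert "overall" in s and "delta %" in s


class TestQualityDeterminants:
    def test_recovers_generator_coefficients(self, cohort, quality_table):
        res = quality_determinants(cohort, quality_table)
        assert res["dmri_motion"].params["age"] == pytest.approx(0.368, abs=0.03)
        assert res["fmri_isnr"].params["bmi"] == pytest.approx(0.408, abs=0.03)
        assert res["fmri_mismatch"].params["sex"] == pytest.approx(0.317, abs=0.03)

    def test_forward_selection_keeps_strong_predictors_only(self, cohort,
                                                            quality_table):
        res = quality_determinants(cohort, quality_table, forward_selection=True)
        sel = set(res["dmri_motion"].params.index)
        assert {"age", "sex"} <= sel
        assert "cvd" not in sel  # configured coefficient 0.020, below noise


class TestCrossCorrelations:
    def test_generated_targets_and_symmetry(self, quality_table):
        r, p = quality_cross_correlations(quality_table)
        assert r.loc["fmri_isnr", "fmri_motion"] == pytest.approx(0.522, abs=0.04)
        assert r.loc["dmri_isnr", "dmri_motion"] == pytest.approx(0.298, abs=0.04)
        assert np.allclose(r.to_numpy(), r.to_numpy().T)
        assert (np.diag(r) == 1).all()
        assert p.loc["fmri_isnr", "fmri_motion"] < 0.001

    def test_independent_columns_near_zero(self, rng):
        n = 10_000
        q = pd.DataFrame({f"{m}_{k}": rng.standard_normal(n)
                          for m in ("dmri", "fmri")
                          for k in ("isnr", "motion", "mismatch")})
        r, _ = quality_cross_correlations(q)
        off = r.to_numpy()[~np.eye(6, dtype=bool)]
        assert np.abs(off).max() < 0.03

    def test_too_few_rows_rejected(self):
        with pytest.raises(ValueError):
            quality_cross_correlations(pd.DataFrame({"dmri_isnr": [1.0, 2.0]}))


class TestHighMotionExclusion:
    def test_infinite_threshold_is_identity(self, cohort, quality_table):
        res = exclude_high_motion(cohort, quality_table, threshold=np.inf)
        assert res.n_excluded == 0
        assert res.n_retained == len(cohort)

    def test_threshold_below_minimum_rejected(self, cohort, quality_table):
        with pytest.raises(ValueError):
            exclude_high_motion(cohort, quality_table,
                                threshold=quality_table.dmri_motion.min() / 2)

    def test_excluded_count_matches_direct_tail_count(self, cohort, quality_table):
        res = exclude_high_motion(cohort, quality_table, threshold=1.0)
        expect = int((quality_table.dmri_motion > 1.0).sum())
        assert res.n_excluded == expect
        assert (res.quality.dmri_motion <= 1.0).all()
        # calibrated generator: ~1-2% above 1.0 mm (2.25 SD above the mean)
        assert 0.002 < res.n_excluded / len(cohort) < 0.05

    def test_refit_runs_on_subset(self, rng):
        cohort, quality, conn = _simulated_confound_tables(rng, n=500)
        res = exclude_high_motion(cohort, quality, conn, threshold=0.8)
        assert res.results["SC"].ledger is not None
        assert res.n_retained == len(res.connectivity)
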