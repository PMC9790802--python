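"""Corer-comparison statistics: pairwise matching, major-axis regression,
variance decomposition, replicate consistency, heteroscedasticity."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize_scalar

from sedcarbon import (
    MixingParams,
    SurveySpec,
    bulk_density_from_carbon,
    compare_instruments,
    comparison_matrix,
    fit_mixing_model,
    generate_survey,
    heteroscedasticity_test,
    identity_slope_test,
    major_axis_slope_origin,
    pairwise_overlap,
    replicate_consistency_test,
    samples_to_frame,
    variance_decomposition,
    within_stratum_decomposition,
)


def _frame(rows):
    return pd.DataFrame(rows, columns=["instrument", "site", "depth_label", "bulk_density"])


class TestPairwiseOverlap:
    def test_shared_strata_are_matched_once(self):
        rows = []
        for s in ("s1", "s2", "s3"):
            for d in ("shallow", "mid"):
                rows.append(("a", s, d, 1.0))
                rows.append(("b", s, d, 1.1))
        matched = pairwise_overlap(_frame(rows))
        xa, xb = matched[("a", "b")]
        assert xa.size == xb.size == 6

    def test_full_design_pair_counts(self):
        # 4 instruments everywhere on 7 sites x 2 depths -> 14 matches each
        rows = [
            (i, f"s{k}", d, 1.0 + 0.01 * k)
            for i in "abcd"
            for k in range(7)
            for d in ("shallow", "mid")
        ]
        matched = pairwise_overlap(_frame(rows))
        assert len(matched) == 6
        assert all(x.size == 14 for x, _ in matched.values())

    def test_disjoint_instruments_give_empty_overlap(self):
        rows = [("a", "s1", "shallow", 1.0), ("b", "s2", "mid", 0.9)]
        matched = pairwise_overlap(_frame(rows))
        xa, xb = matched[("a", "b")]
        assert xa.size == 0


class TestMajorAxisSlope:
    def test_identity_data(self):
        x = np.array([0.2, 0.5, 1.1, 1.6])
        b, se = major_axis_slope_origin(x, x)
        assert b == pytest.approx(1.0, rel=1e-12)
        assert se == pytest.approx(0.0, abs=1e-12)

    def test_reciprocity(self, rng):
        x = rng.uniform(0.1, 2.0, 10)
        y = 0.8 * x + rng.normal(0, 0.1, 10)
        b_xy, _ = major_axis_slope_origin(x, y)
        b_yx, _ = major_axis_slope_origin(y, x)
        assert b_xy == pytest.approx(1.0 / b_yx, rel=1e-10)

    def test_matches_numeric_perpendicular_minimisation(self, rng):
        x = rng.uniform(0.1, 2.0, 10)
        y = 1.1 * x + rng.normal(0, 0.15, 10)

        def objective(b):
            return np.sum((y - b * x) ** 2) / (1 + b**2)

        res = minimize_scalar(objective, bounds=(0.1, 10.0), method="bounded",
                              options={"xatol": 1e-10})
        b, _ = major_axis_slope_origin(x, y)
        assert b == pytest.approx(res.x, abs=1e-6)

    def test_scaling_behaviour(self, rng):
        # common rescaling of both axes leaves the slope unchanged; scaling
        # one axis is equivariant only when the data are exactly proportional
        # (major-axis regression is not scale-equivariant in general)
        x = rng.uniform(0.1, 2.0, 12)
        y = 0.9 * x + rng.normal(0, 0.1, 12)
        b, _ = major_axis_slope_origin(x, y)
        b_common, _ = major_axis_slope_origin(3.0 * x, 3.0 * y)
        assert b_common == pytest.approx(b, rel=1e-10)
        b_exact, _ = major_axis_slope_origin(x, 2.0 * (0.9 * x))
        assert b_exact == pytest.approx(1.8, rel=1e-10)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            major_axis_slope_origin([1.0, 2.0], [1.0, 2.0])
        with pytest.raises(ValueError, match="cross-products"):
            major_axis_slope_origin([1.0, -1.0, 1.0, -1.0], [1.0, 1.0, -1.0, -1.0])


class TestIdentitySlopeTest:
    def test_slope_one_gives_p_one(self):
        t, p = identity_slope_test(1.0, 0.2, 10)
        assert t == 0.0 and p == 1.0

    def test_three_se_away_large_n(self):
        _, p = identity_slope_test(1.3, 0.1, 10_000)
        assert p == pytest.approx(0.0027, abs=2e-4)

    def test_tiny_se_forces_rejection(self):
        _, p = identity_slope_test(1.05, 1e-12, 20)
        assert p < 1e-10


class TestVarianceDecomposition:
    def _survey_fit(self, spec):
        frame = samples_to_frame(generate_survey(spec))
        fit = fit_mixing_model(frame["carbon_fraction"], frame["bulk_density"])
        return frame, fit

    def test_percents_sum_to_100(self, survey_frame):
        fit = fit_mixing_model(survey_frame["carbon_fraction"], survey_frame["bulk_density"])
        vd = variance_decomposition(survey_frame["bulk_density"], fit.fitted, survey_frame)
        assert vd.rows["percent"].sum() == pytest.approx(100.0, abs=1e-6)
        assert (vd.rows["SS"] >= 0).all()

    def test_orthogonal_factors_get_zero_share(self, rng):
        # residuals identical within every factor level explain nothing
        y = np.tile([1.0, 1.2], 10)
        fitted = np.tile([1.0, 1.2], 10)  # zero residuals
        factors = pd.DataFrame({"instrument": ["a", "b"] * 10})
        vd = variance_decomposition(y, fitted, factors, factor_order=["instrument"])
        factor_row = vd.rows.set_index("source").loc["instrument"]
        assert factor_row["SS"] == pytest.approx(0.0, abs=1e-18)

    def test_injected_instrument_offset_dominates_factor_rows(self):
        spec = SurveySpec(instrument_offsets={"soil_probe": 0.12}, seed=3)
        frame, fit = self._survey_fit(spec)
        vd = variance_decomposition(frame["bulk_density"], fit.fitted, frame)
        rows = vd.rows.set_index("source")
        factor_rows = rows.drop(["mixing_model", "residual"])
        assert factor_rows["SS"].idxmax() == "instrument"
        assert rows.loc["instrument", "SS"] > 0

    def test_total_invariant_under_factor_permutation(self, survey_frame):
        fit = fit_mixing_model(survey_frame["carbon_fraction"], survey_frame["bulk_density"])
        a = variance_decomposition(
            survey_frame["bulk_density"], fit.fitted, survey_frame,
            factor_order=["instrument", "site"],
        )
        b = variance_decomposition(
            survey_frame["bulk_density"], fit.fitted, survey_frame,
            factor_order=["site", "instrument"],
        )
        assert a.ss_total == pytest.approx(b.ss_total)
        assert a.rows["SS"].sum() == pytest.approx(b.rows["SS"].sum(), rel=1e-9)


class TestReplicateConsistency:
    def test_identical_replicates_have_zero_within_share(self):
        values = np.repeat([1.0, 1.4, 0.8], 3)
        strata = np.repeat(["a", "b", "c"], 3)
        pct, df, ms = within_stratum_decomposition(values, strata)
        assert pct == pytest.approx(0.0, abs=1e-12)
        assert df == 6

    def test_identical_estimators_give_f_one(self):
        rng = np.random.default_rng(0)
        strata = np.repeat(list("abcdef"), 3)
        values = rng.normal(1.0, 0.2, strata.size)
        out = replicate_consistency_test(values, values, strata)
        assert out["F"] == pytest.approx(1.0)
        assert out["p"] == pytest.approx(1.0)

    def test_no_replicates_rejected(self):
        with pytest.raises(ValueError, match="replicates"):
            within_stratum_decomposition([1.0, 2.0, 3.0], ["a", "b", "c"])

    def test_noisier_estimator_detected(self):
        """Gravimetric noise at twice the carbon-induced noise: the variance
        ratio favours the carbon-based estimator in most surveys."""
        p = MixingParams(0.09, 1.75, 2.2)
        wins = 0
        n_sim = 100
        for seed in range(n_sim):
            spec = SurveySpec(
                cv_delta_measurement=0.10,
                sd_c_measurement=0.0,
                cv_c_measurement=0.05,  # gravimetric CV twice the carbon CV
                instrument_offsets={},
                site_offsets={},
                true_params=p,
                seed=seed,
            )
            frame = samples_to_frame(generate_survey(spec))
            strata = frame["site"] + "|" + frame["depth_label"]
            mixing_delta = bulk_density_from_carbon(
                frame["carbon_fraction"].to_numpy(), p
            )
            out = replicate_consistency_test(
                frame["bulk_density"].to_numpy(), mixing_delta, strata.to_numpy()
            )
            wins += (out["F"] > 1.0) and (out["p"] < 0.05)
        assert wins / n_sim > 0.8


class TestHeteroscedasticity:
    def test_constant_squared_residuals_score_zero(self):
        out = heteroscedasticity_test([0.1, -0.1, 0.1, -0.1], [1.0, 1.1, 1.2, 1.3])
        assert out["r"] == 0.0 and out["F"] == 0.0 and out["p"] == 1.0

    def test_funnel_noise_detected(self, rng):
        fitted = np.linspace(0.01, 0.4, 200)
        resid = rng.normal(0, 1, 200) * fitted  # SD grows with the fitted value
        out = heteroscedasticity_test(resid, fitted)
        assert out["r"] > 0.3
        assert out["p"] < 0.01

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            heteroscedasticity_test([0.1, -0.2, 0.3], [1.0, 1.0, 1.0])
        with pytest.raises(ValueError):
            heteroscedasticity_test([0.1, -0.2], [1.0, 1.1])


class TestComparisonPipeline:
    def test_survey_comparison_reports_near_identity_slopes(self, survey_frame):
        comps = compare_instruments(survey_frame)
        assert comps, "default survey must produce comparable instrument pairs"
        for c in comps:
            assert abs(c.pearson_r) <= 1.0
            assert c.ma_slope_b > 0
            assert c.n_pairs >= 3

    def test_matrix_shape(self, survey_frame):
        comps = compare_instruments(survey_frame)
        mat = comparison_matrix(comps)
        assert mat.shape[0] == mat.shape[1]
        assert (mat.to_numpy().diagonal() == "").all()
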