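"""Random-effects meta-regression: REML estimation, heterogeneity, predictions.

The fixture-based expectations come from two independent sources: the
published meta-analytic results the bundled table reproduces (loose, printed
precision) and a run of R's metafor on the identical harmonized values
(frozen below, tight tolerance), so the REML implementation is checked
against both the literature and a reference implementation.
"""

import dataclasses
import math

import numpy as np
import pytest

from discmeta.effects import DiscountIndex, EffectTable, Group, StudyEffect, TracerTarget
from discmeta.meta import (
    CI_Z,
    compare_models,
    predict_group,
    reml_fit,
    restricted_loglik,
)


def _effect(z, se, group=Group.HEALTHY, sid="s"):
    n = int(round(1.0 / se**2 + 3))
    return StudyEffect(
        study_id=sid, group=group, tracer_target=TracerTarget.D2_RECEPTOR,
        region="whole striatum", index=DiscountIndex.K, n=n,
        r=math.tanh(z), z=z, se=se,
    )


class TestDegenerateFits:
    def test_single_effect_intercept_only(self):
        fit = reml_fit(EffectTable([_effect(0.42, 0.3)]), "intercept")
        assert fit.coefficients[0] == pytest.approx(0.42, abs=1e-10)
        assert fit.tau2 == 0.0

    def test_two_identical_effects_no_heterogeneity(self):
        t = EffectTable([_effect(0.3, 0.25, sid="a"), _effect(0.3, 0.25, sid="b")])
        fit = reml_fit(t, "intercept")
        assert fit.coefficients[0] == pytest.approx(0.3, abs=1e-10)
        assert fit.tau2 == 0.0
        assert fit.QE == pytest.approx(0.0, abs=1e-20)

    def test_nonpositive_se_rejected(self):
        bad = dataclasses.replace(_effect(0.1, 0.2), se=0.0)
        with pytest.raises(ValueError):
            reml_fit(EffectTable([bad, _effect(0.2, 0.3)]), "intercept")


class TestFixedEffectReduction:
    def test_homogeneous_data_gives_inverse_variance_mean(self):
        z = np.array([0.10, 0.12, 0.11, 0.09, 0.08])
        se = np.array([0.30, 0.25, 0.35, 0.28, 0.33])
        t = EffectTable([_effect(zi, si, sid=f"s{i}") for i, (zi, si) in
                         enumerate(zip(z, se))])
        fit = reml_fit(t, "intercept")
        assert fit.tau2 == 0.0
        w = 1.0 / se**2
        assert fit.coefficients[0] == pytest.approx(float(w @ z / w.sum()), abs=1e-10)
        assert fit.coef_se[0] == pytest.approx(1.0 / math.sqrt(w.sum()), abs=1e-10)


class TestFixtureIntercept:
    def test_published_values(self, table1):
        fit = reml_fit(table1, "intercept")
        assert fit.coefficients[0] == pytest.approx(-0.167, abs=0.01)
        assert fit.coef_se[0] == pytest.approx(0.164, abs=0.01)
        assert fit.I2 == pytest.approx(84.7, abs=0.5)

    def test_metafor_cross_check(self, table1):
        fit = reml_fit(table1, "intercept")
        assert fit.coefficients[0] == pytest.approx(-0.1665825, abs=1e-5)
        assert fit.coef_se[0] == pytest.approx(0.1641080, abs=1e-5)
        assert fit.tau2 == pytest.approx(0.3013282, abs=1e-5)
        assert fit.QE == pytest.approx(64.5594105, abs=1e-4)
        assert fit.QM == pytest.approx(1.0303840, abs=1e-4)
        assert fit.I2 == pytest.approx(84.7395273, abs=1e-3)
        assert fit.loglik_reml == pytest.approx(-12.3024085, abs=1e-4)
        assert fit.aic == pytest.approx(28.6048170, abs=1e-3)


class TestFixtureGroupModel:
    def test_published_values(self, table1):
        fit = reml_fit(table1, "group")
        coef = dict(zip(fit.coef_names, fit.coefficients))
        se = dict(zip(fit.coef_names, fit.coef_se))
        assert coef["intercept"] == pytest.approx(-0.138, abs=0.01)
        assert coef["group[addiction]"] == pytest.approx(-0.616, abs=0.01)
        assert coef["group[other_psychopathology]"] == pytest.approx(0.793, abs=0.01)
        assert se["intercept"] == pytest.approx(0.110, abs=0.01)
        assert se["group[addiction]"] == pytest.approx(0.202, abs=0.01)
        assert se["group[other_psychopathology]"] == pytest.approx(0.199, abs=0.01)
        assert fit.I2 == pytest.approx(31.8, abs=0.5)
        assert fit.QM == pytest.approx(35.7, abs=0.5)

    def test_metafor_cross_check(self, table1):
        fit = reml_fit(table1, "group")
        assert fit.coefficients == pytest.approx(
            [-0.1382523, -0.6160037, 0.7933859], abs=1e-5
        )
        assert fit.coef_se == pytest.approx(
            [0.1095629, 0.2018756, 0.1987682], abs=1e-5
        )
        assert fit.tau2 == pytest.approx(0.02742467, abs=1e-5)
        assert fit.QM == pytest.approx(35.72791, abs=1e-3)
        assert fit.QE == pytest.approx(16.29561, abs=1e-4)
        assert fit.I2 == pytest.approx(31.7645, abs=1e-3)
        assert fit.aic == pytest.approx(14.26289, abs=1e-3)

    def test_moderators_absorb_heterogeneity(self, table1):
        m0 = reml_fit(table1, "intercept")
        m1 = reml_fit(table1, "group")
        assert m1.QM > m0.QM
        assert m1.QE < m0.QE
        assert m1.tau2 < m0.tau2

    def test_interaction_model_metafor_cross_check(self, table1):
        fit = reml_fit(table1, "group_x_tracer")
        coef = dict(zip(fit.coef_names, fit.coefficients))
        assert coef["intercept"] == pytest.approx(-0.08755106, abs=1e-5)
        assert coef["group[addiction]"] == pytest.approx(-0.67553459, abs=1e-5)
        assert coef["group[other_psychopathology]"] == pytest.approx(0.72038425, abs=1e-5)
        assert coef["tracer[da_synthesis]"] == pytest.approx(-0.47924173, abs=1e-5)
        assert coef["tracer[dat]"] == pytest.approx(-0.03430701, abs=1e-5)
        assert coef["group[other_psychopathology]:tracer[da_synthesis]"] == pytest.approx(
            0.60458229, abs=1e-5
        )
        assert fit.I2 == pytest.approx(37.14873, abs=1e-3)
        assert fit.aic == pytest.approx(19.84021, abs=1e-3)


class TestFitInvariants:
    @pytest.mark.parametrize("formula", ["intercept", "group", "tracer", "group_x_tracer"])
    def test_structure(self, table1, formula):
        fit = reml_fit(table1, formula)
        assert fit.tau2 >= 0
        assert 0 <= fit.I2 <= 100
        assert np.allclose(fit.coef_cov, fit.coef_cov.T)
        assert np.all(np.linalg.eigvalsh(fit.coef_cov) > -1e-12)
        assert np.allclose(np.diag(fit.coef_cov), fit.coef_se**2, atol=1e-10)
        assert fit.aic == pytest.approx(
            -2 * fit.loglik_reml + 2 * (fit.p_fixed + 1), abs=1e-10
        )


def grid_search_tau2(z, v, X, lo=0.0, hi=2.0, passes=3, points=2001):
    """Independent oracle: iteratively refined dense grid over the restricted
    likelihood profile."""
    for _ in range(passes):
        grid = np.linspace(lo, hi, points)
        lls = [restricted_loglik(t2, z, v, X) for t2 in grid]
        i = int(np.argmax(lls))
        step = grid[1] - grid[0]
        lo, hi = max(0.0, grid[i] - step), grid[i] + step
    return grid[i]


class TestTau2Oracle:
    @pytest.mark.parametrize("formula", ["intercept", "group"])
    def test_reml_matches_dense_grid_search(self, table1, formula):
        fit = reml_fit(table1, formula)
        X = table1.design(formula).matrix
        oracle = grid_search_tau2(table1.z, table1.se**2, X)
        assert fit.tau2 == pytest.approx(oracle, abs=1e-6)


class TestPredictions:
    def test_published_group_correlations(self, table1):
        fit = reml_fit(table1, "group")
        expected = {
            "healthy": (-0.137, -0.339, 0.076),
            "addiction": (-0.638, -0.796, -0.399),
            "other_psychopathology": (0.575, 0.319, 0.753),
        }
        for group, (r, lo, hi) in expected.items():
            p = predict_group(fit, group)
            assert p.r_hat == pytest.approx(r, abs=0.01)
            assert p.r_ci[0] == pytest.approx(lo, abs=0.01)
            assert p.r_ci[1] == pytest.approx(hi, abs=0.01)
            assert -1 < p.r_ci[0] < p.r_hat < p.r_ci[1] < 1

    def test_prediction_consistency_with_coefficients(self, table1):
        fit = reml_fit(table1, "group")
        p = predict_group(fit, Group.ADDICTION)
        coef = dict(zip(fit.coef_names, fit.coefficients))
        assert p.z_hat == pytest.approx(
            coef["intercept"] + coef["group[addiction]"], abs=1e-12
        )
        assert p.r_hat == pytest.approx(math.tanh(p.z_hat), abs=1e-12)

    def test_zero_coefficients_give_zero_correlation(self):
        t = EffectTable([_effect(0.0, 0.3, sid=f"s{i}") for i in range(5)])
        fit = reml_fit(t, "intercept")
        p = predict_group(fit, Group.HEALTHY)
        assert p.r_hat == pytest.approx(0.0, abs=1e-10)

    def test_ci_shrinks_as_precision_grows(self, table1):
        widths = []
        for scale in (1.0, 0.7, 0.4):
            scaled = EffectTable(
                [dataclasses.replace(e, se=e.se * scale) for e in table1.effects]
            )
            p = predict_group(reml_fit(scaled, "group"), Group.ADDICTION)
            widths.append(p.z_ci[1] - p.z_ci[0])
        assert widths[0] > widths[1] > widths[2]

    def test_group_absent_from_design(self, table1):
        healthy_only = EffectTable(
            [e for e in table1.effects if e.group == Group.HEALTHY]
        )
        fit = reml_fit(healthy_only, "group")
        with pytest.raises(ValueError, match="absent"):
            predict_group(fit, Group.ADDICTION)

    def test_non_group_design_rejected(self, table1):
        fit = reml_fit(table1, "tracer")
        with pytest.raises(ValueError, match="ambiguous"):
            predict_group(fit, Group.HEALTHY)

    def test_ci_uses_fixed_multiplier(self, table1):
        fit = reml_fit(table1, "group")
        p = predict_group(fit, Group.HEALTHY)
        half = CI_Z * fit.coef_se[0]
        assert p.z_ci == pytest.approx((p.z_hat - half, p.z_hat + half), abs=1e-12)


class TestModelComparison:
    def test_fixture_ranking(self, table1):
        fits = [reml_fit(table1, f) for f in
                ("intercept", "group", "tracer", "group_x_tracer")]
        ranking = compare_models(fits)
        assert [r["formula"] for r in ranking] == [
            "group", "group_x_tracer", "tracer", "intercept"
        ]
        assert ranking[0]["delta_aic"] == 0.0
        assert all(r["reml_caveat"] for r in ranking)

    def test_identical_fits_tie(self, table1):
        fit = reml_fit(table1, "group")
        ranking = compare_models([fit, fit])
        assert ranking[1]["delta_aic"] == 0.0

    def test_single_fit_rejected(self, table1):
        with pytest.raises(ValueError):
            compare_models([reml_fit(table1, "group")])

    def test_different_tables_rejected(self, table1):
        other = EffectTable(table1.effects[:10])
        with pytest.raises(ValueError, match="same effect table"):
            compare_models([reml_fit(table1, "group"), reml_fit(other, "group")])


class TestSerialization:
    def test_report_round_trips_to_json(self, table1):
        import json

        fit = reml_fit(table1, "group_x_tracer")
        report = json.loads(json.dumps(fit.to_dict()))
        assert report["k_effects"] == 14
        assert len(report["coefficients"]) == fit.p_fixed
        assert report["dropped_columns"]
        assert report["converged"] is True
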