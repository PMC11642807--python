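"""Combined-model regression, beta ratios, interaction slopes and screens."""

import numpy as np
import pandas as pd
import pytest

from tauspread import (UnfittableError, ValidationError, beta_ratios,
                       fit_combined, fit_tdt_interaction, racine_auc,
                       regional_correlation_screen, simulate_cohort)
from tauspread.regression import CombinedModelFit, log10_eps, zscore
from tauspread.synthetic import GroupBetas, make_ground_truth


@pytest.fixture(scope="module")
def preds_small():
    gt = make_ground_truth(n_regions=60, rng_seed=21)
    return gt, gt.predictions()


class TestFitCombined:
    def test_exact_anterograde_regressor(self, preds_small):
        _, preds = preds_small
        fit = fit_combined(preds["anterograde"], preds)
        assert fit.betas["anterograde"] == pytest.approx(1.0, abs=1e-8)
        assert fit.betas["retrograde"] == pytest.approx(0.0, abs=1e-8)
        assert fit.betas["euclidean"] == pytest.approx(0.0, abs=1e-8)
        assert fit.r == pytest.approx(1.0, abs=1e-10)

    def test_orthogonal_response_gives_zero_betas(self, preds_small):
        _, preds = preds_small
        X = np.column_stack([zscore(log10_eps(preds[m]))
                             for m in ("anterograde", "retrograde", "euclidean")])
        rng = np.random.default_rng(2)
        y = rng.normal(size=X.shape[0])
        # project out every predictor (and the mean)
        Q, _ = np.linalg.qr(np.column_stack([np.ones(len(y)), X]))
        y_orth = y - Q @ (Q.T @ y)
        fit = fit_combined(y_orth - y_orth.min() + 1.0,
                           {m: log10_eps(preds[m]) for m in preds},
                           transform=False)
        # response was orthogonalised before the affine shift; betas vanish
        for b in fit.betas.values():
            assert abs(b) < 1e-8

    def test_single_predictor_beta_equals_pearson_r(self):
        rng = np.random.default_rng(3)
        x = rng.lognormal(0, 1, 80)
        y = rng.lognormal(0, 1, 80)
        fit = fit_combined(y, {"anterograde": x})
        r = np.corrcoef(log10_eps(x), log10_eps(y))[0, 1]
        assert fit.betas["anterograde"] == pytest.approx(r, abs=1e-10)

    def test_standardized_betas_scale_invariant(self, preds_small):
        _, preds = preds_small
        rng = np.random.default_rng(4)
        y = preds["retrograde"] * np.exp(rng.normal(0, 0.3, len(preds["retrograde"])))
        base = fit_combined(y, preds)
        scaled = fit_combined(y * 37.0,
                              {"anterograde": preds["anterograde"] * 0.01,
                               "retrograde": preds["retrograde"],
                               "euclidean": preds["euclidean"]})
        for m in base.betas:
            assert scaled.betas[m] == pytest.approx(base.betas[m], abs=1e-9)

    def test_constant_predictor_rejected(self):
        rng = np.random.default_rng(5)
        y = rng.lognormal(0, 1, 30)
        with pytest.raises(ValidationError, match="constant"):
            fit_combined(y, {"anterograde": np.ones(30)})

    def test_too_few_rows_rejected(self):
        with pytest.raises(UnfittableError):
            fit_combined(np.array([1.0, 2.0]),
                         {"anterograde": np.array([1.0, 2.0]),
                          "retrograde": np.array([2.0, 1.0]),
                          "euclidean": np.array([1.5, 1.0])})


class TestBetaRatios:
    def _fit(self, a, r, e):
        return CombinedModelFit(
            betas={"anterograde": a, "retrograde": r, "euclidean": e},
            coefs={}, intercept=0.0, residuals=np.zeros(3), r=1.0,
            n_regions=3, model_tag="bidirectional_euclidean")

    def test_arithmetic(self):
        ratios = beta_ratios(self._fit(0.6, 0.3, 0.2))
        assert ratios["a:r"] == pytest.approx(2.0)
        assert ratios["e:r"] == pytest.approx(2.0 / 3.0)
        assert ratios["a:e"] == pytest.approx(3.0)

    def test_zero_denominator_flagged(self):
        ratios = beta_ratios(self._fit(0.6, 0.0, 0.2))
        assert ratios["a:r"] is None
        assert ratios["e:r"] is None
        assert ratios["a:e"] == pytest.approx(3.0)

    def test_equal_betas_all_one(self):
        ratios = beta_ratios(self._fit(0.4, 0.4, 0.4))
        assert all(v == pytest.approx(1.0) for v in ratios.values())


@pytest.fixture(scope="module")
def fitted():
    betas = {
        ("WT", "Sal"): GroupBetas(a=0.2, r=0.6, e=0.2, t=0.1),
        ("WT", "PTZ"): GroupBetas(a=0.2, r=0.6, e=0.2, t=0.6),
        ("5X", "Sal"): GroupBetas(a=0.2, r=0.6, e=0.2, t=0.1),
        ("5X", "PTZ"): GroupBetas(a=0.2, r=0.6, e=0.2, t=0.6),
    }
    gt = make_ground_truth(n_regions=80, rng_seed=31, betas=betas)
    cohort = simulate_cohort(gt, 8, rng_seed=32)
    return fit_tdt_interaction(cohort, gt.predictions(), gt.regions, "WT")


class TestTdtInteraction:
    def test_simple_slopes_match_coefficients(self, fitted):
        fit, slopes, _ = fitted
        by_group = {s.group: s for s in slopes}
        assert by_group["Sal"].slope == pytest.approx(fit.coefs["tdt"], abs=1e-12)
        assert by_group["PTZ"].slope == pytest.approx(
            fit.coefs["tdt"] + fit.coefs["tdt_x_treatment"], abs=1e-12)

    def test_partial_residuals_reproduce_simple_slopes(self, fitted):
        _, slopes, partial = fitted
        by_group = {s.group: s for s in slopes}
        for group in ("Sal", "PTZ"):
            sub = partial.loc[partial["treatment"] == ("PTZ" if group == "PTZ" else "Sal")]
            slope = np.polyfit(sub["tdt_z"], sub["partial_residual"], 1)[0]
            assert slope == pytest.approx(by_group[group].slope, abs=1e-10)

    def test_detects_ptz_specific_slope(self, fitted):
        _, slopes, _ = fitted
        by_group = {s.group: s for s in slopes}
        assert by_group["PTZ"].p < 0.05
        assert by_group["PTZ"].slope > by_group["Sal"].slope

    def test_constant_tdt_rejected(self, preds_small):
        gt, preds = preds_small
        cohort = simulate_cohort(gt, 6, rng_seed=33)
        cohort["tdt"] = 1.0
        with pytest.raises(ValidationError, match="tdt"):
            fit_tdt_interaction(cohort, preds, gt.regions, "WT")

    def test_missing_treatment_level_rejected(self, preds_small):
        gt, preds = preds_small
        cohort = simulate_cohort(gt, 6, rng_seed=34)
        only_sal = cohort.loc[cohort["treatment"] == "Sal"]
        with pytest.raises(ValidationError, match="both treatments"):
            fit_tdt_interaction(only_sal, preds, gt.regions, "WT")

    def test_mostly_missing_tdt_rejected(self, preds_small):
        gt, preds = preds_small
        cohort = simulate_cohort(gt, 6, rng_seed=35)
        dropped = set(list(gt.regions)[: int(0.6 * len(gt.regions))])
        cohort.loc[cohort["region_id"].isin(dropped), "tdt"] = np.nan
        with pytest.raises(ValidationError, match="missing"):
            fit_tdt_interaction(cohort, preds, gt.regions, "WT")


class TestCorrelationScreen:
    def _cohort(self, values_by_mouse, region="R1"):
        rows = [{"mouse_id": m, "genotype": "WT", "treatment": "Sal",
                 "region_id": region, "pathology": v, "tdt": np.nan}
                for m, v in values_by_mouse.items()]
        return pd.DataFrame(rows)

    def test_perfect_correlation(self):
        vals = {f"m{i}": float(i + 1) for i in range(12)}
        screen = regional_correlation_screen(self._cohort(vals), vals)
        row = screen.iloc[0]
        assert row["r"] == pytest.approx(1.0)
        assert row["p"] < 1e-6
        assert row["n"] == 12

    def test_constant_covariate_rejected(self):
        vals = {f"m{i}": float(i) for i in range(5)}
        with pytest.raises(ValidationError, match="constant"):
            regional_correlation_screen(self._cohort(vals),
                                        {m: 1.0 for m in vals})

    def test_small_regions_skipped(self):
        vals = {"m0": 1.0, "m1": 2.0}
        screen = regional_correlation_screen(
            self._cohort(vals), {"m0": 0.1, "m1": 0.9})
        assert screen.empty


class TestRacineAuc:
    def test_all_zero(self):
        assert racine_auc([0] * 15) == 0.0

    def test_constant_five(self):
        assert racine_auc([5] * 15) == 75.0

    def test_ramp_profile(self):
        scores = [0, 1, 2, 3, 4, 5, 5, 5, 4, 3, 2, 1, 0, 0, 0]
        assert racine_auc(scores) == 35.0

    def test_wrong_length_rejected(self):
        with pytest.raises(ValidationError, match="15"):
            racine_auc([1] * 14)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError, match="0..6"):
            racine_auc([7] + [0] * 14)

    def test_trapezoid_option(self):
        assert racine_auc([5] * 15, rule="trapezoid") == pytest.approx(70.0)
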