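"""Quadratic surface fitting, ANOVA identities and adequacy diagnostics."""

import numpy as np
import pandas as pd
import pytest

from extractopt.design import TABLE1_FACTORS, DesignTable, FactorSpec, build_bbd
from extractopt.rsm import (
    adequacy,
    anova,
    coef_confint,
    fit_quadratic,
    model_matrix,
    predict,
    surface_grid,
    term_names,
)
from extractopt.synthetic import RESPONSE_NAMES, GroundTruth, generate_study

CENTER = {"ethanol_pct": 50.0, "time_min": 35.0, "temperature_C": 40.0, "frequency_kHz": 35.0}


def _random_truth(rng, factors, sd=0.0, seed=0):
    terms = term_names([f.name for f in factors])
    coef = pd.DataFrame({"y": rng.normal(0, 2, len(terms))}, index=terms)
    return GroundTruth(coef=coef, noise_sd={"y": sd}, seed=seed)


class TestFit:
    def test_noiseless_quadratic_recovered_exactly(self, factors):
        truth = _random_truth(np.random.default_rng(7), factors)
        design, responses = generate_study(factors, truth)
        model = fit_quadratic(design, responses["y"], "y")
        np.testing.assert_allclose(
            model.coef.values, truth.coef["y"].values, atol=1e-8
        )

    def test_center_prediction_equals_intercept_under_ordinal(
        self, table1, observed_responses
    ):
        design, *_ = table1
        model = fit_quadratic(
            design.with_scheme("ordinal"), observed_responses["tpc"], "tpc"
        )
        pred = predict(model, {k: [v] for k, v in CENTER.items()})
        assert pred[0] == pytest.approx(model.coef["Intercept"])

    @pytest.mark.parametrize("resp", RESPONSE_NAMES)
    def test_fitted_values_reproduce_published_predictions(self, table1, resp):
        """The affine-coded full quadratic reproduces the published predicted
        column of every response to within print rounding."""
        design, observed, rsm_pred, _ = table1
        model = fit_quadratic(design, observed[resp], resp)
        fitted = predict(model, design.actual)
        assert np.max(np.abs(fitted - rsm_pred[resp].values)) <= 0.05

    def test_mismatched_response_length_rejected(self, table1):
        design, *_ = table1
        with pytest.raises(ValueError, match="length"):
            fit_quadratic(design, np.arange(10.0))

    def test_too_few_runs_rejected(self, factors):
        design = build_bbd(factors, n_center=3)
        small = DesignTable(factors, design.actual.iloc[:15])
        with pytest.raises(ValueError):
            fit_quadratic(small, np.arange(15.0))

    def test_full_model_r2_dominates_submodels(self, table1, observed_responses):
        design, *_ = table1
        y = observed_responses["tpc"].values
        X = model_matrix(design.coded())
        full_sse = float(((y - X.values @ np.linalg.lstsq(X.values, y, rcond=None)[0]) ** 2).sum())
        for drop in ["ethanol_pct^2", "time_min:temperature_C", "frequency_kHz"]:
            Xr = X.drop(columns=drop).values
            sse = float(((y - Xr @ np.linalg.lstsq(Xr, y, rcond=None)[0]) ** 2).sum())
            assert sse >= full_sse - 1e-9


def test_affine_relabelling_of_units_leaves_fit_invariant(table1, observed_responses):
    """Rescaling a factor's physical units is absorbed by the coding, so
    design-point predictions are unchanged."""
    design, *_ = table1
    rescaled = list(TABLE1_FACTORS)
    rescaled[2] = FactorSpec(
        "temperature_C", "degF", tuple(t * 9 / 5 + 32 for t in (20.0, 40.0, 60.0))
    )
    actual = design.actual.copy()
    actual["temperature_C"] = actual["temperature_C"] * 9 / 5 + 32
    design_f = DesignTable(tuple(rescaled), actual, "affine")
    y = observed_responses["tpc"]
    m_c = fit_quadratic(design, y, "tpc")
    m_f = fit_quadratic(design_f, y, "tpc")
    np.testing.assert_allclose(
        predict(m_c, design.actual), predict(m_f, design_f.actual), atol=1e-8
    )


@pytest.fixture(scope="module")
def tpc_report(table1, observed_responses):
    design, *_ = table1
    model = fit_quadratic(design, observed_responses["tpc"], "tpc")
    return anova(model, design, observed_responses["tpc"])


class TestAnova:
    def test_sums_of_squares_are_additive(self, tpc_report):
        t = tpc_report.table
        assert t.loc["Model", "SS"] + t.loc["Residual", "SS"] == pytest.approx(
            t.loc["Total", "SS"]
        )
        assert t.loc["Lack of fit", "SS"] + t.loc["Pure error", "SS"] == pytest.approx(
            t.loc["Residual", "SS"]
        )
        assert (
            t.loc["Lack of fit", "df"] + t.loc["Pure error", "df"]
            == t.loc["Residual", "df"]
        )

    def test_tpc_main_effect_significance_pattern(self, tpc_report):
        t = tpc_report.table
        assert t.loc["ethanol_pct", "p"] < 0.05
        assert t.loc["time_min", "p"] < 0.05
        assert t.loc["temperature_C", "p"] < 0.05
        assert t.loc["frequency_kHz", "p"] > 0.05

    @pytest.mark.parametrize("resp", RESPONSE_NAMES)
    def test_lack_of_fit_nonsignificant_for_all_responses(
        self, table1, observed_responses, resp
    ):
        design, *_ = table1
        model = fit_quadratic(design, observed_responses[resp], resp)
        rep = anova(model, design, observed_responses[resp])
        assert rep.table.loc["Lack of fit", "p"] > 0.05

    def test_lof_rows_absent_without_center_replicates(self, factors):
        design = build_bbd(factors, n_center=3)
        keep = ~design.is_center | (design.actual.index == 25)
        trimmed = DesignTable(factors, design.actual[keep])
        rng = np.random.default_rng(0)
        y = rng.normal(50, 5, trimmed.n_runs)
        model = fit_quadratic(trimmed, y)
        rep = anova(model, trimmed, y)
        assert "Lack of fit" not in rep.table.index


class TestAdequacy:
    @pytest.mark.parametrize("resp", RESPONSE_NAMES)
    def test_fits_meet_quality_thresholds(self, table1, observed_responses, resp):
        design, *_ = table1
        model = fit_quadratic(design, observed_responses[resp], resp)
        r2, adj_r2, cv, ap = adequacy(model, design, observed_responses[resp])
        assert 0.8 <= r2 <= 1.0
        assert adj_r2 <= r2
        assert ap > 4.0

    def test_perfect_fit_degenerate_values(self, factors):
        truth = _random_truth(np.random.default_rng(3), factors)
        design, responses = generate_study(factors, truth)
        model = fit_quadratic(design, responses["y"], "y")
        r2, _, cv, ap = adequacy(model, design, responses["y"])
        assert r2 == pytest.approx(1.0)
        assert cv == pytest.approx(0.0, abs=1e-6)
        assert np.isinf(ap)


def test_confidence_interval_coverage_of_true_coefficients(factors):
    """95% OLS intervals cover the planted coefficients at the nominal rate
    (binomially, 95% +- 4 pp over 200 seeded replicates x 15 terms)."""
    rng = np.random.default_rng(11)
    terms = term_names([f.name for f in factors])
    beta_true = pd.DataFrame({"y": rng.normal(0, 2, len(terms))}, index=terms)
    covered = total = 0
    for rep in range(200):
        truth = GroundTruth(coef=beta_true, noise_sd={"y": 1.5}, seed=rep)
        design, responses = generate_study(factors, truth)
        model = fit_quadratic(design, responses["y"], "y")
        ci = coef_confint(model, design, alpha=0.05)
        hit = (ci["lower"] <= beta_true["y"]) & (beta_true["y"] <= ci["upper"])
        covered += int(hit.sum())
        total += len(hit)
    assert 0.91 <= covered / total <= 0.99


@pytest.fixture(scope="module")
def tpc_model(table1, observed_responses):
    design, *_ = table1
    return fit_quadratic(design, observed_responses["tpc"], "tpc")


class TestSurfaceGrid:
    def test_grid_corners_match_direct_predictions(self, tpc_model):
        ax_a, ax_b, Z = surface_grid(
            tpc_model, ("time_min", "temperature_C"),
            {"ethanol_pct": 50.0, "frequency_kHz": 35.0}, resolution=5,
        )
        for i, j in [(0, 0), (0, -1), (-1, 0), (-1, -1)]:
            direct = predict(
                tpc_model,
                {
                    "time_min": [ax_a[j]], "temperature_C": [ax_b[i]],
                    "ethanol_pct": [50.0], "frequency_kHz": [35.0],
                },
            )[0]
            assert Z[i, j] == pytest.approx(direct)

    def test_grid_shape_and_finiteness(self, tpc_model):
        _, _, Z = surface_grid(
            tpc_model, ("time_min", "temperature_C"),
            {"ethanol_pct": 50.0, "frequency_kHz": 35.0}, resolution=50,
        )
        assert Z.shape == (50, 50) and np.all(np.isfinite(Z))

    def test_grid_argmax_agrees_with_brute_force(self, tpc_model):
        res = 101
        ax_a, ax_b, Z = surface_grid(
            tpc_model, ("time_min", "temperature_C"),
            {"ethanol_pct": 50.0, "frequency_kHz": 35.0}, resolution=res,
        )
        i, j = np.unravel_index(np.argmax(Z), Z.shape)
        # independent brute force: evaluate the polynomial pointwise
        best = (-np.inf, None)
        for bi, tb in enumerate(ax_b):
            pts = pd.DataFrame(
                {
                    "time_min": ax_a, "temperature_C": np.full(res, tb),
                    "ethanol_pct": np.full(res, 50.0),
                    "frequency_kHz": np.full(res, 35.0),
                }
            )
            vals = predict(tpc_model, pts)
            k = int(np.argmax(vals))
            if vals[k] > best[0]:
                best = (vals[k], (bi, k))
        assert (i, j) == best[1]

    def test_varying_a_fixed_factor_rejected(self, tpc_model):
        with pytest.raises(ValueError, match="also appears"):
            surface_grid(
                tpc_model, ("time_min", "temperature_C"),
                {"time_min": 35.0, "ethanol_pct": 50.0, "frequency_kHz": 35.0},
            )
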