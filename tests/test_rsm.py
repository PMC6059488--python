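"""Quadratic surface fitting, ANOVA bookkeeping and model reduction."""

import numpy as np
import pytest

from qpcropt import (
    FactorSpec,
    QuadraticModel,
    SingularDesignError,
    adequate_precision,
    anova,
    default_spec,
    fit_quadratic,
    generate_ccd,
    reduce_model,
    simulate_response,
)
from qpcropt.rsm import expand_quadratic, term_labels
from qpcropt.synthetic import FACTOR_NAMES


def _two_factor_fit(seed=5, noise=0.3):
    fs = [FactorSpec("A", 1.0, 0.3), FactorSpec("B", 2.0, 0.5)]
    d = generate_ccd(fs, n_center=4, alpha="rotatable")
    rng = np.random.default_rng(seed)
    y = (
        20.0
        + 0.8 * d.coded[:, 0]
        - 1.2 * d.coded[:, 1]
        + 0.5 * d.coded[:, 0] ** 2
        + rng.normal(0, noise, d.n_runs)
    )
    return d, y


class TestFitQuadratic:
    def test_noiseless_data_recovers_coefficients_exactly(self, design50, rsv_model):
        y = np.asarray(rsv_model.predict(design50.coded))
        m = fit_quadratic(design50, y)
        assert np.allclose(m.coef_vector(), rsv_model.coef_vector(), atol=1e-8)
        assert m.r_squared() == pytest.approx(1.0)

    def test_constant_response(self, design50):
        m = fit_quadratic(design50, np.full(50, 24.5))
        assert m.intercept == pytest.approx(24.5)
        assert np.allclose(m.coef_vector()[1:], 0.0, atol=1e-10)

    def test_monte_carlo_bias_and_standard_errors(self, design50, rsv_model):
        """Coefficient estimates are unbiased with spread matching OLS theory."""
        sigma = 0.2
        z = expand_quadratic(design50.coded)
        cov = np.linalg.inv(z.T @ z) * sigma**2  # analytic coefficient covariance
        analytic_se = np.sqrt(np.diag(cov))
        reps = 30
        estimates = np.empty((reps, z.shape[1]))
        for r in range(reps):
            spec = default_spec("RSV", noise_sd=sigma, replicates_per_run=1, seed=100 + r)
            y = simulate_response(design50, spec)["ct_mean"].to_numpy()
            estimates[r] = fit_quadratic(design50, y).coef_vector()
        bias = estimates.mean(axis=0) - rsv_model.coef_vector()
        # mean of 30 draws: sd of the mean is analytic_se/sqrt(30); allow 4 sd
        assert np.all(np.abs(bias) < 4 * analytic_se / np.sqrt(reps))
        empirical_se = estimates.std(axis=0, ddof=1)
        assert np.all(empirical_se / analytic_se > 0.6)
        assert np.all(empirical_se / analytic_se < 1.7)

    def test_response_length_mismatch(self, design50):
        with pytest.raises(ValueError):
            fit_quadratic(design50, np.zeros(10))

    def test_rank_deficiency_names_collinear_terms(self):
        # no axial points and one center: pure-quadratic columns are confounded
        fs = [FactorSpec("A", 1.0, 0.3), FactorSpec("B", 2.0, 0.5)]
        d = generate_ccd(fs, n_center=4, alpha="rotatable")
        d.frame = d.frame[d.frame["point_type"] != "axial"].reset_index(drop=True)
        with pytest.raises(SingularDesignError, match="\\^2"):
            fit_quadratic(d, np.arange(float(d.n_runs)))


class TestAnova:
    def test_degrees_of_freedom_bookkeeping(self, design50, noisy_fit):
        model, y = noisy_fit
        at = anova(model, design50, y)
        assert at.row("Model")["df"] == 20
        assert at.row("Residual")["df"] == 29
        assert at.row("Pure Error")["df"] == 7  # 8 center replicates
        assert at.row("Lack of Fit")["df"] == 22
        assert at.row("Cor Total")["df"] == 49

    def test_sum_of_squares_additivity(self, design50, noisy_fit):
        model, y = noisy_fit
        at = anova(model, design50, y)
        assert at.row("Model")["SS"] + at.row("Residual")["SS"] == pytest.approx(
            at.row("Cor Total")["SS"], abs=1e-8
        )
        assert at.row("Lack of Fit")["SS"] + at.row("Pure Error")["SS"] == pytest.approx(
            at.row("Residual")["SS"], abs=1e-8
        )
        assert (
            at.row("Lack of Fit")["df"] + at.row("Pure Error")["df"]
            == at.row("Residual")["df"]
        )

    def test_exact_fit_is_flagged_infinite(self, design50, rsv_model):
        y = np.asarray(rsv_model.predict(design50.coded))
        m = fit_quadratic(design50, y)
        at = anova(m, design50, y)
        assert np.isinf(at.row("Model")["F"])
        assert at.row("D")["P"] == 0.0

    def test_against_independent_linear_model_oracle(self):
        """SS/F/P per term agree with statsmodels OLS to 1e-6.

        For one-df terms the partial SS equals t^2 * MS_residual, so the
        general-purpose regression t-tests are an independent route to the
        same table.
        """
        sm = pytest.importorskip("statsmodels.api")
        d, y = _two_factor_fit()
        m = fit_quadratic(d, y)
        at = anova(m, d, y)
        res = sm.OLS(y, expand_quadratic(d.coded)).fit()
        for j, label in enumerate(term_labels(d.factor_names), start=1):
            row = at.row(label)
            assert row["SS"] == pytest.approx(
                float(res.tvalues[j] ** 2 * res.mse_resid), abs=1e-6
            )
            assert row["F"] == pytest.approx(float(res.tvalues[j] ** 2), abs=1e-6)
            assert row["P"] == pytest.approx(float(res.pvalues[j]), abs=1e-6)
        assert m.coef_vector() == pytest.approx(res.params, abs=1e-8)

    def test_no_replicates_warns_and_omits_split(self):
        fs = [FactorSpec("A", 1.0, 0.3), FactorSpec("B", 2.0, 0.5)]
        d = generate_ccd(fs, n_center=1, alpha="rotatable")
        rng = np.random.default_rng(0)
        y = rng.normal(20, 1, d.n_runs)
        m = fit_quadratic(d, y)
        with pytest.warns(UserWarning, match="pure error undefined"):
            at = anova(m, d, y)
        assert not at.pure_error_defined
        assert "Lack of Fit" not in set(at.table["Source"])

    def test_linear_partial_ss_invariant_on_orthogonal_design(self, design50):
        """On orthogonal coded columns a linear term's partial SS is its
        marginal SS, independent of the other linear terms."""
        rng = np.random.default_rng(9)
        y = 22 - 1.5 * design50.coded[:, 3] + rng.normal(0, 0.3, 50)
        m = fit_quadratic(design50, y)
        at = anova(m, design50, y)
        x_d = design50.coded[:, 3]
        marginal_ss = float((x_d @ y) ** 2 / (x_d @ x_d))
        assert at.row("D")["SS"] == pytest.approx(marginal_ss, rel=1e-10)


class TestAdequatePrecision:
    def test_strong_signal_far_exceeds_threshold(self, design50):
        # effect-to-noise ratio ~50
        spec = default_spec("RSV", noise_sd=0.05, seed=2)
        y = simulate_response(design50, spec)["ct_mean"].to_numpy()
        m = fit_quadratic(design50, y)
        assert adequate_precision(m, design50) > 100

    def test_pure_noise_is_an_order_of_magnitude_smaller(self, design50):
        """With a flat true surface the signal-to-noise ratio collapses.

        The ratio's null distribution straddles the conventional cut-off 4
        (fitted-range and residual scale are both noise-driven), so the
        check is separation from the signal case plus quantile sanity, not
        an all-seeds bound.
        """
        flat = QuadraticModel.from_coefficients(FACTOR_NAMES, {"intercept": 23.0})
        aps = []
        for s in range(40):
            from qpcropt import SyntheticSurfaceSpec

            spec = SyntheticSurfaceSpec(true_model=flat, noise_sd=0.3, seed=s)
            y = simulate_response(design50, spec)["ct_mean"].to_numpy()
            aps.append(adequate_precision(fit_quadratic(design50, y), design50))
        aps = np.array(aps)
        assert np.median(aps) < 8
        assert np.percentile(aps, 25) < 4.5
        assert aps.max() < 15  # nowhere near the strong-signal regime

    def test_doubling_signal_doubles_numerator(self, design50, noisy_fit):
        model, y = noisy_fit
        ap1 = adequate_precision(model, design50)
        doubled = QuadraticModel(
            factor_names=model.factor_names,
            intercept=model.intercept,
            linear=2 * model.linear,
            quadratic=2 * model.quadratic,
            interaction=2 * model.interaction,
            residual_ms=model.residual_ms,
        )
        assert adequate_precision(doubled, design50) == pytest.approx(2 * ap1)

    def test_zero_residual_reports_infinite(self, design50, rsv_model):
        y = np.asarray(rsv_model.predict(design50.coded))
        m = fit_quadratic(design50, y)
        assert np.isinf(adequate_precision(m, design50))


class TestReduceModel:
    def test_threshold_one_keeps_everything(self, design50, noisy_fit):
        model, y = noisy_fit
        at = anova(model, design50, y)
        red = reduce_model(model, at, p_threshold=1.0)
        assert red.kept_terms == term_labels(model.factor_names)
        assert np.allclose(red.coef_vector(), model.coef_vector(), atol=1e-10)

    def test_nothing_significant_gives_intercept_only(self, design50):
        flat = QuadraticModel.from_coefficients(FACTOR_NAMES, {"intercept": 23.0})
        from qpcropt import SyntheticSurfaceSpec

        spec = SyntheticSurfaceSpec(true_model=flat, noise_sd=0.5, seed=21)
        y = simulate_response(design50, spec)["ct_mean"].to_numpy()
        m = fit_quadratic(design50, y)
        at = anova(m, design50, y)
        red = reduce_model(m, at, p_threshold=1e-12)
        assert red.kept_terms == []
        assert red.intercept == pytest.approx(y.mean())

    def test_active_term_recall_and_nominal_false_positives(self, design50):
        """Truly active terms are always retained at high signal; inactive
        terms slip in at ~ the nominal 5% per-term rate (18 inactive terms
        => about 0.9 false inclusions per fit on average)."""
        truth = QuadraticModel.from_coefficients(
            FACTOR_NAMES, {"intercept": 23.6, "D": -1.63, "D^2": 0.95}
        )
        from qpcropt import SyntheticSurfaceSpec

        reps = 100
        recall_hits = 0
        false_counts = []
        for s in range(reps):
            spec = SyntheticSurfaceSpec(true_model=truth, noise_sd=0.1, seed=3000 + s)
            y = simulate_response(design50, spec)["ct_mean"].to_numpy()
            m = fit_quadratic(design50, y)
            at = anova(m, design50, y)
            red = reduce_model(m, at)
            kept = set(red.kept_terms)
            if {"D", "D^2"} <= kept:
                recall_hits += 1
            false_counts.append(len(kept - {"D", "D^2"}))
        assert recall_hits >= int(0.95 * reps)
        assert np.mean(false_counts) < 2.0  # nominal expectation ~0.9

    def test_refit_changes_coefficients_from_full_fit(self, design50, noisy_fit):
        model, y = noisy_fit
        at = anova(model, design50, y)
        red = reduce_model(model, at)
        full_map = model.coef_by_label()
        red_map = red.coef_by_label()
        kept = red.kept_terms
        assert kept  # D at least
        # refit on an orthogonal design leaves linear terms equal but the
        # intercept re-absorbs the dropped quadratic columns
        assert red.intercept != pytest.approx(model.intercept, abs=1e-12)
        for label in kept:
            assert red_map[label] != 0.0
        dropped = set(full_map) - set(kept)
        assert all(red_map[l] == 0.0 for l in dropped)


class TestPredict:
    def test_printed_reduced_surfaces_at_origin(self):
        assert default_spec("RSV").true_model.predict(np.zeros(5)) == pytest.approx(23.600)
        assert default_spec("INF").true_model.predict(np.zeros(5)) == pytest.approx(23.740)
        assert default_spec("HMPV").true_model.predict(np.zeros(5)) == pytest.approx(23.600)

    def test_rsv_surface_off_origin_hand_arithmetic(self):
        m = default_spec("RSV").true_model
        point = np.zeros(5)
        point[3] = 1.0  # D = +1
        assert m.predict(point) == pytest.approx(23.600 - 1.630 + 0.950)

    def test_extrapolation_warning(self, rsv_model):
        point = np.zeros(5)
        point[3] = 3.0
        with pytest.warns(UserWarning, match="extrapolat"):
            rsv_model.predict(point, warn_extrapolation=2.378)


def test_r_squared_nested_monotonicity(design50, noisy_fit):
    """Adding terms never lowers training R^2."""
    model, y = noisy_fit
    at = anova(model, design50, y)
    red = reduce_model(model, at)
    assert model.r_squared() >= red.r_squared() - 1e-12

    # build a chain of nested refits and check monotone R^2
    labels = term_labels(model.factor_names)
    z = expand_quadratic(design50.coded)
    prev = -np.inf
    for upto in range(0, len(labels) + 1, 5):
        cols = [0] + list(range(1, 1 + upto))
        beta, _, _, _ = np.linalg.lstsq(z[:, cols], y, rcond=None)
        resid = y - z[:, cols] @ beta
        r2 = 1 - resid @ resid / np.sum((y - y.mean()) ** 2)
        assert r2 >= prev - 1e-12
        prev = r2


def test_model_json_roundtrip(noisy_fit):
    model, _ = noisy_fit
    from qpcropt import QuadraticModel

    back = QuadraticModel.from_json(model.to_json())
    assert np.allclose(back.coef_vector(), model.coef_vector())
    assert back.factor_names == model.factor_names
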