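"""Restricted cubic spline basis and logistic model fitting."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.linalg import null_space

from psdoc.regression import (
    ModelSpec,
    compare_models,
    default_knots,
    fit_logistic,
    fit_logistic_design,
    rcs_basis,
)
from psdoc.synth import GeneratorConfig, generate_regression_cohort


class TestRcsBasis:
    def test_linear_below_first_knot(self):
        x = np.linspace(-5, 0.5, 50)
        basis = rcs_basis(x, [1.0, 2.0, 3.0])
        assert basis.shape == (50, 2)
        assert np.allclose(basis[:, 1], 0.0)
        assert np.allclose(basis[:, 0], x)

    def test_second_derivative_zero_beyond_boundary_knots(self):
        """Numerical second differences vanish outside [t1, tk]."""
        knots = [30.0, 55.0, 80.0]
        h = 0.01
        for region in (np.arange(10, 29, 0.7), np.arange(81, 120, 0.7)):
            for col in range(2):
                f = lambda v: rcs_basis(
                    np.concatenate([v, [0.0, 50.0, 100.0]]), knots)[: len(v), col]
                second = (f(region + h) - 2 * f(region) + f(region - h)) / h**2
                assert np.max(np.abs(second)) < 1e-6

    def test_matches_constraint_projection_oracle(self):
        """Span equality with the truncated-power basis under the two
        linearity constraints, imposed by direct linear algebra."""
        rng = np.random.default_rng(0)
        x = rng.uniform(20, 90, 200)
        knots = np.quantile(x, [0.1, 0.5, 0.9])
        t = knots

        # unrestricted coefficients over [x, x^2, x^3, (x-t_j)^3_+ ...]
        pp3 = lambda v: np.clip(v, 0, None) ** 3
        B = np.column_stack([x, x**2, x**3] + [pp3(x - tj) for tj in t])
        # natural-spline constraints: no x^2/x^3 terms below t1, cubic and
        # quadratic coefficients cancel above tk
        C = np.array([
            [0, 1, 0, 0, 0, 0],
            [0, 0, 1, 0, 0, 0],
            [0, 0, 1, 1, 1, 1],
            [0, 1, 0, -3 * t[0], -3 * t[1], -3 * t[2]],
        ], dtype=float)
        N = null_space(C)
        oracle = B @ N  # n x 2 basis of the constrained space

        ours = rcs_basis(x, knots)
        # same column space: cross-projection residuals vanish
        for A, Z in ((oracle, ours), (ours, oracle)):
            coef, res, *_ = np.linalg.lstsq(A, Z, rcond=None)
            resid = Z - A @ coef
            assert np.max(np.abs(resid)) < 1e-8 * max(1.0, np.max(np.abs(Z)))

    def test_degenerate_and_invalid_inputs(self):
        with pytest.raises(ValueError, match="degenerate"):
            rcs_basis(np.array([1.0, 1.0, 1.0, 2.0]), [1.0, 1.5, 2.0])
        with pytest.raises(ValueError):
            rcs_basis(np.arange(10.0), [3.0, 3.0, 4.0])
        with pytest.raises(ValueError):
            rcs_basis(np.arange(10.0), [3.0, 4.0])

    def test_default_knots_are_outer_quantiles(self):
        x = np.arange(101.0)
        assert default_knots(x, 3) == pytest.approx([10.0, 50.0, 90.0])


class TestFitLogistic:
    def test_two_by_two_odds_ratio_closed_form(self):
        """Counts (30,10,10,30) give OR = 900/100 = 9 in the saturated fit."""
        x = np.array([1] * 40 + [0] * 40, dtype=float)
        y = np.array([1] * 30 + [0] * 10 + [1] * 10 + [0] * 30, dtype=float)
        X = pd.DataFrame({"intercept": np.ones_like(x), "x": x})
        fit = fit_logistic_design(X, y)
        assert fit.odds_ratios["x"] == pytest.approx(9.0, rel=1e-6)
        assert fit.converged

    def test_intercept_only_balanced(self):
        X = pd.DataFrame({"intercept": np.ones(50)})
        y = np.array([1, 0] * 25, dtype=float)
        fit = fit_logistic_design(X, y)
        assert fit.coefficients["intercept"] == pytest.approx(0.0, abs=1e-8)
        assert fit.predicted(X.to_numpy())[0] == pytest.approx(0.5)

    def test_log_or_roundtrip(self):
        x = np.array([1] * 40 + [0] * 40, dtype=float)
        y = np.array([1] * 30 + [0] * 10 + [1] * 10 + [0] * 30, dtype=float)
        X = pd.DataFrame({"intercept": np.ones_like(x), "x": x})
        fit = fit_logistic_design(X, y)
        for term, est in fit.coefficients.items():
            assert math.log(fit.odds_ratios[term]) == pytest.approx(est, abs=1e-12)
            lo, hi = fit.ci95[term]
            assert lo < fit.odds_ratios[term] < hi

    def test_single_class_outcome_raises(self):
        X = pd.DataFrame({"intercept": np.ones(10)})
        with pytest.raises(ValueError, match="both classes"):
            fit_logistic_design(X, np.ones(10))

    def test_rank_deficiency_names_collinear_terms(self):
        n = 30
        x = np.arange(n, dtype=float)
        X = pd.DataFrame({"intercept": np.ones(n), "x": x, "x2": 2 * x})
        y = (x > 15).astype(float)
        with pytest.raises(ValueError, match="collinear"):
            fit_logistic_design(X, y)

    def test_separation_flagged(self):
        x = np.array([0.0] * 20 + [1.0] * 20)
        y = x.copy()
        X = pd.DataFrame({"intercept": np.ones(40), "x": x})
        fit = fit_logistic_design(X, y)
        assert "x" in fit.separation_flags

    def test_null_covariate_coverage(self):
        """Covariate independent of outcome: the 95% CI covers OR = 1 in at
        least 93 of 100 seeded replicates (n = 10,000 each)."""
        hits = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            x = rng.random(10_000) < 0.5
            y = (rng.random(10_000) < 0.4).astype(float)
            X = pd.DataFrame({"intercept": np.ones(10_000),
                              "x": x.astype(float)})
            fit = fit_logistic_design(X, y)
            lo, hi = fit.ci95["x"]
            hits += lo <= 1.0 <= hi
        assert hits >= 93


@pytest.fixture(scope="module")
def cohort():
    return generate_regression_cohort(GeneratorConfig(n_patients=20_000, seed=17))


class TestFullModel:

    def test_both_variants_converge(self, cohort):
        fit_a, fit_b, table = compare_models(cohort)
        assert fit_a.converged and fit_b.converged
        assert "metastatic_at_dx" in fit_b.odds_ratios
        assert "metastatic_at_dx" not in fit_a.odds_ratios
        assert set(table["term"]) == set(fit_a.odds_ratios)

    def test_adjustment_stability(self):
        """With metastatic status drawn independently of the covariates,
        adding it moves the other ORs by well under 10%."""
        cfg = GeneratorConfig(n_patients=20_000, seed=31)
        cfg.p_metastatic_by_group = {g: 0.22 for g in cfg.p_metastatic_by_group}
        stable = generate_regression_cohort(cfg)
        _, _, table = compare_models(stable)
        other = table[~table["term"].str.startswith(("intercept", "age"))]
        assert (np.abs(np.log(other["or_ratio"].dropna())) < np.log(1.10)).all()

    def test_null_metastatic_effect_recovered(self):
        cfg = GeneratorConfig(n_patients=20_000, seed=23)
        cfg.ps_propensity.metastatic = 0.0
        cohort = generate_regression_cohort(cfg)
        fit = fit_logistic(ModelSpec(include_metastatic=True), cohort)
        lo, hi = fit.ci95["metastatic_at_dx"]
        assert lo <= 1.0 <= hi

    def test_reference_level_invariance_of_fitted_probabilities(self, cohort):
        sub = cohort.iloc[:4000]
        import psdoc.regression as reg
        fits = []
        for g in ("Breast", "Lung"):
            spec = ModelSpec(reference_group=g)
            X = reg._build_design(sub, spec)
            fit = fit_logistic_design(X, sub["has_ps"].astype(float).to_numpy())
            fits.append(fit.predicted(X.to_numpy()))
        assert np.allclose(fits[0], fits[1], atol=1e-6)

    def test_missing_reference_level_raises(self, cohort):
        with pytest.raises(ValueError, match="reference"):
            fit_logistic(ModelSpec(reference_group="Nonexistent"), cohort.iloc[:500])

    def test_spec_requires_three_knots(self):
        with pytest.raises(ValueError):
            ModelSpec(n_knots=2)
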