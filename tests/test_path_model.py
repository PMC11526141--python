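import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from dielpredict.path_model import (PathFit, PathModelSpec, compare_models, fishers_c,
                                    fit_indices, fit_path_model, standardize_table)


def simulate_chain(n=200, seed=0, b_yx1=0.4, b_yx2=-0.3, b_zy=0.6, rho=0.5):
    """x1, x2 correlated exogenous; y <- x1, x2; z <- y. All unit variance."""
    rng = np.random.default_rng(seed)
    x1 = rng.normal(size=n)
    x2 = rho * x1 + rng.normal(size=n) * np.sqrt(1 - rho**2)
    var_y_struct = b_yx1**2 + b_yx2**2 + 2 * b_yx1 * b_yx2 * rho
    y = b_yx1 * x1 + b_yx2 * x2 + rng.normal(size=n) * np.sqrt(1 - var_y_struct)
    z = b_zy * y + rng.normal(size=n) * np.sqrt(1 - b_zy**2)
    return pd.DataFrame({"x1": x1, "x2": x2, "y": y, "z": z})


CHAIN_SPEC = "y ~ x1 + x2\nz ~ y\nx1 ~~ x2"


class TestSpecGrammar:
    def test_parse(self):
        spec = PathModelSpec.from_string(CHAIN_SPEC)
        assert spec.regressions == [("y", ["x1", "x2"]), ("z", ["y"])]
        assert spec.covariances == [("x1", "x2")]
        assert set(spec.exogenous) == {"x1", "x2"}

    def test_cycle_rejected(self):
        with pytest.raises(ValueError, match="acyclic"):
            PathModelSpec.from_string("a ~ b\nb ~ a")

    def test_garbage_line_rejected(self):
        with pytest.raises(ValueError, match="parse"):
            PathModelSpec.from_string("a -> b")


class TestStandardize:
    def test_closed_form(self):
        df = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [1.0, 0.0, 1.0], "c": [0, 1, 2],
                           "d": [3, 1, 2]})
        out = standardize_table(df, ["a"])
        np.testing.assert_allclose(out["a"], [-1.0, 0.0, 1.0])

    def test_idempotent(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame({"a": rng.normal(size=20), "b": rng.normal(size=20)})
        once = standardize_table(df, ["a", "b"])
        twice = standardize_table(once, ["a", "b"])
        np.testing.assert_allclose(once.to_numpy(), twice.to_numpy(), atol=1e-10)

    def test_contract(self):
        df = simulate_chain(seed=2)
        out = standardize_table(df, list(df.columns))
        assert np.abs(out.mean()).max() < 1e-10
        np.testing.assert_allclose(out.std(ddof=1), 1.0)

    def test_zero_variance_named(self):
        df = pd.DataFrame({"a": [1.0, 1.0, 1.0, 1.0], "b": [1, 2, 3, 4]})
        with pytest.raises(ValueError, match="'a'"):
            standardize_table(df, ["a", "b"])


class TestFitPathModel:
    def test_saturated_chi2_zero(self):
        df = standardize_table(simulate_chain(seed=3), ["x1", "x2", "y", "z"])
        fit = fit_path_model(PathModelSpec.saturated(["x1", "x2", "y", "z"]), df)
        assert fit.dof == 0
        assert fit.chi2 == pytest.approx(0.0, abs=1e-6)
        assert fit.cfi == 1.0 and fit.rmsea == 0.0

    def test_ml_equals_per_equation_ols(self):
        df = standardize_table(simulate_chain(seed=4), ["x1", "x2", "y", "z"])
        fit = fit_path_model(PathModelSpec.from_string(CHAIN_SPEC), df)
        ols = sm.OLS(df["y"], df[["x1", "x2"]]).fit()
        assert fit.coefficients[("y", "x1")][0] == pytest.approx(ols.params["x1"], abs=1e-6)
        assert fit.coefficients[("y", "x2")][0] == pytest.approx(ols.params["x2"], abs=1e-6)

    def test_relabeling_invariance(self):
        df = standardize_table(simulate_chain(seed=5), ["x1", "x2", "y", "z"])
        fit1 = fit_path_model(PathModelSpec.from_string(CHAIN_SPEC), df)
        renamed = df.rename(columns={"x1": "p", "x2": "q", "y": "r", "z": "s"})
        fit2 = fit_path_model(
            PathModelSpec.from_string("r ~ p + q\ns ~ r\np ~~ q"), renamed)
        assert fit2.cfi == pytest.approx(fit1.cfi, abs=1e-8)
        assert fit2.rmsea == pytest.approx(fit1.rmsea, abs=1e-8)

    def test_extra_parameter_never_increases_chi2(self):
        df = standardize_table(simulate_chain(seed=6), ["x1", "x2", "y", "z"])
        small = fit_path_model(PathModelSpec.from_string(CHAIN_SPEC), df)
        bigger = fit_path_model(
            PathModelSpec.from_string(CHAIN_SPEC + "\nz ~ x1"), df)
        assert bigger.chi2 <= small.chi2 + 1e-8

    def test_null_coefficient_within_two_se(self):
        hits = 0
        for seed in range(30):
            rng = np.random.default_rng(seed)
            df = pd.DataFrame({"a": rng.normal(size=40), "b": rng.normal(size=40)})
            fit = fit_path_model(PathModelSpec.from_string("b ~ a"),
                                 standardize_table(df, ["a", "b"]))
            e, s, _ = fit.coefficients[("b", "a")]
            hits += abs(e) < 2 * s
        assert hits / 30 >= 0.9

    def test_singular_covariance_rejected(self):
        df = pd.DataFrame({"a": [1.0, 2, 3, 4, 5.0]})
        df["b"] = df["a"] * 1.0
        df = (df - df.mean()) / df.std(ddof=1)
        with pytest.raises(ValueError, match="singular|variance"):
            fit_path_model(PathModelSpec.from_string("b ~ a"), df)

    def test_variables_missing_from_data(self):
        df = standardize_table(simulate_chain(seed=7), ["x1", "y"])
        with pytest.raises(ValueError, match="missing"):
            fit_path_model(PathModelSpec.from_string("y ~ nope"), df)


class TestFitIndices:
    def _fit(self, chi2, dof, chi2_null=100.0, dof_null=6, n=18):
        f = PathFit(spec=None, coefficients={}, covariances={}, variances={},
                    chi2=chi2, dof=dof, chi2_null=chi2_null, dof_null=dof_null,
                    n=n, loglik=0.0, converged=True)
        return fit_indices(f, n)

    def test_perfect_fit_boundary(self):
        f = self._fit(chi2=5.0, dof=5)
        assert f.cfi == 1.0 and f.rmsea == 0.0

    def test_rmsea_formula(self):
        f = self._fit(chi2=10.0, dof=5, n=18)
        assert f.rmsea == pytest.approx(np.sqrt(5.0 / (5 * 17)), abs=1e-6)

    def test_dof_zero_noted(self):
        f = self._fit(chi2=0.0, dof=0)
        assert f.rmsea == 0.0
        assert any("saturated" in note for note in f.notes)


class TestModelComparison:
    def test_saturated_beats_misspecified(self):
        df = standardize_table(simulate_chain(seed=8), ["x1", "x2", "y", "z"])
        sat = fit_path_model(PathModelSpec.saturated(["x1", "x2", "y", "z"]), df)
        bad = fit_path_model(
            PathModelSpec.from_string("y ~ x1\nz ~ x1\nx1 ~~ x2"), df)
        assert bad.dof > 0 and bad.cfi < 1.0
        assert compare_models([bad, sat])[0] is sat

    def test_tie_preserves_input_order(self):
        df = standardize_table(simulate_chain(seed=9), ["x1", "x2", "y", "z"])
        spec = PathModelSpec.from_string(CHAIN_SPEC)
        f1, f2 = fit_path_model(spec, df), fit_path_model(spec, df)
        assert compare_models([f1, f2]) == [f1, f2]

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            compare_models([])


class TestFishersC:
    def test_chain_claim_matches_partial_regression(self):
        df = standardize_table(simulate_chain(seed=10), ["x1", "x2", "y", "z"])
        spec = PathModelSpec.from_string(CHAIN_SPEC)
        C, dof, p, claims = fishers_c(spec, df)
        assert dof == 2 * len(claims) and len(claims) == 2  # z vs x1, z vs x2
        # oracle: recompute one claim's p-value directly
        (resp, other, cond, pval) = claims[0]
        X = sm.add_constant(df[[other] + list(cond)])
        expect = float(sm.OLS(df[resp], X).fit().pvalues[other])
        assert pval == pytest.approx(expect)
        assert C == pytest.approx(-2 * sum(np.log(c[-1]) for c in claims))

    def test_saturated_has_no_claims(self):
        df = standardize_table(simulate_chain(seed=11), ["x1", "x2", "y", "z"])
        C, dof, p, claims = fishers_c(PathModelSpec.saturated(["x1", "x2", "y", "z"]), df)
        assert (C, dof, p, claims) == (0.0, 0, 1.0, [])
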