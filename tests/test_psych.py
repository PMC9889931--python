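"""Correlation, reliability, and CFA statistics against independent oracles."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from semflex import (
    CFAModelSpec,
    FactorSimConfig,
    composite_reliability,
    cronbach_alpha,
    fisher_z_compare,
    fit_cfa,
    fit_indices,
    independence_model,
    pearson_r_ci,
    rmsea_from_chi2,
    simulate_factor_data,
    spearman_rho,
)
from semflex.psych import (
    cronbach_alpha_from_cov,
    load_cfa_spec,
    rmsea_confidence_interval,
    steiger_z_compare,
)


class TestCorrelations:
    def test_spearman_monotone_is_one(self):
        x = [1, 2, 3, 4, 5]
        assert spearman_rho(x, [2, 4, 9, 16, 30]).r == pytest.approx(1.0)
        assert spearman_rho(x, x[::-1]).r == pytest.approx(-1.0)

    def test_spearman_rank_formula_oracle(self):
        # 1 - 6 sum(d^2) / (n(n^2-1)) with d = (0,-1,1,-1,1) -> 1 - 24/120 = 0.8
        res = spearman_rho([1, 2, 3, 4, 5], [1, 3, 2, 5, 4])
        assert res.r == pytest.approx(0.8, abs=1e-12)

    def test_spearman_constant_input_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            spearman_rho([1, 1, 1, 1], [1, 2, 3, 4])

    def test_spearman_ci_brackets_rho(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(100)
        res = spearman_rho(x, x + rng.standard_normal(100))
        assert res.ci_low < res.r < res.ci_high

    def test_pearson_affine_is_one(self):
        x = np.arange(10.0)
        assert pearson_r_ci(x, 2 * x + 1).r == pytest.approx(1.0)
        assert pearson_r_ci(x, -x).r == pytest.approx(-1.0)

    def test_pearson_hand_computation(self):
        # sum of cross products 3, sqrt(2 * 14/3) -> 0.981981
        assert pearson_r_ci([1, 2, 3], [1, 2, 4]).r == pytest.approx(0.9820, abs=5e-5)

    def test_pearson_ci_matches_fisher_formula(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal(50)
        y = x + rng.standard_normal(50)
        res = pearson_r_ci(x, y)
        lo = math.tanh(math.atanh(res.r) - 1.959963984540054 / math.sqrt(47))
        assert res.ci_low == pytest.approx(lo, abs=1e-9)


class TestFisherCompare:
    def test_equal_correlations_give_zero(self):
        assert fisher_z_compare(0.4, 50, 0.4, 80) == 0.0

    def test_published_arithmetic(self):
        assert fisher_z_compare(0.302, 224, 0.825, 224) == pytest.approx(9.05, abs=5e-3)

    def test_hand_computation(self):
        z = fisher_z_compare(0.0, 28, 0.5, 28)
        assert z == pytest.approx(math.atanh(0.5) / math.sqrt(2 / 25), abs=1e-12)
        assert round(z, 2) == 1.94

    @settings(deadline=None, derandomize=True)
    @given(
        st.floats(-0.95, 0.95), st.floats(-0.95, 0.95),
        st.integers(5, 500), st.integers(5, 500),
    )
    def test_antisymmetry(self, r1, r2, n1, n2):
        assert fisher_z_compare(r1, n1, r2, n2) == pytest.approx(
            -fisher_z_compare(r2, n2, r1, n1), abs=1e-12
        )

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            fisher_z_compare(1.0, 50, 0.2, 50)
        with pytest.raises(ValueError):
            fisher_z_compare(0.1, 3, 0.2, 50)

    def test_steiger_sign_convention(self):
        assert steiger_z_compare(0.3, 0.6, 0.4, 100) > 0
        assert steiger_z_compare(0.6, 0.3, 0.4, 100) < 0


def _compound_symmetric(k, rho):
    return np.full((k, k), rho) + (1 - rho) * np.eye(k)


class TestAlpha:
    def test_compound_symmetry_closed_form_exact(self):
        for k, rho in [(10, 0.3), (5, 0.6), (20, 0.1)]:
            alpha = cronbach_alpha_from_cov(_compound_symmetric(k, rho))
            assert alpha == pytest.approx(k * rho / (1 + (k - 1) * rho), abs=1e-10)

    def test_k10_rho03_value(self):
        assert cronbach_alpha_from_cov(_compound_symmetric(10, 0.3)) == pytest.approx(
            0.8108, abs=5e-5
        )

    def test_perfectly_correlated_items(self):
        rng = np.random.default_rng(2)
        x = rng.standard_normal(50)
        assert cronbach_alpha(np.column_stack([x, x])) == pytest.approx(1.0)

    def test_uncorrelated_items_near_zero(self):
        # population alpha is 0; exact 0 holds at the covariance level
        assert cronbach_alpha_from_cov(np.eye(8)) == pytest.approx(0.0, abs=1e-12)

    def test_matches_pingouin_on_sample_data(self):
        pingouin = pytest.importorskip("pingouin")
        data = simulate_factor_data(
            FactorSimConfig(loadings={f"v{i}": ("g", 0.6) for i in range(6)}, n=300, seed=3)
        )
        expected = float(pingouin.cronbach_alpha(data=data)[0])
        assert cronbach_alpha(data) == pytest.approx(expected, abs=1e-10)

    def test_too_few_items_or_rows(self):
        with pytest.raises(ValueError):
            cronbach_alpha(np.ones((10, 1)))
        with pytest.raises(ValueError):
            cronbach_alpha(np.ones((2, 3)))


class TestCompositeReliability:
    def test_homogeneous_identity(self):
        rel = composite_reliability([0.6] * 10)
        assert rel.omega == pytest.approx(0.8491, abs=5e-5)
        assert rel.omega == pytest.approx(rel.coefficient_h, abs=1e-10)

    def test_near_perfect_loadings_approach_one(self):
        rel = composite_reliability([0.999] * 5)
        assert rel.omega > 0.99 and rel.coefficient_h > 0.99

    def test_h_exceeds_omega_with_heterogeneous_loadings(self):
        rel = composite_reliability([0.9, 0.1])
        assert rel.coefficient_h > rel.omega

    def test_loading_at_one_rejected(self):
        with pytest.raises(ValueError):
            composite_reliability([1.0, 0.5])


def _one_factor_data(lam=0.7, k=10, n=5000, seed=11):
    return simulate_factor_data(
        FactorSimConfig(loadings={f"v{i}": ("g", lam) for i in range(k)}, n=n, seed=seed)
    )


class TestCFA:
    def test_one_factor_loading_recovery(self):
        data = _one_factor_data()
        res = fit_cfa(data, CFAModelSpec(factors={"g": list(data.columns)}))
        assert res.converged
        assert np.all(np.abs(res.loadings.to_numpy() - 0.7) < 0.05)
        assert res.df == 35

    def test_df_formula(self):
        data = _one_factor_data(k=6, n=500)
        res = fit_cfa(data, CFAModelSpec(factors={"g": list(data.columns)}))
        # p(p+1)/2 moments minus 6 loadings + 6 residuals
        assert res.df == 21 - 12 == res.df
        assert res.n_free_parameters == 12

    def test_saturated_three_variable_model(self):
        data = _one_factor_data(k=3, n=500)
        res = fit_cfa(data, CFAModelSpec(factors={"g": list(data.columns)}))
        assert res.df == 0
        assert res.chi_square == pytest.approx(0.0, abs=1e-6)

    def test_three_factor_recovery_with_residual_covariances(self):
        items = [f"i{k}" for k in range(10)]
        loadings = {}
        for fac, lam in (("flex", 0.6), ("orig", 0.65), ("flu", 0.8)):
            for it in items:
                loadings[f"{fac}_{it}"] = (fac, lam)
        fcors = {("flex", "orig"): 0.7, ("flex", "flu"): 0.4, ("orig", "flu"): 0.3}
        rpairs = {}
        for it in items:
            rpairs[(f"flex_{it}", f"orig_{it}")] = 0.10
            rpairs[(f"flex_{it}", f"flu_{it}")] = 0.05
            rpairs[(f"orig_{it}", f"flu_{it}")] = 0.05
        data = simulate_factor_data(
            FactorSimConfig(loadings=loadings, factor_correlations=fcors,
                            residual_pairs=rpairs, n=2000, seed=5)
        )
        spec = CFAModelSpec(
            factors={f: [f"{f}_{it}" for it in items] for f in ("flex", "orig", "flu")},
            residual_pairs=list(rpairs),
        )
        res = fit_cfa(data, spec)
        assert res.converged
        assert res.df == 372
        for pair, truth in fcors.items():
            assert res.factor_correlations.loc[pair] == pytest.approx(truth, abs=0.1)

    def test_chi_square_invariant_to_variable_order_and_scale(self):
        data = _one_factor_data(k=5, n=800, seed=21)
        spec = CFAModelSpec(factors={"g": list(data.columns)})
        base = fit_cfa(data, spec, standardize=True)
        shuffled = data[list(data.columns[::-1])] * [2.0, 0.5, 7.0, 1.0, 0.1]
        spec2 = CFAModelSpec(factors={"g": list(shuffled.columns)})
        other = fit_cfa(shuffled, spec2, standardize=True)
        assert other.chi_square == pytest.approx(base.chi_square, abs=1e-4)

    def test_cross_loading_rejected(self):
        with pytest.raises(ValueError, match="more than one factor"):
            CFAModelSpec(factors={"a": ["x", "y", "z"], "b": ["z", "w", "q"]})

    def test_same_factor_residual_pair_rejected(self):
        with pytest.raises(ValueError, match="same factor|factor"):
            CFAModelSpec(factors={"a": ["x", "y", "z"]}, residual_pairs=[("x", "y")])

    def test_underidentified_model_rejected(self):
        data = _one_factor_data(k=2, n=100)
        with pytest.raises(ValueError, match="not identified"):
            fit_cfa(data, CFAModelSpec(factors={"g": list(data.columns)}))

    def test_spec_file_roundtrip(self, tmp_path):
        p = tmp_path / "model.ini"
        p.write_text(
            "[factors]\nflex = a, b, c\norig = d, e, f\n"
            "[residual_pairs]\np1 = a:d\np2 = b:e\n"
            "[options]\nfactor_covariances = free\n",
            encoding="utf-8",
        )
        spec = load_cfa_spec(p)
        assert spec.factors == {"flex": ["a", "b", "c"], "orig": ["d", "e", "f"]}
        assert spec.residual_pairs == [("a", "d"), ("b", "e")]


class TestFitIndices:
    def test_perfect_fit_limits(self):
        data = _one_factor_data(k=5, n=1000, seed=9)
        res = fit_cfa(data, CFAModelSpec(factors={"g": list(data.columns)}))
        fit = fit_indices(res)
        if res.chi_square <= res.df:
            assert fit.rmsea == 0.0 and fit.cfi == 1.0

    def test_rmsea_arithmetic_from_published_chi_squares(self):
        assert round(rmsea_from_chi2(48.060, 35, 296), 3) == 0.036
        assert round(rmsea_from_chi2(553.67, 372, 296), 3) == 0.041

    def test_rmsea_zero_when_chi2_below_df(self):
        assert rmsea_from_chi2(30.0, 35, 296) == 0.0

    def test_rmsea_ci_brackets_point_estimate(self):
        lo, hi = rmsea_confidence_interval(48.060, 35, 296)
        assert lo <= rmsea_from_chi2(48.060, 35, 296) <= hi
        assert lo == 0.0  # chi2 barely above df

    def test_indices_on_well_fitting_model(self):
        data = _one_factor_data(n=2000, seed=17)
        res = fit_cfa(data, CFAModelSpec(factors={"g": list(data.columns)}))
        fit = fit_indices(res, independence_model(data, list(data.columns)))
        assert fit.rmsea < 0.05
        assert fit.cfi > 0.95 and fit.tli > 0.95
        assert fit.srmr < 0.05

    def test_saturated_model_note(self):
        data = _one_factor_data(k=3, n=500)
        res = fit_cfa(data, CFAModelSpec(factors={"g": list(data.columns)}))
        fit = fit_indices(res)
        assert fit.rmsea == 0.0 and "saturated" in fit.note

    def test_independence_baseline_closed_form(self):
        rng = np.random.default_rng(3)
        data = pd.DataFrame(rng.standard_normal((200, 4)), columns=list("abcd"))
        chi2_b, df_b, n = independence_model(data, list("abcd"))
        R = np.corrcoef(data.to_numpy(), rowvar=False)
        assert chi2_b == pytest.approx(-(n - 1) * np.log(np.linalg.det(R)), rel=1e-10)
        assert df_b == 6
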