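"""Derivative estimation, per-gene regression, estimators, and edge-list
properties of the ODE-based network inference."""

import numpy as np
import pytest

from dtni.errors import DataValidationError, InferenceError
from dtni.expression import average_replicates
from dtni.inference import (InferenceParams, assemble_regression,
                            encode_perturbation, estimate_derivatives,
                            fit_from_derivatives, fit_gene_model, infer_network)
from dtni.simulate import SimulationDesign, sample_true_system, simulate_expression

from conftest import make_ds


class TestEncodePerturbation:
    @pytest.mark.parametrize("dose,expected", [(1000.0, 1.0), (10.0, 0.01), (100.0, 0.1)])
    def test_max_scaled(self, dose, expected):
        assert encode_perturbation(dose, [10, 100, 1000], "max_scaled") == pytest.approx(expected)

    def test_rank_scaled(self):
        assert encode_perturbation(100.0, [10, 100, 1000], "rank_scaled") == pytest.approx(2 / 3)

    def test_log_scaled_endpoints(self):
        assert encode_perturbation(1000.0, [10, 100, 1000], "log_scaled") == pytest.approx(1.0)
        u = encode_perturbation(10.0, [10, 100, 1000], "log_scaled")
        assert u == pytest.approx(np.log1p(10) / np.log1p(1000))

    def test_unknown_dose_rejected(self):
        with pytest.raises(DataValidationError):
            encode_perturbation(50.0, [10, 100, 1000])


class TestEstimateDerivatives:
    def test_constant_trajectory(self):
        ds = make_ds(genes=("G1",), values=np.full((1, 9), 0.7))
        derivs = estimate_derivatives(ds, InferenceParams())
        np.testing.assert_allclose(derivs.derivatives, 0.0)
        np.testing.assert_allclose(derivs.predictors, 0.7)

    def test_two_point_slope_and_midpoint(self):
        # x(2)=0, x(8)=0.6 -> derivative 0.1/h, midpoint predictor 0.3
        ds = make_ds(genes=("G1",), times=(2.0, 8.0, 24.0), values=None)
        for j, s in enumerate(ds.samples):
            ds.values[0, j] = {2.0: 0.0, 8.0: 0.6, 24.0: 0.6}[s.time]
        derivs = estimate_derivatives(ds, InferenceParams())
        first = np.flatnonzero(derivs.time == 5.0)
        np.testing.assert_allclose(derivs.derivatives[first, 0], 0.1)
        np.testing.assert_allclose(derivs.predictors[first, 0], 0.3)

    def test_linear_trajectory_exact_slope_under_unequal_spacing(self):
        c = 0.037
        ds = make_ds(genes=("G1",), times=(2.0, 8.0, 24.0))
        for j, s in enumerate(ds.samples):
            ds.values[0, j] = c * s.time
        derivs = estimate_derivatives(ds, InferenceParams())
        np.testing.assert_allclose(derivs.derivatives[:, 0], c)

    def test_forward_scheme_uses_left_endpoint(self):
        ds = make_ds(genes=("G1",), times=(2.0, 8.0, 24.0))
        for j, s in enumerate(ds.samples):
            ds.values[0, j] = {2.0: 0.0, 8.0: 0.6, 24.0: 0.6}[s.time]
        derivs = estimate_derivatives(ds, InferenceParams(derivative_scheme="forward"))
        first = np.flatnonzero(derivs.time == 5.0)
        np.testing.assert_allclose(derivs.predictors[first, 0], 0.0)

    def test_u_constant_within_dose_block(self, small_ds):
        derivs = estimate_derivatives(small_ds, InferenceParams())
        for rank in (1, 2, 3):
            us = {derivs.u[k] for k in range(derivs.n_observations)
                  if derivs.dose_rank[k] == rank}
            assert len(us) == 1


class TestAssembleRegression:
    def test_shape_two_genes(self, small_ds):
        derivs = estimate_derivatives(small_ds, InferenceParams())
        y, X = assemble_regression(derivs, 0)
        assert X.shape == (6, 3)  # 3 doses x 2 intervals, 2 genes + u
        assert y.shape == (6,)

    def test_column_order_is_gene_order_then_u(self, small_ds):
        derivs = estimate_derivatives(small_ds, InferenceParams())
        _, X = assemble_regression(derivs, 1)
        np.testing.assert_array_equal(X[:, 0], derivs.predictors[:, 0])
        np.testing.assert_array_equal(X[:, -1], derivs.u)


class TestFitGeneModel:
    def test_null_response_gives_zero_coefficients(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(10, 3))
        fit = fit_gene_model(np.zeros(10), X, InferenceParams())
        np.testing.assert_allclose(fit.coefficients, 0.0, atol=1e-12)
        np.testing.assert_allclose(fit.pvalues, 1.0)

    def test_exact_linear_dependence_recovered(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(10, 3))
        y = 2.0 * X[:, 0]
        fit = fit_gene_model(y, X, InferenceParams())
        np.testing.assert_allclose(fit.coefficients, [2.0, 0.0, 0.0], atol=1e-10)
        assert fit.pvalues[0] < 1e-12

    def test_ols_underdetermined_raises_with_advice(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(5, 8))
        with pytest.raises(InferenceError, match="lasso_ols or permutation"):
            fit_gene_model(rng.normal(size=5), X, InferenceParams())

    def test_aliased_column_dropped_with_warning_note(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(12, 3))
        X[:, 2] = X[:, 0]  # aliased
        y = X[:, 0] + rng.normal(0, 0.1, size=12)
        fit = fit_gene_model(y, X, InferenceParams())
        assert fit.warnings
        assert (fit.coefficients[2] == 0.0) or (fit.coefficients[0] == 0.0)

    def test_lasso_ols_selects_true_support(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(30, 10))
        y = 1.5 * X[:, 2] - 2.0 * X[:, 7] + rng.normal(0, 0.05, size=30)
        fit = fit_gene_model(y, X, InferenceParams(estimator="lasso_ols", seed=0))
        assert fit.pvalues[2] < 0.05 and fit.pvalues[7] < 0.05
        assert fit.coefficients[2] == pytest.approx(1.5, abs=0.1)
        assert fit.coefficients[7] == pytest.approx(-2.0, abs=0.1)

    def test_permutation_pvalues_bounded_and_signal_detected(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(20, 3))
        y = 3.0 * X[:, 1] + rng.normal(0, 0.1, size=20)
        params = InferenceParams(estimator="permutation", permutation_count=200, seed=0)
        fit = fit_gene_model(y, X, params)
        assert fit.pvalues[1] == pytest.approx(1 / 201, abs=1e-12)
        assert np.all(fit.pvalues >= 1 / 201) and np.all(fit.pvalues <= 1.0)

    def test_oracle_derivatives_recover_system_exactly(self):
        """With analytic derivatives and zero noise, OLS matches both a
        direct least-squares solve and the generating system to 1e-8."""
        ts = sample_true_system(3, density=0.5, k_perturbed=2, seed=11)
        design = SimulationDesign(times=[1, 2, 4, 8, 16, 24], noise_sd=0.0,
                                  replicates=1, seed=0)
        _, oracle = simulate_expression(ts, design, return_derivatives=True)
        net = fit_from_derivatives(oracle, InferenceParams())
        for i in range(3):
            y, X = assemble_regression(oracle, i)
            direct, *_ = np.linalg.lstsq(X, y, rcond=None)
            np.testing.assert_allclose(net.A_hat[i], direct[:3], rtol=1e-8, atol=1e-10)
            np.testing.assert_allclose(net.b_hat[i], direct[3], rtol=1e-8, atol=1e-10)
        np.testing.assert_allclose(net.A_hat, ts.A, rtol=1e-8, atol=1e-8)
        np.testing.assert_allclose(net.b_hat, ts.b, rtol=1e-8, atol=1e-8)


class TestInferNetwork:
    def test_all_zero_expression_gives_empty_network(self):
        ds = make_ds(values=np.zeros((2, 9)))
        net = infer_network(ds, InferenceParams())
        assert net.edges == []
        assert net.perturbed_genes == []

    def test_threshold_monotonicity_on_identical_fits(self):
        ds = make_ds(genes=("A", "B", "C"), seed=5, values=None)
        net = infer_network(ds, InferenceParams())
        for a1, a2 in [(0.01, 0.05), (0.05, 0.2), (0.001, 0.5)]:
            e1 = {(e.source, e.target) for e in net.edges_at(a1)}
            e2 = {(e.source, e.target) for e in net.edges_at(a2)}
            assert e1 <= e2

    def test_determinism_same_seed_same_edges(self):
        ts = sample_true_system(6, 0.3, 2, seed=9)
        ds = simulate_expression(ts, SimulationDesign(seed=9))
        params = InferenceParams(estimator="lasso_ols", seed=123)
        n1 = infer_network(average_replicates(ds), params)
        n2 = infer_network(average_replicates(ds), params)
        assert [(e.source, e.target, e.weight, e.pvalue) for e in n1.edges] == \
               [(e.source, e.target, e.weight, e.pvalue) for e in n2.edges]

    def test_gene_order_invariance(self):
        ts = sample_true_system(4, 0.5, 2, seed=3)
        ds = simulate_expression(ts, SimulationDesign(times=[2, 4, 8, 16, 24],
                                                      noise_sd=0.0, replicates=1))
        ds = average_replicates(ds)
        net = infer_network(ds, InferenceParams())
        perm = [2, 0, 3, 1]
        from dtni.expression import DoseTimeExpressionSet
        ds_p = DoseTimeExpressionSet(genes=[ds.genes[i] for i in perm],
                                     samples=list(ds.samples),
                                     values=ds.values[perm, :])
        net_p = infer_network(ds_p, InferenceParams())
        edges = {(e.source, e.target, e.sign) for e in net.edges}
        edges_p = {(e.source, e.target, e.sign) for e in net_p.edges}
        assert edges == edges_p

    def test_finite_difference_error_shrinks_with_grid_halving(self):
        """Midpoint-scheme recovery error decreases monotonically over three
        successive halvings of the sampling interval (noise-free)."""
        ts = sample_true_system(4, 0.4, 2, seed=21)
        errors = []
        for step in (4.0, 2.0, 1.0, 0.5):
            times = list(np.arange(step, 24.0 + 1e-9, step))
            ds = simulate_expression(ts, SimulationDesign(times=times, noise_sd=0.0,
                                                          replicates=1))
            net = infer_network(average_replicates(ds), InferenceParams())
            errors.append(np.abs(net.A_hat - ts.A).max())
        assert errors == sorted(errors, reverse=True)
        assert errors[-1] < errors[0] / 10

    def test_gene_guard_above_hard_limit(self):
        ds = make_ds(genes=[f"G{i}" for i in range(201)],
                     values=np.zeros((201, 9)))
        with pytest.raises(DataValidationError, match="200"):
            infer_network(ds, InferenceParams())
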