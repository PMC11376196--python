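"""Bilevel fitting: state matrices, the exact linear inner solve, the outer
objective and full fits, plus the sklearn estimator front end."""

import numpy as np
import pytest

from titrakit.data import ConcentrationPlan, TitrationData
from titrakit.exceptions import DomainError, RankDeficiencyError
from titrakit.fitting import (
    FitSession,
    TitrationFitter,
    fit,
    outer_objective,
    solve_linear_spectra,
    state_concentration_matrix,
)
from titrakit.model import (
    EquilibriumParameterisation,
    ObservationModel,
    Variable,
    build_observation_matrix_map,
)
from titrakit.speciation import SpeciationProblem, solve_speciation
from titrakit.synthetic import make_scenario, simulate_titration

from conftest import make_1to1_titration


def _speciate(model, beta, totals):
    from titrakit.model import build_stoichiometry_matrix

    M = build_stoichiometry_matrix(model)
    out, warm = [], None
    for k in range(totals.shape[0]):
        r = solve_speciation(SpeciationProblem(totals[k], np.asarray(beta), M), warm)
        assert r.converged
        out.append(r)
        warm = r.s
    return out


class TestStateMatrix:
    def test_slow_exchange_columns_are_concentrations(self, hg_model):
        obs = ObservationModel(exchange="slow", active_states=("H", "G", "HG"))
        obs_map = build_observation_matrix_map(obs, hg_model, ("w0",))
        totals = np.array([[1e-3, 0.0], [1e-3, 1e-3]])
        specs = _speciate(hg_model, [1e3], totals)
        A = state_concentration_matrix(specs, obs_map, hg_model, totals)
        np.testing.assert_allclose(A[0], [1e-3, 0.0, 0.0], atol=1e-18)
        np.testing.assert_allclose(
            A[1], [specs[1].s[0], specs[1].s[1], specs[1].c[0]], rtol=1e-12
        )

    def test_fast_exchange_rows_are_mole_fractions(self, hg2_model):
        obs = ObservationModel(
            exchange="fast", active_states=("H", "HG", "HG2"), reference="H"
        )
        obs_map = build_observation_matrix_map(obs, hg2_model, ("s0",))
        totals = np.array([[2e-4, 0.0], [2e-4, 5e-4], [2e-4, 5e-2]])
        specs = _speciate(hg2_model, [300.0, 3e4], totals)
        A = state_concentration_matrix(specs, obs_map, hg2_model, totals)
        np.testing.assert_allclose(A.sum(axis=1), 1.0, atol=1e-10)
        assert A[0, 0] == pytest.approx(1.0)  # all host free before guest

    def test_half_bound_host_averages_shifts(self, hg_model):
        obs = ObservationModel(exchange="fast", active_states=("H", "HG"), reference="H")
        obs_map = build_observation_matrix_map(obs, hg_model, ("s0",))
        # synthetic speciation: exactly half of the host in the complex
        from titrakit.speciation import SpeciationResult

        spec = SpeciationResult(np.array([5e-4, 1e-3]), np.array([5e-4]),
                                np.zeros(0), True, 0.0)
        totals = np.array([[1e-3, 1.5e-3]])
        A = state_concentration_matrix([spec, spec], obs_map, hg_model, np.vstack([totals, totals]))
        d_free, d_bound = 7.0, 9.0
        predicted = A[0] @ np.array([d_free, d_bound])
        assert predicted == pytest.approx((d_free + d_bound) / 2)


class TestLinearSolve:
    def _map(self, model, states=("H", "G", "HG"), **kw):
        obs = ObservationModel(exchange="slow", active_states=states, **kw)
        return build_observation_matrix_map(obs, model, ("w0", "w1"))

    def test_noiseless_identity_recovery(self, hg_model):
        obs_map = self._map(hg_model)
        rng = np.random.default_rng(0)
        A = rng.uniform(0, 1e-3, size=(8, 3))
        X0 = rng.uniform(100, 1e4, size=(3, 2))
        Y = A @ X0
        res = solve_linear_spectra(A, obs_map, Y)
        np.testing.assert_allclose(res.X, X0, rtol=1e-10)
        assert res.rmse < 1e-10 * np.abs(Y).max()

    def test_residual_orthogonality(self, hg_model):
        # normal equations: design^T residual = 0 for the OLS solution
        obs_map = self._map(hg_model)
        rng = np.random.default_rng(1)
        A = rng.uniform(0, 1e-3, size=(10, 3))
        Y = rng.uniform(0, 1.0, size=(10, 2))
        res = solve_linear_spectra(A, obs_map, Y)
        np.testing.assert_allclose(A.T @ res.residuals, 0.0, atol=1e-8)

    def test_nonnegative_clamps_and_costs(self, hg_model):
        # force a negative unconstrained coefficient; NNLS must clamp it,
        # matching exhaustive active-set enumeration on the 2-variable toy
        obs_map = self._map(hg_model, states=("H", "HG"))
        rng = np.random.default_rng(2)
        A = np.abs(rng.uniform(0.1, 1.0, size=(12, 2)))
        X0 = np.array([[5.0, 2.0], [-3.0, 1.0]])
        Y = A @ X0
        ols = solve_linear_spectra(A, obs_map, Y)
        nn = solve_linear_spectra(A, obs_map, Y, nonnegative=True)
        assert np.all(nn.X >= -1e-12)
        assert nn.rmse >= ols.rmse
        # brute force over active sets {none, x0=0, x1=0, both}
        best = np.inf
        for zero in [(), (0,), (1,), (0, 1)]:
            free = [i for i in (0, 1) if i not in zero]
            x = np.zeros(2)
            if free:
                sol, *_ = np.linalg.lstsq(A[:, free], Y[:, 0], rcond=None)
                if np.all(sol >= 0):
                    x[free] = sol
                else:
                    continue
            best = min(best, np.sqrt(np.mean((Y[:, 0] - A @ x) ** 2)))
        rmse_sig0 = np.sqrt(np.nanmean(nn.residuals[:, 0] ** 2))
        assert rmse_sig0 == pytest.approx(best, rel=1e-8)

    def test_rank_deficiency_names_variables(self, hg_model):
        obs_map = self._map(hg_model)
        A = np.ones((6, 3))  # identical columns: unidentifiable
        Y = np.ones((6, 2))
        with pytest.raises(RankDeficiencyError, match="HG"):
            solve_linear_spectra(A, obs_map, Y)
        res = solve_linear_spectra(A, obs_map, Y, strict=False)
        assert not res.rank_ok

    def test_masked_cells_excluded(self, hg_model):
        obs_map = self._map(hg_model, states=("H", "HG"))
        rng = np.random.default_rng(3)
        A = rng.uniform(0, 1, size=(8, 2))
        X0 = rng.uniform(1, 2, size=(2, 2))
        Y = A @ X0
        Y_masked = Y.copy()
        Y_masked[2, 0] = np.nan
        res = solve_linear_spectra(A, obs_map, Y_masked)
        np.testing.assert_allclose(res.X, X0, rtol=1e-10)
        assert np.isnan(res.residuals[2, 0])


class TestOuterObjective:
    def test_zero_at_generating_parameters(self):
        sc = make_scenario("uv_1to1", noise_sd=0.0)
        data, _ = simulate_titration(sc.spec)
        session = FitSession(sc.spec.model, sc.fit_parameterisation,
                             sc.spec.observation, data, sc.fit_plan)
        rmse = outer_objective(session, {"K1": 5e3})
        assert rmse < 1e-10 * np.abs(data.Y).max()

    def test_minimum_on_log_grid_at_truth(self):
        sc = make_scenario("uv_1to1", noise_sd=0.0)
        data, _ = simulate_titration(sc.spec)
        session = FitSession(sc.spec.model, sc.fit_parameterisation,
                             sc.spec.observation, data, sc.fit_plan)
        grid = np.geomspace(5e3 / 100, 5e3 * 100, 21)
        values = [outer_objective(session, {"K1": k}) for k in grid]
        assert int(np.argmin(values)) == 10  # the grid point at K = 5e3

    def test_fixed_variables_not_searchable(self):
        sc = make_scenario("displacement_partial")
        data, _ = simulate_titration(sc.spec)
        session = FitSession(sc.spec.model, sc.fit_parameterisation,
                             sc.spec.observation, data, sc.fit_plan)
        assert "KA" not in session.outer_names  # KA has role="fixed"
        with pytest.raises(DomainError):
            session.fixing("KA", 1.0)  # not an optimisable variable

    def test_penalty_on_mismatched_plan(self, hg_model, hg_param, hg_obs):
        data = TitrationData(np.ones((3, 1)))
        plan = make_1to1_titration(n_add=4)
        with pytest.raises(DomainError):
            FitSession(hg_model, hg_param, hg_obs, data, plan)


class TestFit:
    def test_bilevel_optimality(self):
        # the fitted RMSE is a lower bound on the objective at random
        # parameter draws for the same data
        sc = make_scenario("uv_1to1", noise_sd=0.002)
        data, _ = simulate_titration(sc.spec, seed=7)
        session = FitSession(sc.spec.model, sc.fit_parameterisation,
                             sc.spec.observation, data, sc.fit_plan)
        result = session.fit()
        rng = np.random.default_rng(4)
        for _ in range(100):
            theta = np.array([rng.uniform(1.0, 6.0)])
            assert result.rmse <= session.objective(theta) + 1e-12

    def test_separability_on_noiseless_data(self):
        sc = make_scenario("nmr_1to2", noise_sd=0.0)
        data, truth = simulate_titration(sc.spec)
        result = fit(sc.spec.model, sc.fit_parameterisation, sc.spec.observation,
                     data, sc.fit_plan)
        scale = np.abs(data.Y).max()
        assert result.rmse <= 1e-8 * scale
        np.testing.assert_allclose(
            result.variable_values["K1"], 328.0, rtol=1e-3
        )
        np.testing.assert_allclose(result.X, truth["spectra"], rtol=1e-5)

    def test_rmse_definition(self):
        sc = make_scenario("uv_1to1", noise_sd=0.003)
        data, _ = simulate_titration(sc.spec, seed=3)
        result = fit(sc.spec.model, sc.fit_parameterisation, sc.spec.observation,
                     data, sc.fit_plan)
        n_cells = np.isfinite(data.Y).sum()
        np.testing.assert_allclose(
            result.rmse**2 * n_cells, np.nansum(result.residuals**2), rtol=1e-12
        )

    def test_estimator_api(self):
        sc = make_scenario("uv_1to1", noise_sd=0.0)
        data, _ = simulate_titration(sc.spec)
        totals = np.column_stack([
            np.full(15, 1e-4),
            np.concatenate([[0.0], np.geomspace(2e-5, 2e-3, 14)]),
        ])
        est = TitrationFitter(sc.spec.model, sc.fit_parameterisation,
                              sc.spec.observation)
        est.fit(totals, data.Y)
        assert est.converged_
        assert est.rmse_ == est.result_.rmse
        np.testing.assert_allclose(est.variable_values_["K1"], 5e3, rtol=1e-6)
        # predictions at the fitted parameters reproduce the data
        np.testing.assert_allclose(est.predict(totals), data.Y, atol=1e-8)
        # sklearn parameter plumbing
        assert est.get_params()["restarts"] == 1
        est.set_params(restarts=2)
        assert est.restarts == 2
        assert est.score(totals, data.Y) > 0.999

    def test_fast_exchange_mole_fraction_rows_sum_to_one(self):
        sc = make_scenario("nmr_1to2", noise_sd=0.0)
        data, _ = simulate_titration(sc.spec)
        session = FitSession(sc.spec.model, sc.fit_parameterisation,
                             sc.spec.observation, data, sc.fit_plan)
        *_, totals, specs, A, _lin = session.evaluate(session.theta0)
        np.testing.assert_allclose(A.sum(axis=1), 1.0, atol=1e-10)
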