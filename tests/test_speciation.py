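"""Speciation solver: closed-form and polynomial-root oracles, gradient
identities, polymer series, convexity, uniqueness."""

import numpy as np
import pytest

from helpers import (
    free_conc_1to1,
    free_conc_1to2,
    polymer_sums_by_summation,
    random_network,
)
from titrakit.exceptions import DomainError
from titrakit.speciation import (
    SpeciationProblem,
    complex_concentrations,
    objective_and_gradient,
    polymer_terms,
    solve_speciation,
    speciation_bounds,
)

M11 = np.array([[1], [1]])
M12 = np.array([[1, 1], [1, 2]])


class TestComplexConcentrations:
    def test_direct_arithmetic(self):
        c = complex_concentrations([1e-3, 1e-3], [1e3, 1e5], M12)
        np.testing.assert_allclose(c, [1e3 * 1e-6, 1e5 * 1e-9], rtol=1e-14)

    def test_zero_component_gives_zero_complex(self):
        c = complex_concentrations([1e-3, 0.0], [1e3, 1e5], M12)
        np.testing.assert_array_equal(c, [0.0, 0.0])

    def test_continuity_in_beta(self):
        c_small = complex_concentrations([1e-3, 1e-3], [1e-30, 1e-30], M12)
        assert np.all(c_small > 0) and np.all(c_small < 1e-30)

    def test_negative_concentration_rejected(self):
        with pytest.raises(DomainError):
            complex_concentrations([-1e-3, 1e-3], [1e3, 1e5], M12)


class TestObjectiveGradient:
    def test_no_complexes_minimum_at_totals(self):
        t = np.array([1e-3, 2e-5])
        problem = SpeciationProblem(t, np.zeros(0), np.zeros((2, 0)))
        _F, g = objective_and_gradient(np.log(t), problem)
        # analytic minimum at s = t (up to the round trip through log space)
        np.testing.assert_allclose(g, 0.0, atol=1e-18)

    def test_gradient_vanishes_at_closed_form_root(self):
        K, t = 1e3, 1e-3
        h, _g = free_conc_1to1(K, t, t)
        problem = SpeciationProblem(np.array([t, t]), np.array([K]), M11)
        _F, grad = objective_and_gradient(np.log([h, h]), problem)
        np.testing.assert_allclose(grad, 0.0, atol=1e-16)

    def test_gradient_is_mass_balance_residual(self):
        rng = np.random.default_rng(5)
        t = np.array([1e-3, 5e-4])
        beta = np.array([1e4, 1e6])
        problem = SpeciationProblem(t, beta, M12)
        x = np.log(t) - rng.uniform(0.5, 3.0, 2)
        s = np.exp(x)
        c = complex_concentrations(s, beta, M12)
        _F, g = objective_and_gradient(x, problem)
        np.testing.assert_allclose(g, s + M12 @ c - t, rtol=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_gradient_matches_central_differences(self, seed):
        rng = np.random.default_rng(seed)
        M = random_network(rng)
        n = M.shape[0]
        t = 10.0 ** rng.uniform(-6, -2, n)
        beta = 10.0 ** rng.uniform(0, 6, M.shape[1])
        polymers = ((0, 100.0, 50.0),) if seed % 2 else ()
        problem = SpeciationProblem(t, beta, M, polymers)
        x = np.log(t) - rng.uniform(0.2, 2.0, n)
        F, g = objective_and_gradient(x, problem)
        eps = 1e-6
        for i in range(n):
            dx = np.zeros(n)
            dx[i] = eps
            fp, _ = objective_and_gradient(x + dx, problem)
            fm, _ = objective_and_gradient(x - dx, problem)
            # finite differences themselves carry ~eps^2 truncation and
            # eps_mach/eps cancellation error relative to the scale of F
            np.testing.assert_allclose(
                g[i], (fp - fm) / (2 * eps), rtol=1e-6, atol=1e-8 * (1 + abs(F))
            )


class TestBounds:
    def test_zero_total_component_eliminated(self):
        problem = SpeciationProblem(np.array([1e-3, 0.0]), np.array([1e5]), M11)
        b = speciation_bounds(problem)
        assert b.active.tolist() == [True, False]
        assert b.kept_complexes.tolist() == [False]
        r = solve_speciation(problem)
        assert r.converged
        np.testing.assert_allclose(r.s, [1e-3, 0.0], rtol=1e-12)
        assert r.s[1] == 0.0
        np.testing.assert_array_equal(r.c, [0.0])

    def test_polymer_upper_bound(self):
        problem = SpeciationProblem(
            np.array([1e-3]), np.zeros(0), np.zeros((1, 0)), ((0, 1e4, 1e4),)
        )
        b = speciation_bounds(problem)
        np.testing.assert_allclose(
            np.exp(b.upper), min(1e-3, (1 - 1e-9) / 1e4), rtol=1e-12
        )

    def test_no_polymer_upper_bound_is_total(self):
        problem = SpeciationProblem(np.array([1e-3, 2e-3]), np.array([1e3]), M11)
        b = speciation_bounds(problem)
        np.testing.assert_allclose(np.exp(b.upper), [1e-3, 2e-3], rtol=1e-12)


class TestSolveAgainstOracles:
    def test_1to1_textbook_point(self):
        r = solve_speciation(
            SpeciationProblem(np.array([1e-3, 1e-3]), np.array([1e3]), M11)
        )
        np.testing.assert_allclose(r.c[0], 3.8196601125e-4, rtol=1e-9)

    def test_1to1_random_draws_match_quadratic(self):
        rng = np.random.default_rng(11)
        for _ in range(300):
            K = 10.0 ** rng.uniform(0, 8)
            t_h, t_g = 10.0 ** rng.uniform(-9, 0, 2)
            r = solve_speciation(
                SpeciationProblem(np.array([t_h, t_g]), np.array([K]), M11)
            )
            assert r.converged
            h, g = free_conc_1to1(K, t_h, t_g)
            np.testing.assert_allclose(r.s, [h, g], rtol=1e-9)

    def test_1to2_random_draws_match_cubic(self):
        rng = np.random.default_rng(12)
        for _ in range(300):
            b1, b2 = 10.0 ** rng.uniform(0, 8, 2)
            t_h, t_g = 10.0 ** rng.uniform(-9, 0, 2)
            r = solve_speciation(
                SpeciationProblem(np.array([t_h, t_g]), np.array([b1, b2]), M12)
            )
            assert r.converged
            h, g = free_conc_1to2(b1, b2, t_h, t_g)
            np.testing.assert_allclose(r.s, [h, g], rtol=1e-9)

    def test_no_binding_limit(self):
        t = np.array([1e-3, 2e-3])
        r = solve_speciation(SpeciationProblem(t, np.array([1e-12]), M11))
        np.testing.assert_allclose(r.s, t, rtol=1e-9)

    def test_warm_start_agrees_with_cold(self):
        problem = SpeciationProblem(np.array([1e-3, 1.2e-3]), np.array([5e4]), M11)
        cold = solve_speciation(problem)
        warm = solve_speciation(problem, warm_start=np.array([9e-4, 1.1e-3]))
        np.testing.assert_allclose(cold.s, warm.s, rtol=1e-10)


class TestRandomNetworks:
    def test_mass_balance_and_uniqueness(self):
        # random <=4-component networks: per-component mass balance and
        # agreement of solves started from different random interior points
        rng = np.random.default_rng(21)
        for _ in range(200):
            M = random_network(rng)
            n_comp, n_cplx = M.shape
            t = 10.0 ** rng.uniform(-9, 0, n_comp)
            beta = 10.0 ** rng.uniform(0, 8, n_cplx)
            problem = SpeciationProblem(t, beta, M)
            r1 = solve_speciation(problem)
            assert r1.converged
            residual = np.abs(t - r1.s - M @ r1.c)
            assert np.all(residual <= 1e-8 * np.maximum(t, 1e-12))
            start = t * 10.0 ** rng.uniform(-6, 0, n_comp)
            r2 = solve_speciation(problem, warm_start=start)
            assert r2.converged
            np.testing.assert_allclose(r1.s, r2.s, rtol=1e-6)

    def test_monotonicity_in_beta(self):
        # raising beta_j weakly raises c_j; for a single-complex system it
        # also weakly lowers both free concentrations.  (With competing
        # complexes the free concentrations need not be monotone: shifting
        # a limiting guest into 2:1 complexes can release host.)
        rng = np.random.default_rng(31)
        for _ in range(40):
            b1, b2 = 10.0 ** rng.uniform(1, 6, 2)
            t = 10.0 ** rng.uniform(-5, -2, 2)
            j = int(rng.integers(0, 2))
            lo = solve_speciation(SpeciationProblem(t, np.array([b1, b2]), M12))
            hi_beta = np.array([b1, b2])
            hi_beta[j] *= 3.0
            hi = solve_speciation(SpeciationProblem(t, hi_beta, M12))
            assert hi.c[j] >= lo.c[j] * (1 - 1e-9)
        for _ in range(20):
            K = 10.0 ** rng.uniform(1, 7)
            t = 10.0 ** rng.uniform(-5, -2, 2)
            lo = solve_speciation(SpeciationProblem(t, np.array([K]), M11))
            hi = solve_speciation(SpeciationProblem(t, np.array([3 * K]), M11))
            assert hi.c[0] >= lo.c[0] * (1 - 1e-9)
            assert np.all(hi.s <= lo.s * (1 + 1e-9))

    def test_convexity_witness(self):
        # F at segment midpoints never exceeds the chord
        rng = np.random.default_rng(41)
        for _ in range(100):
            M = random_network(rng)
            n = M.shape[0]
            t = 10.0 ** rng.uniform(-6, -1, n)
            beta = 10.0 ** rng.uniform(0, 6, M.shape[1])
            problem = SpeciationProblem(t, beta, M)
            xa = np.log(t) - rng.uniform(0, 8, n)
            xb = np.log(t) - rng.uniform(0, 8, n)
            fa, _ = objective_and_gradient(xa, problem)
            fb, _ = objective_and_gradient(xb, problem)
            fm, _ = objective_and_gradient(0.5 * (xa + xb), problem)
            assert fm <= 0.5 * (fa + fb) + 1e-12 * (abs(fa) + abs(fb))


class TestPolymerTerms:
    @pytest.mark.parametrize("u", [0.01, 0.3, 0.9, 0.99])
    def test_isodesmic_closed_form_vs_summation(self, u):
        kn = 1e4
        s = u / kn
        pt = polymer_terms(s, kn, kn)
        mass, chains = polymer_sums_by_summation(s, kn, kn)
        np.testing.assert_allclose(pt.component_in_chains, mass, rtol=1e-9)
        np.testing.assert_allclose(pt.chain_number_concentration, chains, rtol=1e-9)

    def test_cooperative_closed_form_vs_summation(self):
        s, k2, kn = 2e-5, 5e3, 2e4
        pt = polymer_terms(s, k2, kn)
        mass, chains = polymer_sums_by_summation(s, k2, kn)
        np.testing.assert_allclose(pt.component_in_chains, mass, rtol=1e-9)
        np.testing.assert_allclose(pt.chain_number_concentration, chains, rtol=1e-9)

    def test_dimer_only_truncates(self):
        s, k2 = 1e-4, 1e3
        pt = polymer_terms(s, k2, 0.0)
        np.testing.assert_allclose(pt.component_in_chains, 2 * k2 * s * s, rtol=1e-12)
        np.testing.assert_allclose(pt.chain_number_concentration, k2 * s * s, rtol=1e-12)

    def test_vanishes_as_s_to_zero(self):
        pt = polymer_terms(0.0, 1e4, 1e4)
        assert pt.component_in_chains == 0.0 and pt.F_contribution == 0.0

    def test_divergent_series_rejected(self):
        with pytest.raises(DomainError):
            polymer_terms(2e-4, 1e4, 1e4)

    def test_solve_with_polymer_conserves_mass(self):
        t = np.array([2e-3])
        problem = SpeciationProblem(
            t, np.zeros(0), np.zeros((1, 0)), ((0, 5e3, 5e3),)
        )
        r = solve_speciation(problem)
        assert r.converged
        np.testing.assert_allclose(r.s[0] + r.polymer_totals[0], t[0], rtol=1e-10)


class TestDiagnostics:
    def test_all_zero_totals(self):
        r = solve_speciation(SpeciationProblem(np.zeros(2), np.array([1e3]), M11))
        assert r.converged
        np.testing.assert_array_equal(r.s, [0.0, 0.0])

    def test_result_reports_gradient_norm(self):
        r = solve_speciation(
            SpeciationProblem(np.array([1e-3, 1e-3]), np.array([1e3]), M11)
        )
        assert r.grad_norm <= 1e-10 * 1e-3
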