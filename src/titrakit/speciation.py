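"""Equilibrium speciation by convex minimisation.

Given total concentrations ``t``, global constants ``beta`` and the
stoichiometry matrix ``M``, the free-component concentrations ``s`` at
equilibrium satisfy the mass-balance constraints ``t = s + M c(s)`` with
``c_j(s) = beta_j * prod_i s_i**M_ij``.  Writing ``x_i = ln(s_i / c_std)``
(c_std = 1 M keeps the logarithm dimensionless), those constraints are
exactly the stationarity conditions of the scalar function ::

    F(x) = sum_i s_i + sum_j c_j(s) - sum_i t_i x_i  (+ polymer term)
    dF/dx_i = s_i + sum_j M_ij c_j + (polymer mass) - t_i

F is convex in x (each term is an exponential of a linear form, minus a
linear form), so the equilibrium is the unique minimum and the final
gradient norm *is* the physical mass-balance error.

Homopolymers contribute chains of every length n >= 2 with
``c_n = K2 * Kn**(n-2) * s**n`` (dimerisation constant K2, elongation
constant Kn; isodesmic means K2 = Kn).  The geometric series give closed
forms, valid for Kn*s < 1::

    sum_{n>=2} c_n     = K2 s^2 / (1 - Kn s)          (chains, and F term)
    sum_{n>=2} n c_n   = K2 s^2 (2 - Kn s)/(1 - Kn s)^2   (monomer in chains)
    sum_{n>=2} n^2 c_n = K2 s^2 (4 - 3u + u^2)/(1 - u)^3,  u = Kn s

The solver works in x-space inside a box that guarantees numerical
stability: s_i <= t_i (a free component cannot exceed its total, and for a
polymer component additionally s_i < 1/Kn so the series converge), and
x_i >= ln(t_i) - 500 to prevent underflow.  Components with t_i = 0 are
eliminated from the problem (together with every complex containing them)
rather than perturbed, avoiding log singularities.  The primary solve is a
projected damped-Newton iteration on the exact Hessian, which drives the
gradient to near machine precision; scipy's L-BFGS-B serves as a fallback
for ill-conditioned starts.
"""

from __future__ import annotations

from collections.abc import Sequence
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
from scipy.optimize import minimize

from .exceptions import DomainError

__all__ = [
    "SpeciationProblem",
    "SpeciationResult",
    "PolymerTerms",
    "complex_concentrations",
    "polymer_terms",
    "objective_and_gradient",
    "speciation_bounds",
    "solve_speciation",
]

C_STANDARD = 1.0  # reference concentration, M
_LOG_FLOOR = 500.0  # lower bound: ln(s) >= ln(t) - 500
_POLY_SAFETY = 1.0 - 1e-9  # keep Kn*s strictly below 1


@dataclass(frozen=True)
class SpeciationProblem:
    """Inputs of one speciation solve.

    ``polymers`` is a sequence of ``(component_index, K2, Kn)`` triples,
    K2/Kn in M^-1 (Kn = 0 gives a dimer-only species).
    """

    t: np.ndarray
    beta: np.ndarray
    M: np.ndarray
    polymers: tuple[tuple[int, float, float], ...] = ()
    c_standard: float = C_STANDARD

    def __post_init__(self):
        t = np.asarray(self.t, dtype=float)
        beta = np.asarray(self.beta, dtype=float)
        M = np.atleast_2d(np.asarray(self.M, dtype=float))
        if M.size == 0:
            M = M.reshape(t.size, 0)
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "beta", beta)
        object.__setattr__(self, "M", M)
        object.__setattr__(self, "polymers", tuple(tuple(p) for p in self.polymers))
        if np.any(~np.isfinite(t)) or np.any(t < 0):
            raise DomainError("totals must be finite and >= 0")
        if np.any(~np.isfinite(beta)) or np.any(beta <= 0):
            raise DomainError("global constants must be finite and > 0")
        if M.shape != (t.size, beta.size):
            raise DomainError(f"M has shape {M.shape}, expected {(t.size, beta.size)}")
        for comp, k2, kn in self.polymers:
            if not (0 <= comp < t.size):
                raise DomainError("polymer component index out of range")
            if k2 < 0 or kn < 0:
                raise DomainError("polymer constants must be >= 0")


@dataclass
class SpeciationResult:
    s: np.ndarray
    c: np.ndarray
    polymer_totals: np.ndarray  # per polymer: component sequestered in chains, M
    converged: bool
    grad_norm: float
    n_iterations: int = 0
    message: str = ""


class PolymerTerms(NamedTuple):
    component_in_chains: float  # sum n*c_n  (mass-balance contribution)
    chain_number_concentration: float  # sum c_n  (number of chains)
    F_contribution: float  # term added to F(s); equals sum c_n
    dF_dx_contribution: float  # equals component_in_chains


def polymer_terms(s_i: float, k2: float, kn: float) -> PolymerTerms:
    """Closed-form geometric-series sums for one homopolymer at free
    monomer concentration ``s_i``; requires ``kn * s_i < 1``."""
    u = kn * s_i
    if u >= 1.0:
        raise DomainError(f"polymer series diverges: Kn*s = {u} >= 1")
    chains = k2 * s_i * s_i / (1.0 - u)
    mass = k2 * s_i * s_i * (2.0 - u) / (1.0 - u) ** 2
    return PolymerTerms(mass, chains, chains, mass)


def _polymer_curvature(s_i: float, k2: float, kn: float) -> float:
    """sum n^2 c_n = d(mass)/dx — the polymer's Hessian diagonal term."""
    u = kn * s_i
    return k2 * s_i * s_i * (4.0 - 3.0 * u + u * u) / (1.0 - u) ** 3


def complex_concentrations(
    s: Sequence[float], beta: Sequence[float], M: np.ndarray
) -> np.ndarray:
    """``c_j = beta_j * prod_i s_i**M_ij`` with the convention 0**0 = 1."""
    s = np.asarray(s, dtype=float)
    beta = np.asarray(beta, dtype=float)
    M = np.atleast_2d(np.asarray(M, dtype=float))
    if np.any(s < 0):
        raise DomainError("free concentrations must be >= 0")
    if M.shape[1] == 0:
        return np.zeros(0)
    with np.errstate(divide="ignore"):
        logs = np.where(s > 0, np.log(np.where(s > 0, s, 1.0)), -np.inf)
    log_c = np.log(beta) + logs @ M
    # 0**0 = 1: -inf only propagates through columns with M_ij > 0
    zero_cols = (M[s == 0] > 0).any(axis=0) if np.any(s == 0) else np.zeros(M.shape[1], bool)
    c = np.exp(np.where(zero_cols, -np.inf, log_c))
    return c


def _fgh(x, t, beta, M, polymers, need_hess=False):
    """F, gradient and (optionally) Hessian of F at x = ln(s)."""
    s = np.exp(x)
    log_c = np.log(beta) + M.T @ x if beta.size else np.zeros(0)
    c = np.exp(log_c)
    F = s.sum() + c.sum() - t @ x
    g = s + (M @ c if c.size else 0.0) - t
    diag_extra = np.zeros_like(s)
    for comp, k2, kn in polymers:
        pt = polymer_terms(s[comp], k2, kn)
        F += pt.F_contribution
        g[comp] += pt.dF_dx_contribution
        if need_hess:
            diag_extra[comp] += _polymer_curvature(s[comp], k2, kn)
    if not need_hess:
        return F, g
    H = np.diag(s + diag_extra)
    if c.size:
        H += (M * c) @ M.T
    return F, g, H


def objective_and_gradient(x: Sequence[float], problem: SpeciationProblem):
    """Evaluate ``F`` and its gradient with respect to ``x = ln(s/c_std)``.

    The gradient components are exactly minus the mass-balance residuals
    ``f_i = t_i - s_i - sum_j M_ij c_j - (polymer mass)``, so a zero
    gradient certifies equilibrium.
    """
    x = np.asarray(x, dtype=float)
    if x.shape != problem.t.shape:
        raise DomainError("x has wrong shape")
    return _fgh(x, problem.t, problem.beta, problem.M, problem.polymers)


@dataclass
class SpeciationBounds:
    """Box bounds in x-space for the active (t > 0) components."""

    active: np.ndarray  # boolean mask over components
    lower: np.ndarray  # over active components
    upper: np.ndarray
    kept_complexes: np.ndarray = field(default_factory=lambda: np.zeros(0, bool))


def speciation_bounds(problem: SpeciationProblem) -> SpeciationBounds:
    """Stability box: ``s_i <= t_i`` (and ``s_i < 1/Kn`` for polymer
    components), ``ln s_i >= ln t_i - 500``; zero-total components are
    eliminated along with every complex that contains them."""
    t = problem.t
    active = t > 0
    kept = ~((problem.M[~active] > 0).any(axis=0)) if problem.M.size else np.zeros(0, bool)
    ub_s = t[active].copy()
    idx_map = {i: k for k, i in enumerate(np.nonzero(active)[0])}
    for comp, _k2, kn in problem.polymers:
        if active[comp] and kn > 0:
            k = idx_map[comp]
            ub_s[k] = min(ub_s[k], _POLY_SAFETY / kn)
    upper = np.log(ub_s)
    lower = np.log(t[active]) - _LOG_FLOOR
    return SpeciationBounds(active, lower, upper, kept)


def _newton(x, t, beta, M, polymers, lb, ub, aim, max_iter=200):
    """Projected damped-Newton minimisation of F.

    ``aim`` is a per-component vector of absolute gradient targets, so each
    component's mass balance is driven to *relative* accuracy even when the
    totals span many orders of magnitude.  Returns (x, g, iters, hit_aim).
    """

    def scaled(g):
        return np.max(np.abs(g) / aim) if g.size else 0.0

    x = np.clip(x, lb, ub)
    F, g = _fgh(x, t, beta, M, polymers)
    # walk back into the region where F is finite (huge beta at the start box)
    guard = 0
    while not np.isfinite(F) and guard < 200:
        x = np.clip(x - 5.0, lb, ub)
        F, g = _fgh(x, t, beta, M, polymers)
        guard += 1
    if not np.isfinite(F):
        return x, g, guard, False
    for it in range(max_iter):
        sn = scaled(g)
        if sn <= 1.0:
            return x, g, it, True
        _F, _g, H = _fgh(x, t, beta, M, polymers, need_hess=True)
        try:
            dx = np.linalg.solve(H, -g)
        except np.linalg.LinAlgError:
            dx = -g / np.maximum(np.diag(H), 1e-300)
        # cap the step at 100 nats per coordinate: near-singular Hessian
        # rows (a concentration that underflowed) otherwise propose steps
        # no line search can tame
        dx = np.clip(dx, -100.0, 100.0)
        predicted = g @ dx  # < 0 for a descent direction
        if abs(predicted) <= 1e-13 * (1.0 + abs(F)):
            # the F-decrease is below the floating-point resolution of F;
            # in this regime Newton still contracts the gradient
            # quadratically, so accept full steps on gradient decrease alone
            xn = np.clip(x + dx, lb, ub)
            Fn, gn = _fgh(xn, t, beta, M, polymers)
            if np.isfinite(Fn) and scaled(gn) < sn:
                x, F, g = xn, Fn, gn
                continue
            return x, g, it + 1, sn <= 1.0
        step = 1.0
        accepted = False
        for _ls in range(60):
            xn = np.clip(x + step * dx, lb, ub)
            Fn, gn = _fgh(xn, t, beta, M, polymers)
            if np.isfinite(Fn) and Fn <= F + 1e-4 * (g @ (xn - x)):
                x, F, g = xn, Fn, gn
                accepted = True
                break
            step *= 0.5
        if not accepted:
            return x, g, it + 1, scaled(g) <= 1.0
    return x, g, max_iter, scaled(g) <= 1.0


def solve_speciation(
    problem: SpeciationProblem,
    warm_start: Sequence[float] | None = None,
    tol: float | None = None,
) -> SpeciationResult:
    """Solve one speciation problem to equilibrium.

    Parameters
    ----------
    warm_start : optional free-concentration vector ``s`` from a previous,
        nearby solve (e.g. the preceding titration addition); it is clipped
        into the new stability box.
    tol : scalar absolute gradient (= mass-balance) tolerance applied to
        every component; the default is per-component,
        ``max(1e-10 * t_i, 1e-22)`` M, so trace components are balanced to
        the same relative accuracy as abundant ones.

    Non-convergence is reported through ``converged=False`` and
    ``grad_norm``/``message`` diagnostics, never silently.
    """
    t_full = problem.t
    n_comp = t_full.size
    bounds = speciation_bounds(problem)
    active = bounds.active
    kept = bounds.kept_complexes

    s_full = np.zeros(n_comp)
    c_full = np.zeros(problem.beta.size)
    poly_tot = np.zeros(len(problem.polymers))


    if not np.any(active):
        return SpeciationResult(s_full, c_full, poly_tot, True, 0.0, 0, "all totals zero")

    t = t_full[active]
    M = problem.M[np.ix_(active, kept)] if problem.M.size else problem.M[active]
    beta = problem.beta[kept]
    idx_map = {i: k for k, i in enumerate(np.nonzero(active)[0])}
    polymers = [
        (idx_map[comp], k2, kn)
        for comp, k2, kn in problem.polymers
        if active[comp] and k2 > 0
    ]
    lb, ub = bounds.lower, bounds.upper

    # per-component tolerances: acceptance at relative 1e-10 per component
    # (absolute floor 1e-22 M); the iteration aims ~3 decades lower, near
    # the floating-point noise of each mass-balance row
    if tol is None:
        accept = np.maximum(1e-10 * t, 1e-22)
    else:
        accept = np.full(t.shape, float(tol))
    aim = np.minimum(accept, np.maximum(1e-13 * t, 1e-22))

    if warm_start is not None:
        ws = np.asarray(warm_start, dtype=float)[active]
        with np.errstate(divide="ignore"):
            x0 = np.where(ws > 0, np.log(np.where(ws > 0, ws, 1.0)), lb)
        x0 = np.clip(x0, lb, ub)
    else:
        x0 = np.clip(np.log(t) - np.log(2.0), lb, ub)

    x, g, iters, _ = _newton(x0, t, beta, M, polymers, lb, ub, aim)
    ok = bool(np.all(np.abs(g) <= accept))
    message = "newton"
    if not ok:
        # robust fallback: bounded quasi-Newton, then polish again
        res = minimize(
            _fgh,
            x,
            args=(t, beta, M, polymers),
            jac=True,
            method="L-BFGS-B",
            bounds=list(zip(lb, ub)),
            options={"maxiter": 2000, "ftol": 1e-18, "gtol": 1e-14},
        )
        x, g, it2, _ = _newton(res.x, t, beta, M, polymers, lb, ub, aim)
        ok = bool(np.all(np.abs(g) <= accept))
        iters += it2 + res.nit
        message = "lbfgsb+newton"
    gnorm = float(np.max(np.abs(g))) if g.size else 0.0

    s = np.exp(x)
    c = complex_concentrations(s, beta, M) if beta.size else np.zeros(0)
    s_full[active] = s
    c_full[kept] = c
    for p_idx, (comp, k2, kn) in enumerate(problem.polymers):
        if active[comp] and k2 > 0:
            poly_tot[p_idx] = polymer_terms(s_full[comp], k2, kn).component_in_chains
    if not ok:
        worst = float(np.max(np.abs(g) / accept))
        message = f"missed per-component tolerance by factor {worst:.3g}"
    return SpeciationResult(s_full, c_full, poly_tot, ok, float(gnorm), iters, message)
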