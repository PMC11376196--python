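"""Bilevel fitting of titration data.

The observed data obey ``Y = A X``: ``A`` (additions x active states) holds
state concentrations (slow exchange) or mole fractions (fast exchange), and
``X`` (spectral variables x signals) holds the unknown spectra / chemical
shifts.  Equilibrium constants and unknown concentrations enter ``A``
nonlinearly through the speciation solve; ``X`` enters linearly.  The two
groups are therefore separated: the outer derivative-free simplex search
(Nelder--Mead) runs over the log-transformed nonlinear variables only, and
at each outer point ``X`` is recovered exactly by (nonnegative) linear
least squares.  The outer objective is the pooled RMSE of that exact inner
solution.

The separation makes a 601-variable UV/vis problem (one constant plus two
spectra at 300 wavelengths) a one-dimensional outer search.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import minimize, nnls
from sklearn.base import BaseEstimator, RegressorMixin

from .data import (  # noqa: F401  (re-exported: these are fitting-layer types)
    ConcentrationPlan,
    TitrationData,
    totals_from_additions,
)
from .exceptions import ConvergenceError, DomainError, RankDeficiencyError
from .model import (
    EquilibriumParameterisation,
    ObservationMap,
    ObservationModel,
    StoichiometryModel,
    Variable,
    build_observation_matrix_map,
    build_stoichiometry_matrix,
    global_constants,
)
from .speciation import SpeciationProblem, SpeciationResult, solve_speciation

__all__ = [
    "TitrationData",
    "ConcentrationPlan",
    "totals_from_additions",
    "FitResult",
    "FitSession",
    "TitrationFitter",
    "state_concentration_matrix",
    "solve_linear_spectra",
    "LinearSolveResult",
    "outer_objective",
    "fit",
]

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# A matrix and the linear inner solve
# ---------------------------------------------------------------------------


def _block_slices(obs_map: ObservationMap) -> list[slice]:
    slices, start = [], 0
    for block in obs_map.blocks:
        slices.append(slice(start, start + len(block.states)))
        start += len(block.states)
    return slices


def _state_value(label, model, spec: SpeciationResult):
    if label in model.components.names:
        return spec.s[model.components.index(label)]
    for j, cplx in enumerate(model.complexes):
        if cplx.label == label:
            return spec.c[j]
    for p, poly in enumerate(model.polymers):
        if poly.label == label:
            return spec.polymer_totals[p]
    raise DomainError(f"unknown state {label!r}")


def state_concentration_matrix(
    speciations: Sequence[SpeciationResult],
    obs_map: ObservationMap,
    model: StoichiometryModel,
    totals: np.ndarray | None = None,
) -> np.ndarray:
    """Build ``A`` (additions x states, block columns concatenated in
    ``obs_map.blocks`` order).

    Slow exchange: entries are molar state concentrations (a polymer state
    counts the monomer concentration sequestered in chains, so its spectrum
    is per repeat unit).  Fast exchange: entries are the mole fraction of
    the block's reference component in each state — a species containing m
    copies contributes ``m c / t_ref`` — so each block's rows sum to 1 and
    the solved spectra are chemical shifts.
    """
    n_add = len(speciations)
    slices = _block_slices(obs_map)
    A = np.zeros((n_add, slices[-1].stop if slices else 0))
    M = build_stoichiometry_matrix(model)
    for block, sl in zip(obs_map.blocks, slices):
        ref = block.ref_component
        if ref is not None and totals is None:
            raise DomainError("fast exchange requires per-addition totals")
        for k, spec in enumerate(speciations):
            for pos, label in enumerate(block.states):
                v = _state_value(label, model, spec)
                if ref is not None:
                    mult = model.stoichiometry_of(label)[ref]
                    t_ref = totals[k, ref]
                    v = (mult * v / t_ref) if t_ref > 0 else 0.0
                A[k, sl.start + pos] = v
    return A


@dataclass
class LinearSolveResult:
    X: np.ndarray  # (n_spectral_variables x n_signals); NaN where not solved
    predicted: np.ndarray  # (additions x signals)
    residuals: np.ndarray  # Y - predicted, NaN at masked cells
    rmse: float
    rank_ok: bool = True


def solve_linear_spectra(
    A: np.ndarray,
    obs_map: ObservationMap,
    Y: np.ndarray,
    *,
    weights: np.ndarray | None = None,
    nonnegative: bool | None = None,
    strict: bool = True,
) -> LinearSolveResult:
    """Exact inner solve: per signal, ordinary least squares (or NNLS when
    the nonnegative constraint is on) of ``Y - known_offset`` against the
    design ``A R``; masked (NaN) cells are excluded.

    RMSE pools all signals with equal weight unless a per-signal ``weights``
    vector is given.  With ``strict=True`` a rank-deficient design raises
    :class:`RankDeficiencyError` naming the unidentifiable variables.
    """
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    n_add, n_signals = Y.shape
    mask = np.isfinite(Y)
    nn = obs_map.nonnegative if nonnegative is None else nonnegative
    X = np.full((obs_map.n_variables, n_signals), np.nan)
    predicted = np.zeros((n_add, n_signals))
    rank_ok = True
    slices = _block_slices(obs_map)
    for block, sl in zip(obs_map.blocks, slices):
        A_block = A[:, sl]
        D = A_block @ block.R if obs_map.n_variables else np.zeros((n_add, 0))
        cols = np.nonzero(np.any(block.R != 0, axis=0))[0] if block.R.size else np.array([], int)
        for sig in block.signal_indices:
            offset = np.zeros(n_add)
            for pos, values in block.known:
                offset += A_block[:, pos] * values[sig]
            rows = mask[:, sig]
            rhs = Y[rows, sig] - offset[rows]
            Dm = D[np.ix_(rows, cols)]
            if cols.size:
                if np.linalg.matrix_rank(Dm) < cols.size:
                    rank_ok = False
                    if strict:
                        raise RankDeficiencyError(
                            [obs_map.variable_names[c] for c in cols]
                        )
                if nn:
                    x, _ = nnls(Dm, rhs)
                else:
                    x, *_ = np.linalg.lstsq(Dm, rhs, rcond=None)
                X[cols, sig] = x
                predicted[:, sig] = offset + D[:, cols] @ x
            else:
                predicted[:, sig] = offset
    residuals = np.where(mask, Y - predicted, np.nan)
    w = np.ones(n_signals) if weights is None else np.asarray(weights, dtype=float)
    sq = np.where(mask, residuals**2, 0.0)
    rmse = float(np.sqrt((sq * w).sum() / (mask * w).sum()))
    return LinearSolveResult(X, predicted, residuals, rmse, rank_ok)


# ---------------------------------------------------------------------------
# the outer problem
# ---------------------------------------------------------------------------


class _SpeciationFailure(Exception):
    pass


@dataclass
class FitResult:
    """Result of one bilevel fit.

    ``variable_values`` holds the optimised nonlinear variables in natural
    units (equilibrium constants, unknown concentrations in M);
    ``fixed_values`` the constants held fixed.  ``X`` is the solved spectra
    matrix (spectral variables x signals).
    """

    variable_values: dict[str, float]
    fixed_values: dict[str, float]
    X: np.ndarray
    rmse: float
    speciation: list[SpeciationResult]
    totals: np.ndarray
    predicted: np.ndarray
    residuals: np.ndarray
    spectral_variable_names: tuple[str, ...]
    n_outer_evaluations: int
    converged: bool
    theta: np.ndarray = field(default_factory=lambda: np.zeros(0))
    session: "FitSession | None" = field(default=None, repr=False)

    @property
    def beta(self) -> np.ndarray:
        all_values = {**self.fixed_values, **self.variable_values}
        return global_constants(self.session.parameterisation, {
            n: all_values[n] for n in self.session.parameterisation.variable_names
        })


class FitSession:
    """Everything needed to evaluate and optimise the outer objective for
    one dataset + model; reused by the fitter, the RMSE profile and the CLI.

    Outer variables are, in order: the equilibrium variables with
    ``role="optimised"`` (searched in log10), then the plan's "?"/"~"
    concentration cells (searched in log10 M; a "~" guess bounds the search
    to two decades either side, an unguessed "?" to [1e-12, 10] M).
    """

    def __init__(
        self,
        model: StoichiometryModel,
        parameterisation: EquilibriumParameterisation,
        observation: ObservationModel,
        data: TitrationData,
        plan: ConcentrationPlan,
        *,
        weights: np.ndarray | None = None,
        nonnegative: bool | None = None,
        penalty_factor: float = 1e6,
        speciation_tol: float | None = None,
    ):
        if plan.n_additions != data.n_additions:
            raise DomainError(
                f"plan has {plan.n_additions} additions, data has {data.n_additions}"
            )
        if tuple(plan.component_names) != tuple(model.components.names):
            raise DomainError("plan components do not match model components")
        self.model = model
        self.parameterisation = parameterisation
        self.observation = observation
        self.data = data
        self.plan = plan
        self.weights = weights
        self.nonnegative = nonnegative
        self.penalty_factor = penalty_factor
        self.speciation_tol = speciation_tol
        self.obs_map = build_observation_matrix_map(observation, model, data.signal_labels)
        self.M = build_stoichiometry_matrix(model)
        self.data_scale = float(np.nanmax(np.abs(data.Y))) or 1.0

        names, theta0, lo, hi = [], [], [], []
        for v in parameterisation.variables:
            if v.role == "optimised":
                names.append(v.name)
                theta0.append(np.log10(v.value))
                lo.append(-np.inf)
                hi.append(np.inf)
        self._n_eq = len(names)
        for cname, guess in plan.unknown_variables():
            names.append(cname)
            if guess is not None:
                theta0.append(np.log10(guess))
                lo.append(np.log10(guess) - 2.0)
                hi.append(np.log10(guess) + 2.0)
            else:
                theta0.append(0.0)  # 1 M default initial guess
                lo.append(-12.0)
                hi.append(1.0)
        self.outer_names = tuple(names)
        self.theta0 = np.array(theta0)
        self.theta_bounds = (np.array(lo), np.array(hi))
        self.n_evaluations = 0

    # -- transforms ---------------------------------------------------------
    def split_values(self, theta: np.ndarray):
        theta = np.asarray(theta, dtype=float)
        if theta.shape != self.theta0.shape:
            raise DomainError(f"theta must have length {self.theta0.size}")
        eq_names = self.outer_names[: self._n_eq]
        eq = dict(zip(eq_names, 10.0 ** theta[: self._n_eq]))
        conc = dict(zip(self.outer_names[self._n_eq :], 10.0 ** theta[self._n_eq :]))
        return eq, conc

    def theta_from_values(self, values: Mapping[str, float]) -> np.ndarray:
        return np.array([np.log10(values[n]) for n in self.outer_names])

    def _all_equilibrium_values(self, eq: Mapping[str, float]) -> dict[str, float]:
        out = {}
        for v in self.parameterisation.variables:
            out[v.name] = v.value if v.role == "fixed" else eq[v.name]
        return out

    # -- evaluation ---------------------------------------------------------
    def _speciate_all(self, beta, polymers, totals):
        specs = []
        warm = None
        for k in range(totals.shape[0]):
            problem = SpeciationProblem(totals[k], beta, self.M, polymers)
            res = solve_speciation(problem, warm_start=warm, tol=self.speciation_tol)
            if not res.converged:
                raise _SpeciationFailure(res.message)
            specs.append(res)
            warm = res.s
        return specs

    def evaluate(self, theta, *, strict=False):
        """Full inner evaluation at one outer point: speciation per
        addition (warm-started along the titration), A, exact linear solve."""
        eq, conc = self.split_values(theta)
        values = self._all_equilibrium_values(eq)
        beta = global_constants(self.parameterisation, values)
        k2kn = self.parameterisation.polymer_k2_kn(values)
        polymers = tuple(
            (poly.component, k2, kn)
            for poly, (k2, kn) in zip(self.model.polymers, k2kn)
        )
        totals = totals_from_additions(self.plan.resolve(conc))
        specs = self._speciate_all(beta, polymers, totals)
        A = state_concentration_matrix(specs, self.obs_map, self.model, totals)
        lin = solve_linear_spectra(
            A, self.obs_map, self.data.Y,
            weights=self.weights, nonnegative=self.nonnegative, strict=strict,
        )
        return values, conc, totals, specs, A, lin

    def objective(self, theta) -> float:
        """The outer objective: RMSE of the exact inner solution; failed
        speciation returns a large penalty (keeps the simplex search alive)."""
        self.n_evaluations += 1
        try:
            *_rest, lin = self.evaluate(theta)
            return lin.rmse
        except (_SpeciationFailure, DomainError, OverflowError) as exc:
            logger.warning("inner evaluation failed at theta=%s: %s", theta, exc)
            return self.penalty_factor * self.data_scale

    # -- optimisation -------------------------------------------------------
    def fit(
        self,
        theta0: np.ndarray | None = None,
        *,
        maxfev: int | None = None,
        restarts: int = 1,
    ) -> FitResult:
        theta0 = self.theta0 if theta0 is None else np.asarray(theta0, dtype=float)
        self.n_evaluations = 0
        n = theta0.size
        if n == 0:
            theta, converged = theta0, True
        else:
            lo, hi = self.theta_bounds
            bounds = list(zip(lo, hi)) if np.any(np.isfinite(lo) | np.isfinite(hi)) else None
            maxfev = maxfev or 600 * max(n, 1)
            res = minimize(
                self.objective, np.clip(theta0, lo, hi), method="Nelder-Mead",
                bounds=bounds,
                options={"maxfev": maxfev, "fatol": 1e-10, "xatol": 1e-6},
            )
            converged = bool(res.success)
            for _ in range(max(restarts, 0)):
                # restart from the incumbent with tightened tolerances:
                # simplex spread < 1e-12 (1 + rmse) in objective, ~1e-6
                # relative in the natural parameters (4e-7 in log10)
                res = minimize(
                    self.objective, res.x, method="Nelder-Mead", bounds=bounds,
                    options={
                        "maxfev": maxfev,
                        "fatol": 1e-12 * (1.0 + res.fun),
                        "xatol": 4e-7,
                    },
                )
                converged = bool(res.success)
            theta = res.x
            if not converged:
                logger.warning("outer optimisation did not converge: %s", res.message)
        values, conc, totals, specs, A, lin = self.evaluate(theta, strict=False)
        optimised = {n_: v for n_, v in values.items()
                     if n_ in self.outer_names[: self._n_eq]}
        optimised.update(conc)
        fixed = {v.name: v.value for v in self.parameterisation.variables
                 if v.role == "fixed"}
        return FitResult(
            variable_values=optimised,
            fixed_values=fixed,
            X=lin.X,
            rmse=lin.rmse,
            speciation=specs,
            totals=totals,
            predicted=lin.predicted,
            residuals=lin.residuals,
            spectral_variable_names=tuple(self.obs_map.variable_names),
            n_outer_evaluations=self.n_evaluations,
            converged=converged,
            theta=np.asarray(theta, dtype=float),
            session=self,
        )

    def fixing(self, name: str, value: float) -> "FitSession":
        """A new session with outer variable ``name`` held fixed at
        ``value`` (used by the RMSE profile)."""
        if name not in self.outer_names:
            raise DomainError(f"{name!r} is not an optimisable variable")
        if name in self.parameterisation.variable_names:
            variables = tuple(
                Variable(v.name, "fixed", value) if v.name == name else v
                for v in self.parameterisation.variables
            )
            param = EquilibriumParameterisation(
                variables,
                self.parameterisation.exponents,
                self.parameterisation.statistical_factors,
                self.parameterisation.polymer_constants,
            )
            plan = self.plan
        elif name in self.outer_names:
            param = self.parameterisation
            plan = _resolve_single(self.plan, name, value)
        else:
            raise DomainError(f"{name!r} is not an optimisable variable")
        return FitSession(
            self.model, param, self.observation, self.data, plan,
            weights=self.weights, nonnegative=self.nonnegative,
            penalty_factor=self.penalty_factor, speciation_tol=self.speciation_tol,
        )


def _resolve_single(plan: ConcentrationPlan, name: str, value: float) -> ConcentrationPlan:
    from .data import ConcentrationCell

    cells = plan._cells().copy()
    it = iter(plan.unknown_variables())
    for (i, j), cell in np.ndenumerate(cells):
        if cell.is_free:
            vname, _ = next(it)
            if vname == name:
                cells[i, j] = ConcentrationCell("value", float(value))
    if plan.mode == "totals":
        return ConcentrationPlan("totals", plan.component_names, totals=cells)
    return ConcentrationPlan("stocks", plan.component_names, stocks=cells,
                             volumes=plan.volumes, stock_labels=plan.stock_labels)


def outer_objective(session: FitSession, values) -> float:
    """RMSE at one outer point; ``values`` is either a theta vector (log10)
    or a mapping of natural-unit values for the outer variables."""
    if isinstance(values, Mapping):
        values = session.theta_from_values(values)
    return session.objective(values)


# ---------------------------------------------------------------------------
# estimator front end
# ---------------------------------------------------------------------------


class TitrationFitter(BaseEstimator, RegressorMixin):
    """Scikit-learn style estimator around the bilevel fit.

    Parameters
    ----------
    model, parameterisation, observation : the declarative system
        description (see :mod:`titrakit.model`).
    plan : ConcentrationPlan, optional
        Used when ``fit`` receives no explicit concentrations.
    weights : per-signal RMSE weights (default: equal).
    nonnegative : override the observation model's nonnegativity flag.
    restarts : Nelder--Mead restarts from the incumbent (default 1).
    n_starts, seed : optional multi-start — additional starts perturb the
        initial point by up to one decade; deterministic for a fixed seed.

    After ``fit``: ``variable_values_``, ``spectra_`` (X), ``rmse_``,
    ``speciation_``, ``n_outer_evaluations_``, ``converged_``, ``result_``.
    """

    def __init__(
        self,
        model=None,
        parameterisation=None,
        observation=None,
        plan=None,
        weights=None,
        nonnegative=None,
        penalty_factor=1e6,
        maxfev=None,
        restarts=1,
        n_starts=1,
        seed=None,
    ):
        self.model = model
        self.parameterisation = parameterisation
        self.observation = observation
        self.plan = plan
        self.weights = weights
        self.nonnegative = nonnegative
        self.penalty_factor = penalty_factor
        self.maxfev = maxfev
        self.restarts = restarts
        self.n_starts = n_starts
        self.seed = seed

    # -- helpers ------------------------------------------------------------
    def _coerce_plan(self, X) -> ConcentrationPlan:
        if X is None:
            if self.plan is None:
                raise DomainError("no concentrations: pass X or set plan")
            return self.plan
        if isinstance(X, ConcentrationPlan):
            return X
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return ConcentrationPlan.from_totals(X, self.model.components.names)

    def _coerce_data(self, y) -> TitrationData:
        if isinstance(y, TitrationData):
            return y
        return TitrationData(np.atleast_2d(np.asarray(y, dtype=float)))

    def fit(self, X, y):
        """Fit the model; ``X`` is the totals matrix (additions x
        components, M) or a :class:`ConcentrationPlan`, ``y`` the observed
        signal matrix (additions x signals) with NaN for missing cells."""
        if self.model is None or self.parameterisation is None or self.observation is None:
            raise DomainError("model, parameterisation and observation are required")
        plan = self._coerce_plan(X)
        data = self._coerce_data(y)
        session = FitSession(
            self.model, self.parameterisation, self.observation, data, plan,
            weights=self.weights, nonnegative=self.nonnegative,
            penalty_factor=self.penalty_factor,
        )
        best = session.fit(maxfev=self.maxfev, restarts=self.restarts)
        if self.n_starts > 1:
            rng = np.random.default_rng(self.seed)
            for _ in range(self.n_starts - 1):
                theta0 = session.theta0 + rng.uniform(-1, 1, session.theta0.shape)
                cand = session.fit(theta0, maxfev=self.maxfev, restarts=self.restarts)
                if cand.rmse < best.rmse:
                    best = cand
        self.session_ = session
        self.result_ = best
        self.variable_values_ = best.variable_values
        self.spectra_ = best.X
        self.rmse_ = best.rmse
        self.speciation_ = best.speciation
        self.n_outer_evaluations_ = best.n_outer_evaluations
        self.converged_ = best.converged
        self.n_features_in_ = len(self.model.components)
        return self

    def predict(self, X):
        """Predicted signal matrix at the fitted parameters for new totals
        (or a plan; its unknowns are filled with the fitted values)."""
        if not hasattr(self, "result_"):
            raise ConvergenceError("fit the estimator first")
        plan = self._coerce_plan(X)
        res = self.result_
        all_values = {**res.fixed_values, **res.variable_values}
        beta = global_constants(self.parameterisation, {
            n: all_values[n] for n in self.parameterisation.variable_names
        })
        k2kn = self.parameterisation.polymer_k2_kn({
            n: all_values[n] for n in self.parameterisation.variable_names
        })
        polymers = tuple(
            (poly.component, k2, kn)
            for poly, (k2, kn) in zip(self.model.polymers, k2kn)
        )
        conc = {n: v for n, v in res.variable_values.items()
                if n not in self.parameterisation.variable_names}
        totals = totals_from_additions(plan.resolve(conc))
        session = self.session_
        M = session.M
        specs, warm = [], None
        for k in range(totals.shape[0]):
            r = solve_speciation(SpeciationProblem(totals[k], beta, M, polymers), warm)
            specs.append(r)
            warm = r.s
        A = state_concentration_matrix(specs, session.obs_map, self.model, totals)
        X_hat = np.nan_to_num(res.X)
        predicted = np.zeros((totals.shape[0], session.obs_map.n_signals))
        for block, sl in zip(session.obs_map.blocks, _block_slices(session.obs_map)):
            D = A[:, sl] @ block.R
            for sig in block.signal_indices:
                offset = np.zeros(totals.shape[0])
                for pos, values in block.known:
                    offset += A[:, sl][:, pos] * values[sig]
                predicted[:, sig] = offset + D @ X_hat[:, sig]
        return predicted


def fit(
    model: StoichiometryModel,
    parameterisation: EquilibriumParameterisation,
    observation: ObservationModel,
    data: TitrationData,
    plan: ConcentrationPlan,
    **options,
) -> FitResult:
    """Functional front end: build a :class:`TitrationFitter` and fit."""
    est = TitrationFitter(model, parameterisation, observation, **options)
    est.fit(plan, data)
    return est.result_
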