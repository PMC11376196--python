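"""Forward simulation of titration experiments with known ground truth.

A :class:`SimulationSpec` holds a fully specified system (model,
equilibrium parameterisation with true variable values, observation model,
concentration plan and true spectra); :func:`simulate_titration` runs the
forward model — speciation per addition, state matrix ``A``, signal matrix
``Y = A R X_true`` — and adds iid Gaussian noise per cell.  The packaged
scenarios mirror the study designs that motivate the fitting machinery:

``uv_1to1``
    Plain UV/vis 1:1 isotherm with a silent guest (K = 5000 M^-1, host at
    K*t = 0.5); the workhorse design for parameter-recovery experiments.
``uv_1to1_guest``
    UV/vis 1:1 binding where the free guest also absorbs, so three species
    contribute to each wavelength (K = 3800 M^-1, 0.047 mM host).
``nmr_1to2``
    Fast-exchange 1H NMR 1:2 isotherm with three signals of very different
    sensitivity to the second binding event (K1 = 328 M^-1,
    K2 = 34800 M^-2, 0.208 mM host).
``tight_1to2_stock``
    31P NMR 1:2 titration in the tight-binding regime (host >> 10/K;
    nominal stocks 1.11 mM host / 25.0 mM guest) where the true host stock
    differs from the nominal value by 16% and must be optimised.
``displacement_partial``
    Fluorescence displacement assay with two site types, only one of which
    binds the silent competitor; site concentrations are optimised.
``denaturation_network``
    Ten-species denaturation of a duplex by a competing solvent, with
    equilibrium constants tied to five independently measured values
    through statistical factors and exponents (including a squared
    denaturant constant), and chemical shifts constrained to two variables
    plus one independently measured dimer shift.

Gaussian iid noise per cell is the simulator's only error model;
instrument-specific noise, heteroscedasticity and baseline drift are out of
scope.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .data import ConcentrationPlan, TitrationData, totals_from_additions
from .exceptions import DomainError
from .fitting import (
    FitResult,
    FitSession,
    _block_slices,
    solve_linear_spectra,
    state_concentration_matrix,
)
from .model import (
    Complex,
    ComponentSet,
    EquilibriumParameterisation,
    ObservationModel,
    StoichiometryModel,
    Variable,
    build_observation_matrix_map,
    build_stoichiometry_matrix,
    global_constants,
)
from .speciation import SpeciationProblem, solve_speciation

__all__ = [
    "SimulationSpec",
    "Scenario",
    "simulate_titration",
    "fit_scenario",
    "recovery_experiment",
    "noiseless_signal_span",
    "make_scenario",
    "SCENARIOS",
]


@dataclass
class SimulationSpec:
    """A fully known system plus its true spectra and noise level.

    ``true_variables`` override the parameterisation's stored values;
    ``spectra`` is (n_spectral_variables x n_signals) in signal units;
    ``noise_sd`` is a scalar or per-signal Gaussian sigma in signal units.
    """

    model: StoichiometryModel
    parameterisation: EquilibriumParameterisation
    observation: ObservationModel
    plan: ConcentrationPlan
    true_variables: dict[str, float]
    spectra: np.ndarray
    signal_labels: tuple[str, ...]
    noise_sd: float | np.ndarray = 0.0
    seed: int = 0

    def __post_init__(self):
        self.spectra = np.atleast_2d(np.asarray(self.spectra, dtype=float))
        if np.any(np.asarray(self.noise_sd) < 0):
            raise DomainError("noise_sd must be >= 0")


@dataclass
class Scenario:
    """A simulation spec together with the fitting setup a user would
    apply to the simulated data: which variables are optimised (with
    realistic initial guesses) and which concentrations are flagged
    unknown."""

    name: str
    spec: SimulationSpec
    fit_parameterisation: EquilibriumParameterisation
    fit_plan: ConcentrationPlan
    description: str = ""
    fit_observation: ObservationModel | None = None

    @property
    def observation_for_fit(self) -> ObservationModel:
        return self.fit_observation or self.spec.observation


def simulate_titration(spec: SimulationSpec, seed: int | None = None):
    """Run the forward model and return ``(TitrationData, ground_truth)``.

    ``ground_truth`` records the generating variables, spectra, totals and
    per-addition speciation.  A fixed seed gives bitwise-reproducible data.
    """
    model, param = spec.model, spec.parameterisation
    values = {**param.default_values(), **spec.true_variables}
    beta = global_constants(param, values)
    k2kn = param.polymer_k2_kn(values)
    polymers = tuple(
        (poly.component, k2, kn) for poly, (k2, kn) in zip(model.polymers, k2kn)
    )
    totals = totals_from_additions(spec.plan)
    M = build_stoichiometry_matrix(model)
    obs_map = build_observation_matrix_map(spec.observation, model, spec.signal_labels)
    if spec.spectra.shape != (obs_map.n_variables, len(spec.signal_labels)):
        raise DomainError(
            f"spectra must be {(obs_map.n_variables, len(spec.signal_labels))}, "
            f"got {spec.spectra.shape}"
        )
    specs, warm = [], None
    for k in range(totals.shape[0]):
        res = solve_speciation(SpeciationProblem(totals[k], beta, M, polymers), warm)
        if not res.converged:
            raise DomainError(f"speciation failed at addition {k}: {res.message}")
        specs.append(res)
        warm = res.s
    A = state_concentration_matrix(specs, obs_map, model, totals)
    Y = np.zeros((totals.shape[0], len(spec.signal_labels)))
    for block, sl in zip(obs_map.blocks, _block_slices(obs_map)):
        D = A[:, sl] @ block.R
        for sig in block.signal_indices:
            offset = np.zeros(totals.shape[0])
            for pos, kv in block.known:
                offset += A[:, sl][:, pos] * kv[sig]
            Y[:, sig] = offset + D @ spec.spectra[:, sig]
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    sd = np.broadcast_to(np.asarray(spec.noise_sd, dtype=float), (len(spec.signal_labels),))
    noise = rng.standard_normal(Y.shape) * sd
    data = TitrationData(Y + noise, spec.signal_labels)
    ground_truth = {
        "variables": dict(values),
        "spectra": spec.spectra.copy(),
        "totals": totals,
        "noise_sd": np.array(sd),
        "speciation": specs,
        "noiseless_Y": Y,
    }
    return data, ground_truth


def fit_scenario(scenario: Scenario, data: TitrationData, **fit_kw) -> FitResult:
    """Fit simulated data with the scenario's fitting setup."""
    session = FitSession(
        scenario.spec.model,
        scenario.fit_parameterisation,
        scenario.observation_for_fit,
        data,
        scenario.fit_plan,
    )
    return session.fit(**fit_kw)


def recovery_experiment(
    scenario: Scenario,
    n_replicates: int,
    seed: int = 0,
    noise_sd: float | np.ndarray | None = None,
    **fit_kw,
) -> pd.DataFrame:
    """Repeatedly simulate and refit; summarise per-variable recovery.

    Returns a DataFrame indexed by variable with columns ``true``,
    ``median_rel_error`` (median |estimate - true| / true over replicates),
    ``max_rel_error`` and ``iqr_rel_error`` (inter-replicate spread).
    """
    if n_replicates < 2:
        raise DomainError("need at least 2 replicates")
    spec = scenario.spec
    if noise_sd is not None:
        spec = replace(copy.copy(spec), noise_sd=noise_sd)
    rng = np.random.default_rng(seed)
    sub_seeds = rng.integers(0, 2**31 - 1, size=n_replicates)
    truth = {**spec.parameterisation.default_values(), **spec.true_variables}
    rows: dict[str, list[float]] = {}
    for rep_seed in sub_seeds:
        data, _gt = simulate_titration(spec, seed=int(rep_seed))
        result = fit_scenario(scenario, data, **fit_kw)
        for name, value in result.variable_values.items():
            true = truth.get(name)
            if true is None:  # unknown concentration: truth from the generating plan
                true = _true_concentration(spec.plan, scenario.fit_plan, name)
            rows.setdefault(name, []).append(abs(value - true) / abs(true))
    records = []
    for name, errs in rows.items():
        errs = np.array(errs)
        true = truth.get(name)
        if true is None:
            true = _true_concentration(spec.plan, scenario.fit_plan, name)
        records.append({
            "variable": name,
            "true": true,
            "median_rel_error": float(np.median(errs)),
            "max_rel_error": float(errs.max()),
            "iqr_rel_error": float(np.subtract(*np.percentile(errs, [75, 25]))),
        })
    return pd.DataFrame.from_records(records).set_index("variable")


def _true_concentration(true_plan: ConcentrationPlan, fit_plan: ConcentrationPlan, name: str):
    """Ground-truth value of an unknown-concentration variable: the cell at
    the same position in the generating plan."""
    cells_fit = fit_plan._cells()
    cells_true = true_plan._cells()
    it = iter(fit_plan.unknown_variables())
    for (i, j), cell in np.ndenumerate(cells_fit):
        if cell.is_free:
            vname, _ = next(it)
            if vname == name:
                return cells_true[i, j].value
    raise DomainError(f"no ground truth for {name!r}")


# ---------------------------------------------------------------------------
# packaged scenarios
# ---------------------------------------------------------------------------


def _uv_1to1() -> Scenario:
    # The workhorse design: plain 1:1 binding with a silent guest, host
    # below 10/K (K*t_host = 0.5), guest to twenty equivalents, eight
    # wavelengths.  Used for parameter-recovery experiments.
    comps = ComponentSet(("H", "G"))
    model = StoichiometryModel(comps, (Complex("HG", (1, 1)),))
    param_true = EquilibriumParameterisation(
        (Variable("K1", "optimised", 5e3),), np.array([[1.0]])
    )
    obs = ObservationModel(exchange="slow", active_states=("H", "HG"))
    n_add = 15
    t_host = np.full(n_add, 1.0e-4)
    t_guest = np.concatenate([[0.0], np.geomspace(2e-5, 2e-3, n_add - 1)])
    plan = ConcentrationPlan.from_totals(np.column_stack([t_host, t_guest]), comps.names)
    signals = tuple(f"w{i}" for i in range(8))
    spectra = np.array([  # molar absorption coefficients, rows H / HG
        [12400.0, 9800.0, 7000.0, 4600.0, 2900.0, 1700.0, 900.0, 380.0],
        [6200.0, 8900.0, 9100.0, 7600.0, 5400.0, 3300.0, 1750.0, 700.0],
    ])
    spec = SimulationSpec(model, param_true, obs, plan, {"K1": 5e3},
                          spectra, signals, noise_sd=0.0, seed=0)
    fit_param = EquilibriumParameterisation(
        (Variable("K1", "optimised", 1e3),), np.array([[1.0]])
    )
    return Scenario("uv_1to1", spec, fit_param, plan,
                    "plain UV/vis 1:1 isotherm with a silent guest")


def noiseless_signal_span(spec: SimulationSpec) -> np.ndarray:
    """Per-signal total change of the noiseless forward model — the
    natural scale for expressing noise as a fraction of the signal."""
    noiseless = replace(copy.copy(spec), noise_sd=0.0)
    _data, truth = simulate_titration(noiseless)
    Y = truth["noiseless_Y"]
    return Y.max(axis=0) - Y.min(axis=0)


def _uv_1to1_guest() -> Scenario:
    # 1:1 complex; host, complex and free guest all absorb.  Constants from
    # a weak amide / phosphine-oxide system: K = 3800 M^-1, 0.047 mM host.
    comps = ComponentSet(("H", "G"))
    model = StoichiometryModel(comps, (Complex("HG", (1, 1)),))
    param_true = EquilibriumParameterisation(
        (Variable("K1", "optimised", 3800.0),), np.array([[1.0]])
    )
    obs = ObservationModel(
        exchange="slow", active_states=("H", "G", "HG"), nonnegative=False
    )
    n_add = 15
    t_host = np.full(n_add, 4.7e-5)
    t_guest = np.concatenate([[0.0], np.geomspace(5e-5, 8e-3, n_add - 1)])
    plan = ConcentrationPlan.from_totals(
        np.column_stack([t_host, t_guest]), comps.names
    )
    signals = ("A300", "A320", "A340", "A360")
    # molar absorption coefficients (M^-1 cm^-1): rows H, G, HG
    spectra = np.array([
        [9000.0, 12000.0, 6000.0, 1500.0],
        [220.0, 90.0, 25.0, 4.0],  # weak guest tail, large total concentration
        [4000.0, 9500.0, 11000.0, 5200.0],
    ])
    spec = SimulationSpec(model, param_true, obs, plan, {"K1": 3800.0},
                          spectra, signals, noise_sd=0.0, seed=0)
    fit_param = EquilibriumParameterisation(
        (Variable("K1", "optimised", 1000.0),), np.array([[1.0]])
    )
    return Scenario("uv_1to1_guest", spec, fit_param, plan,
                    "UV/vis 1:1 isotherm with an absorbing guest")


def _nmr_1to2() -> Scenario:
    # 1:2 isotherm, fast exchange, three 1H signals; the third signal is
    # dominated by the second binding event.  K1 = 328 M^-1, K2 = 34800 M^-2.
    comps = ComponentSet(("H", "G"))
    model = StoichiometryModel(comps, (Complex("HG", (1, 1)), Complex("HG2", (1, 2))))
    param_true = EquilibriumParameterisation(
        (Variable("K1", "optimised", 328.0), Variable("K2", "optimised", 34800.0)),
        np.eye(2),
    )
    obs = ObservationModel(exchange="fast", active_states=("H", "HG", "HG2"),
                           reference="H")
    n_add = 18
    t_host = np.full(n_add, 2.08e-4)
    t_guest = np.concatenate([[0.0], np.geomspace(2e-4, 1.2e-1, n_add - 1)])
    plan = ConcentrationPlan.from_totals(np.column_stack([t_host, t_guest]), comps.names)
    signals = ("NH", "ArH6", "ArH2")
    # chemical shifts (ppm): rows free H, HG, HG2
    spectra = np.array([
        [7.10, 6.80, 7.45],
        [8.35, 7.12, 7.47],  # first binding event moves NH/ArH6 strongly
        [8.55, 7.18, 7.29],  # ArH2 mostly reports the second event
    ])
    spec = SimulationSpec(model, param_true, obs, plan,
                          {"K1": 328.0, "K2": 34800.0}, spectra, signals,
                          noise_sd=0.001, seed=0)
    fit_param = EquilibriumParameterisation(
        (Variable("K1", "optimised", 100.0), Variable("K2", "optimised", 10000.0)),
        np.eye(2),
    )
    return Scenario("nmr_1to2", spec, fit_param, plan,
                    "fast-exchange NMR 1:2 isotherm")


def _tight_1to2_stock() -> Scenario:
    # Tight-binding 31P titration: host ~ 1 mM >> 10/K.  The true host
    # stock (0.95 mM) is 16% below the nominal weighed-in value (1.11 mM);
    # the fit plan flags it "~1.11e-3" for optimisation.
    comps = ComponentSet(("H", "G"))
    model = StoichiometryModel(comps, (Complex("HG", (1, 1)), Complex("HG2", (1, 2))))
    param_true = EquilibriumParameterisation(
        (Variable("K1", "optimised", 2.76e4), Variable("K2", "optimised", 1.51e5)),
        np.eye(2),
    )
    obs = ObservationModel(exchange="fast", active_states=("H", "HG", "HG2"),
                           reference="H")
    # stocks mode: cell starts with 0.6 mL of host stock; 22 guest aliquots
    # — fine through the turning point, then coarse to high equivalents so
    # the weak second binding event (K2/K1 ~ 5 M^-1) is populated
    n_add = 23
    true_host_stock, guest_stock = 0.95e-3, 25.0e-3
    stocks_true = [[true_host_stock, 0.0], [0.0, guest_stock]]
    volumes = np.zeros((n_add, 2))
    volumes[0, 0] = 6.0e-4
    volumes[1:, 1] = np.concatenate([
        np.full(12, 2.5e-6),  # fine steps through the turning point
        np.full(6, 2.0e-5),
        np.full(4, 2.0e-4),
    ])
    plan_true = ConcentrationPlan.from_stocks(stocks_true, volumes, comps.names,
                                              ("host", "guest"))
    signals = ("P31",)
    spectra = np.array([[25.0], [31.5], [33.2]])  # ppm: free, HG, HG2
    spec = SimulationSpec(model, param_true, obs, plan_true,
                          {"K1": 2.76e4, "K2": 1.51e5}, spectra, signals,
                          noise_sd=0.003, seed=0)
    fit_param = EquilibriumParameterisation(
        (Variable("K1", "optimised", 1e4), Variable("K2", "optimised", 1e5)),
        np.eye(2),
    )
    fit_plan = ConcentrationPlan.from_stocks(
        [["~1.11e-3", 0.0], [0.0, guest_stock]], volumes, comps.names, ("host", "guest")
    )
    return Scenario("tight_1to2_stock", spec, fit_param, fit_plan,
                    "tight-binding 1:2 titration with the host stock optimised")


def _displacement_partial() -> Scenario:
    # Fluorescence displacement assay: reporter ligand A (fluorescent when
    # bound) on two site types P (binds A and the silent competitor B) and
    # Q (binds only A).  K_A fixed from an independent titration; K_B and
    # both site concentrations optimised.
    comps = ComponentSet(("P", "Q", "A", "B"))
    model = StoichiometryModel(comps, (
        Complex("PA", (1, 0, 1, 0)),
        Complex("QA", (0, 1, 1, 0)),
        Complex("PB", (1, 0, 0, 1)),
    ))
    k_a, k_b = 5.0e7, 2.3e7
    variables = (
        Variable("KA", "fixed", k_a),
        Variable("KB", "optimised", k_b),
    )
    E = np.array([[1.0, 1.0, 0.0], [0.0, 0.0, 1.0]])
    param_true = EquilibriumParameterisation(variables, E)
    # bound-reporter emission shared between the two site types; free A
    # emission fixed from an independent measurement
    obs = ObservationModel(
        exchange="slow",
        active_states=("A", "PA", "QA"),
        relationships={"PA": {"eps_bound": 1.0}, "QA": {"eps_bound": 1.0}},
        known_spectra={"A": (1.2e6,)},
    )
    n_add = 16
    sites_p, sites_q = 53.7e-12, 27.6e-12  # 66% / 34% of 81.3 pM
    signals = ("F483",)
    spectra = np.array([[5.0e13]])  # molar emission of the bound reporter
    fit_param = EquilibriumParameterisation(
        (Variable("KA", "fixed", k_a), Variable("KB", "optimised", 1e7)), E
    )
    # the cell holds sites + reporter; a concentrated competitor stock is
    # titrated in (the mild dilution of the background is bookkept exactly)
    volumes = np.zeros((n_add, 2))
    volumes[0, 0] = 1.0e-3
    cumulative = np.geomspace(1e-6, 1.5e-4, n_add - 1)
    volumes[1:, 1] = np.diff(cumulative, prepend=0.0)
    b_stock = 1.5e-5
    plan_true = ConcentrationPlan.from_stocks(
        [[sites_p, sites_q, 1.0e-6, 0.0], [0.0, 0.0, 0.0, b_stock]],
        volumes, comps.names, ("cell", "titrant"),
    )
    fit_plan = ConcentrationPlan.from_stocks(
        [["~6e-11", "~3e-11", 1.0e-6, 0.0], [0.0, 0.0, 0.0, b_stock]],
        volumes, comps.names, ("cell", "titrant"),
    )
    spec = SimulationSpec(model, param_true, obs, plan_true,
                          {"KB": k_b}, spectra, signals, noise_sd=0.5, seed=0)
    return Scenario("displacement_partial", spec, fit_param, fit_plan,
                    "fluorescence displacement assay with partial sites")


def _denaturation_network() -> Scenario:
    # Duplex A.D denatured by solvent S.  Ten stoichiometric species (two
    # free + eight complexes); constants tied to five independently
    # measured values (Ks, K1h, K2h, Ka2, Kd2) plus the one optimised
    # duplex constant Kad.  A makes two acceptor contacts (observed 31P)
    # and one donor; D has two donors and one acceptor.
    comps = ComponentSet(("A", "D", "S"))
    model = StoichiometryModel(comps, (
        Complex("AD", (1, 1, 0)),     # duplex, fully bound
        Complex("ADS", (1, 1, 1)),    # partially denatured (one contact broken)
        Complex("ADS2", (1, 1, 2)),   # singly H-bonded duplex, two S bound
        Complex("AS", (1, 0, 1)),     # S on A's donor site
        Complex("DS", (0, 1, 1)),
        Complex("DS2", (0, 1, 2)),
        Complex("A2", (2, 0, 0)),
        Complex("D2", (0, 2, 0)),
    ))
    variables = (
        Variable("Kad", "optimised", 2150.0),
        Variable("Ks", "fixed", 5.0),       # solvent on one donor, M^-1
        Variable("K1h", "fixed", 40.0),     # duplex with one contact, M^-1
        Variable("K2h", "fixed", 400.0),    # duplex with two contacts, M^-1
        Variable("Ka2", "fixed", 20.0),     # A self-dimerisation, M^-1
        Variable("Kd2", "fixed", 15.0),     # D self-dimerisation, M^-1
    )
    #               AD  ADS  ADS2  AS   DS  DS2  A2   D2
    E = np.array([
        [1.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0],  # Kad
        [0.0, 1.0, 2.0, 1.0, 1.0, 2.0, 0.0, 0.0],  # Ks (squared for ADS2, DS2)
        [0.0, 0.0, 1.0, 0.0, 0.0, 0.0, 0.0, 0.0],  # K1h
        [0.0, 1.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0],  # K2h
        [0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 1.0, 0.0],  # Ka2
        [0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 1.0],  # Kd2
    ])
    # degenerate binding modes absorbed as statistical factors
    sf = np.array([1.0, 2.0, 1.0, 1.0, 2.0, 1.0, 1.0, 1.0])
    param_true = EquilibriumParameterisation(variables, E, sf)
    # 31P of A (two acceptor P=O groups), fast exchange; shifts of every
    # species are population-weighted mixes of delta_f / delta_b except the
    # independently measured dimer shift.
    obs = ObservationModel(
        exchange="fast",
        active_states=("A", "AD", "ADS", "ADS2", "AS", "A2"),
        reference="A",
        relationships={
            "A": {"delta_f": 1.0},
            "AS": {"delta_f": 1.0},
            "AD": {"delta_b": 1.0},
            "ADS": {"delta_f": 0.5, "delta_b": 0.5},
            "ADS2": {"delta_f": 1.0},
        },
        known_spectra={"A2": (29.1,)},
    )
    n_add = 20
    t_a = np.full(n_add, 1.0e-3)
    t_d = np.full(n_add, 1.0e-3)
    t_s = np.concatenate([[0.0], np.geomspace(5e-3, 2.5, n_add - 1)])
    plan = ConcentrationPlan.from_totals(np.column_stack([t_a, t_d, t_s]), comps.names)
    signals = ("P31_A",)
    spectra = np.array([[24.8], [32.6]])  # delta_f, delta_b (ppm)
    spec = SimulationSpec(model, param_true, obs, plan, {"Kad": 2150.0},
                          spectra, signals, noise_sd=0.004, seed=0)
    fit_variables = tuple(
        Variable(v.name, v.role, 500.0 if v.name == "Kad" else v.value)
        for v in variables
    )
    fit_param = EquilibriumParameterisation(fit_variables, E, sf)
    return Scenario("denaturation_network", spec, fit_param, plan,
                    "ten-species duplex denaturation with tied constants and spectra")


SCENARIOS = {
    "uv_1to1": _uv_1to1,
    "uv_1to1_guest": _uv_1to1_guest,
    "nmr_1to2": _nmr_1to2,
    "tight_1to2_stock": _tight_1to2_stock,
    "displacement_partial": _displacement_partial,
    "denaturation_network": _denaturation_network,
}


def make_scenario(name: str, **overrides) -> Scenario:
    """Instantiate a packaged scenario by name; keyword overrides replace
    SimulationSpec fields (e.g. ``noise_sd=0.0``, ``seed=7``)."""
    try:
        factory = SCENARIOS[name]
    except KeyError:
        raise DomainError(
            f"unknown scenario {name!r}; available: {', '.join(sorted(SCENARIOS))}"
        ) from None
    scenario = factory()
    if overrides:
        scenario.spec = replace(copy.copy(scenario.spec), **overrides)
    return scenario
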