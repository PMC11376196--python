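"""Declarative description of multi-component binding equilibria.

A chemical system is described by three orthogonal pieces:

* :class:`StoichiometryModel` — which species exist.  Free components (e.g.
  host ``H`` and guest ``G``) combine into complexes, each given by a vector
  of non-negative integer stoichiometric coefficients; stacking those vectors
  as columns gives the stoichiometry matrix ``M`` (components x complexes).
  Self-assembled polymers of a single component are declared separately,
  since a chain species exists for every length ``n >= 2``.

* :class:`EquilibriumParameterisation` — how the global association
  constants beta_j (for forming complex j directly from free components) are
  generated from a smaller set of variables.  Each beta_j is a statistical
  factor sigma_j times a product of variables raised to per-complex
  exponents::

      beta_j = sigma_j * prod_k  v_k ** e[k, j]

  This covers microscopic constants with statistical factors (the
  non-cooperative model), effective molarities, and constants fixed from
  independent experiments (``role="fixed"``).  Exponents may be negative or
  fractional, which is needed to express, e.g., squared denaturant binding
  constants or effective molarities.  Polymers carry a dimerisation constant
  K2 and an elongation constant Kn; the isodesmic model ties them to a
  single shared variable.

* :class:`ObservationModel` — which species are spectroscopically active and
  how their spectra relate.  Under slow exchange (and for UV/vis or
  fluorescence) the observed signal is a concentration-weighted sum of state
  spectra; under fast exchange (NMR) each signal reports the
  population-weighted average chemical shift over the states of its
  reference component.  Spectra of different states may be tied together by
  linear relationships (rows of the matrix ``R``), e.g. the additive model
  where every binding event causes the same spectral change.
"""

from __future__ import annotations

import math
from collections.abc import Mapping, Sequence
from dataclasses import dataclass, field

import numpy as np

from .exceptions import DomainError, ModelDefinitionError, RankDeficiencyError

__all__ = [
    "ComponentSet",
    "Complex",
    "Polymer",
    "StoichiometryModel",
    "Variable",
    "PolymerConstants",
    "EquilibriumParameterisation",
    "ObservationModel",
    "SignalBlock",
    "ObservationMap",
    "build_stoichiometry_matrix",
    "build_observation_matrix_map",
    "global_constants",
    "noncooperative_betas",
    "noncooperative_model",
    "additive_relationships",
]


# ---------------------------------------------------------------------------
# stoichiometry
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ComponentSet:
    """Ordered, unique labels for the free components of the system."""

    names: tuple[str, ...]

    def __post_init__(self):
        names = tuple(self.names)
        object.__setattr__(self, "names", names)
        if len(names) == 0:
            raise ModelDefinitionError("a system needs at least one component")
        if any(not n for n in names):
            raise ModelDefinitionError("component names must be non-empty")
        if len(set(names)) != len(names):
            raise ModelDefinitionError(f"duplicate component names in {names}")

    def __len__(self):
        return len(self.names)

    def index(self, name: str) -> int:
        try:
            return self.names.index(name)
        except ValueError:
            raise ModelDefinitionError(f"unknown component {name!r}") from None


@dataclass(frozen=True)
class Complex:
    """One complex species: a label and its stoichiometric coefficients
    (one non-negative integer per component, in component order)."""

    label: str
    coefficients: tuple[int, ...]

    def __post_init__(self):
        coeff = tuple(int(c) for c in self.coefficients)
        object.__setattr__(self, "coefficients", coeff)
        if any(c < 0 for c in coeff):
            raise ModelDefinitionError(f"negative coefficient in complex {self.label!r}")
        if sum(coeff) < 1:
            raise ModelDefinitionError(f"complex {self.label!r} contains no components")


@dataclass(frozen=True)
class Polymer:
    """A homopolymer of one component, declared with stoichiometry "n".

    Chains of every length n >= 2 exist; their concentrations follow from a
    dimerisation constant K2 and an elongation constant Kn (see
    :mod:`titrakit.speciation`).  ``isodesmic=True`` ties K2 and Kn to one
    shared variable.
    """

    label: str
    component: int
    isodesmic: bool = False


@dataclass(frozen=True)
class StoichiometryModel:
    components: ComponentSet
    complexes: tuple[Complex, ...] = ()
    polymers: tuple[Polymer, ...] = ()

    def __post_init__(self):
        object.__setattr__(self, "complexes", tuple(self.complexes))
        object.__setattr__(self, "polymers", tuple(self.polymers))
        n = len(self.components)
        seen_cols: set[tuple[int, ...]] = set()
        labels = set(self.components.names)
        for cplx in self.complexes:
            if len(cplx.coefficients) != n:
                raise ModelDefinitionError(
                    f"complex {cplx.label!r} has {len(cplx.coefficients)} "
                    f"coefficients for {n} components"
                )
            if cplx.coefficients in seen_cols:
                raise ModelDefinitionError(
                    f"duplicate stoichiometry column for complex {cplx.label!r}"
                )
            seen_cols.add(cplx.coefficients)
            if cplx.label in labels:
                raise ModelDefinitionError(f"duplicate species label {cplx.label!r}")
            labels.add(cplx.label)
        for poly in self.polymers:
            if not 0 <= poly.component < n:
                raise ModelDefinitionError(f"polymer {poly.label!r}: bad component index")
            if poly.label in labels:
                raise ModelDefinitionError(f"duplicate species label {poly.label!r}")
            labels.add(poly.label)

    # convenience -----------------------------------------------------------
    @property
    def n_components(self) -> int:
        return len(self.components)

    @property
    def n_complexes(self) -> int:
        return len(self.complexes)

    @property
    def complex_labels(self) -> tuple[str, ...]:
        return tuple(c.label for c in self.complexes)

    def species_labels(self) -> tuple[str, ...]:
        """Deterministic global state ordering: free components first (in
        component order), then complexes (declaration order), then polymers."""
        return (
            self.components.names
            + self.complex_labels
            + tuple(p.label for p in self.polymers)
        )

    def stoichiometry_of(self, label: str) -> np.ndarray:
        """Component-count vector of any species (free, complex or polymer
        — a polymer counts as its repeat unit for observation purposes)."""
        if label in self.components.names:
            v = np.zeros(self.n_components)
            v[self.components.index(label)] = 1
            return v
        for cplx in self.complexes:
            if cplx.label == label:
                return np.asarray(cplx.coefficients, dtype=float)
        for poly in self.polymers:
            if poly.label == label:
                v = np.zeros(self.n_components)
                v[poly.component] = 1
                return v
        raise ModelDefinitionError(f"unknown species {label!r}")


def build_stoichiometry_matrix(model: StoichiometryModel) -> np.ndarray:
    """Return the integer matrix ``M`` (components x complexes); column j is
    complex j's coefficient vector.  Polymers are not columns of ``M``."""
    M = np.zeros((model.n_components, model.n_complexes), dtype=int)
    for j, cplx in enumerate(model.complexes):
        M[:, j] = cplx.coefficients
    return M


# ---------------------------------------------------------------------------
# equilibrium-constant parameterisation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Variable:
    """A (possibly shared) positive fitting variable.

    ``value`` is the fixed value when ``role == "fixed"``, otherwise the
    initial guess for the outer optimisation.  Units are implied by the
    exponents that use the variable.
    """

    name: str
    role: str = "optimised"  # "optimised" | "fixed"
    value: float = 1.0

    def __post_init__(self):
        if self.role not in ("optimised", "fixed"):
            raise ModelDefinitionError(f"variable {self.name!r}: bad role {self.role!r}")
        if not (self.value > 0 and math.isfinite(self.value)):
            raise ModelDefinitionError(f"variable {self.name!r}: value must be positive")


@dataclass(frozen=True)
class PolymerConstants:
    """Names of the variables supplying K2 (dimerisation, M^-1) and Kn
    (elongation, M^-1) for one polymer; identical names mean the two
    constants are one shared variable (isodesmic)."""

    k2_variable: str
    kn_variable: str

    @property
    def tied(self) -> bool:
        return self.k2_variable == self.kn_variable


@dataclass(frozen=True)
class EquilibriumParameterisation:
    """Map from free variables to global constants.

    ``exponents`` has shape (n_variables, n_complexes);
    ``statistical_factors`` has shape (n_complexes,) and defaults to ones.
    """

    variables: tuple[Variable, ...]
    exponents: np.ndarray = field(default_factory=lambda: np.zeros((0, 0)))
    statistical_factors: np.ndarray | None = None
    polymer_constants: tuple[PolymerConstants, ...] = ()

    def __post_init__(self):
        object.__setattr__(self, "variables", tuple(self.variables))
        names = [v.name for v in self.variables]
        if len(set(names)) != len(names):
            raise ModelDefinitionError("duplicate variable names")
        E = np.atleast_2d(np.asarray(self.exponents, dtype=float))
        if E.size == 0:
            E = E.reshape(len(self.variables), 0)
        if E.shape[0] != len(self.variables):
            raise ModelDefinitionError(
                f"exponent matrix has {E.shape[0]} rows for {len(self.variables)} variables"
            )
        object.__setattr__(self, "exponents", E)
        sf = self.statistical_factors
        sf = np.ones(E.shape[1]) if sf is None else np.asarray(sf, dtype=float)
        if sf.shape != (E.shape[1],):
            raise ModelDefinitionError("statistical_factors shape mismatch")
        if np.any(sf <= 0):
            raise ModelDefinitionError("statistical factors must be positive")
        object.__setattr__(self, "statistical_factors", sf)
        object.__setattr__(self, "polymer_constants", tuple(self.polymer_constants))
        for pc in self.polymer_constants:
            for nm in (pc.k2_variable, pc.kn_variable):
                if nm not in names:
                    raise ModelDefinitionError(f"polymer constant references unknown variable {nm!r}")

    @property
    def variable_names(self) -> tuple[str, ...]:
        return tuple(v.name for v in self.variables)

    def values_array(self, values: Mapping[str, float] | Sequence[float]) -> np.ndarray:
        """Coerce a dict or sequence of variable values into variable order."""
        if isinstance(values, Mapping):
            try:
                arr = np.array([values[v.name] for v in self.variables], dtype=float)
            except KeyError as exc:
                raise DomainError(f"missing value for variable {exc.args[0]!r}") from None
        else:
            arr = np.asarray(values, dtype=float)
            if arr.shape != (len(self.variables),):
                raise DomainError(
                    f"expected {len(self.variables)} variable values, got {arr.shape}"
                )
        if np.any(~np.isfinite(arr)) or np.any(arr <= 0):
            raise DomainError("variable values must be positive and finite")
        return arr

    def default_values(self) -> dict[str, float]:
        return {v.name: v.value for v in self.variables}

    def polymer_k2_kn(self, values: Mapping[str, float] | Sequence[float]):
        """Per-polymer (K2, Kn) values, in M^-1."""
        arr = self.values_array(values)
        lookup = dict(zip(self.variable_names, arr))
        return [(lookup[pc.k2_variable], lookup[pc.kn_variable]) for pc in self.polymer_constants]


def global_constants(
    param: EquilibriumParameterisation,
    values: Mapping[str, float] | Sequence[float],
) -> np.ndarray:
    """Global association constants ``beta_j = sigma_j * prod_k v_k**e_kj``.

    Units of beta_j are M**(1 - sum_i M_ij) by construction.  Computed in log
    space so large constants and large exponents do not overflow.
    """
    v = param.values_array(values)
    E = param.exponents
    log_beta = np.log(param.statistical_factors) + np.log(v) @ E
    return np.exp(log_beta)


def noncooperative_betas(n_sites: int, k_micro: float) -> np.ndarray:
    """Global constants of the non-cooperative model for a host with
    ``n_sites`` independent, identical guest sites:
    ``beta_k = C(n_sites, k) * k_micro**k`` for k = 1..n_sites.

    The statistical factors are binomial coefficients (number of ways to
    choose the occupied sites); at n_sites=2 this gives (2 K, K**2).
    """
    if n_sites < 1:
        raise DomainError("n_sites must be >= 1")
    if not k_micro > 0:
        raise DomainError("k_micro must be positive")
    k = np.arange(1, n_sites + 1)
    comb = np.array([math.comb(n_sites, int(i)) for i in k], dtype=float)
    return comb * k_micro ** k.astype(float)


def noncooperative_model(
    host: str,
    guest: str,
    n_sites: int,
    *,
    k_micro_name: str = "Kmicro",
    role: str = "optimised",
    value: float = 1.0,
) -> tuple[StoichiometryModel, EquilibriumParameterisation]:
    """Build the full non-cooperative host-guest model: complexes HG..HG_n,
    one microscopic-constant variable, binomial statistical factors."""
    comps = ComponentSet((host, guest))
    complexes = tuple(
        Complex(f"{host}{guest}" + (str(k) if k > 1 else ""), (1, k))
        for k in range(1, n_sites + 1)
    )
    model = StoichiometryModel(comps, complexes)
    exponents = np.arange(1, n_sites + 1, dtype=float)[None, :]
    factors = np.array([math.comb(n_sites, k) for k in range(1, n_sites + 1)], dtype=float)
    param = EquilibriumParameterisation(
        (Variable(k_micro_name, role, value),), exponents, factors
    )
    return model, param


# ---------------------------------------------------------------------------
# observation model
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ObservationModel:
    """Which states are spectroscopically active and how their spectra relate.

    Parameters
    ----------
    exchange : "slow" or "fast"
        Slow exchange (and UV/vis, fluorescence): the observed signal is the
        concentration-weighted sum over active states.  Fast exchange (NMR):
        each signal is the population-weighted average shift over the states
        of its reference component.
    active_states : species labels contributing to the signals.
    signals : optional signal labels (defaults to data column labels).
    reference : fast exchange only — the component whose populations a
        signal reports: either one component label for all signals or a
        mapping signal label -> component label.
    relationships : ``None`` (every unknown state gets its own spectral
        variable), the preset string ``"additive"`` (see
        :func:`additive_relationships`; requires ``additive_host``), or a
        mapping ``state -> {variable: weight}`` giving each state's spectrum
        as a linear combination of named spectral variables.
    known_spectra : mapping state -> per-signal spectrum row fixed from
        independent experiments; those states contribute a known offset and
        are removed from the variable set.
    nonnegative : solve the spectra under a non-negativity constraint
        (meaningful for UV/vis absorbances).
    signal_states : optional mapping signal label -> tuple of state labels
        when different signals see different states ("custom, different per
        signal"); states not listed default to ``active_states``.
    """

    exchange: str = "slow"
    active_states: tuple[str, ...] = ()
    signals: tuple[str, ...] | None = None
    reference: Mapping[str, str] | str | None = None
    relationships: Mapping[str, Mapping[str, float]] | str | None = None
    known_spectra: Mapping[str, Sequence[float]] = field(default_factory=dict)
    nonnegative: bool = False
    additive_host: str | None = None
    signal_states: Mapping[str, tuple[str, ...]] | None = None

    def __post_init__(self):
        if self.exchange not in ("slow", "fast"):
            raise ModelDefinitionError(f"exchange must be 'slow' or 'fast', got {self.exchange!r}")
        object.__setattr__(self, "active_states", tuple(self.active_states))
        if self.signals is not None:
            object.__setattr__(self, "signals", tuple(self.signals))
        if self.exchange == "fast" and self.reference is None:
            raise ModelDefinitionError("fast exchange requires a reference component per signal")


def additive_relationships(
    model: StoichiometryModel, host: str, states: Sequence[str]
) -> dict[str, dict[str, float]]:
    """The additive spectral model: every binding event causes the same
    spectral change, so a host complex with k bound ligands has spectrum
    ``spectrum(free host) + k * delta``.  Only two spectral variables are
    produced regardless of the number of sites; non-host states keep their
    own variables.
    """
    host_idx = model.components.index(host)
    rel: dict[str, dict[str, float]] = {}
    for label in states:
        v = model.stoichiometry_of(label)
        if v[host_idx] > 0:
            bound = float(v.sum() - v[host_idx])
            rel[label] = {host: v[host_idx] * 1.0, "delta": bound}
        else:
            rel[label] = {label: 1.0}
    return rel


@dataclass
class SignalBlock:
    """One group of signals sharing a state list and design.

    ``R`` is (n_states x n_variables) over the global spectral-variable
    ordering; rows of known-spectrum states are zero, and their fixed values
    are carried in ``known`` as (state_position, per-signal values).
    """

    signal_indices: list[int]
    states: list[str]
    ref_component: int | None
    R: np.ndarray
    known: list[tuple[int, np.ndarray]]


@dataclass
class ObservationMap:
    """Deterministic index bookkeeping binding an ObservationModel to a
    StoichiometryModel: global spectral variables, and per-signal blocks."""

    variable_names: list[str]
    blocks: list[SignalBlock]
    exchange: str
    nonnegative: bool
    signals: tuple[str, ...]

    @property
    def n_variables(self) -> int:
        return len(self.variable_names)

    @property
    def n_signals(self) -> int:
        return len(self.signals)


def _ordered_states(model: StoichiometryModel, wanted: Sequence[str]) -> list[str]:
    order = model.species_labels()
    wanted_set = set(wanted)
    unknown = wanted_set - set(order)
    if unknown:
        raise ModelDefinitionError(f"active states not in model: {sorted(unknown)}")
    return [s for s in order if s in wanted_set]


def build_observation_matrix_map(
    obs: ObservationModel,
    model: StoichiometryModel,
    signals: Sequence[str] | None = None,
) -> ObservationMap:
    """Resolve an :class:`ObservationModel` against a model: order the
    states deterministically, expand relationship presets, build the
    relationship matrix ``R`` and verify it has full column rank.
    """
    signal_labels = tuple(signals if signals is not None else (obs.signals or ()))
    if not signal_labels:
        raise ModelDefinitionError("no signals declared")
    n_signals = len(signal_labels)

    # resolve per-signal state lists ---------------------------------------
    def states_for(sig: str) -> list[str]:
        if obs.signal_states and sig in obs.signal_states:
            return _ordered_states(model, obs.signal_states[sig])
        return _ordered_states(model, obs.active_states)

    # group signals with identical state lists + reference
    def ref_for(sig: str) -> int | None:
        if obs.exchange != "fast":
            return None
        ref = obs.reference
        name = ref if isinstance(ref, str) else ref.get(sig) if ref else None
        if name is None:
            raise ModelDefinitionError(f"signal {sig!r}: no reference component declared")
        return model.components.index(name)

    groups: dict[tuple, list[int]] = {}
    for i, sig in enumerate(signal_labels):
        key = (tuple(states_for(sig)), ref_for(sig))
        groups.setdefault(key, []).append(i)

    # fast-exchange coverage check: the states of a signal must account for
    # every species containing the reference component
    M = build_stoichiometry_matrix(model)
    for (states, ref), _idx in groups.items():
        if ref is None:
            continue
        containing = {model.components.names[ref]}
        containing.update(
            cplx.label for j, cplx in enumerate(model.complexes) if M[ref, j] > 0
        )
        containing.update(p.label for p in model.polymers if p.component == ref)
        missing = containing - set(states)
        if missing:
            raise ModelDefinitionError(
                f"fast-exchange states do not cover the reference component's "
                f"total concentration; missing {sorted(missing)}"
            )

    # resolve relationships -------------------------------------------------
    all_states: list[str] = []
    for (states, _ref) in groups:
        for s in states:
            if s not in all_states:
                all_states.append(s)
    all_states = _ordered_states(model, all_states)

    known = dict(obs.known_spectra)
    for state, row in known.items():
        if state not in all_states:
            raise ModelDefinitionError(f"known spectrum for inactive state {state!r}")
        if np.asarray(row, dtype=float).shape != (n_signals,):
            raise ModelDefinitionError(
                f"known spectrum for {state!r} must have one value per signal"
            )

    if obs.relationships == "additive":
        if obs.additive_host is None:
            raise ModelDefinitionError("additive preset requires additive_host")
        rel = additive_relationships(model, obs.additive_host, all_states)
    elif obs.relationships is None:
        rel = {s: {s: 1.0} for s in all_states}
    elif isinstance(obs.relationships, str):
        raise ModelDefinitionError(f"unknown relationships preset {obs.relationships!r}")
    else:
        rel = {s: dict(obs.relationships[s]) for s in all_states if s in obs.relationships}
        missing = [s for s in all_states if s not in rel and s not in known]
        for s in missing:  # unrelated states keep their own variable
            rel[s] = {s: 1.0}

    # global variable ordering: first appearance over ordered states
    variable_names: list[str] = []
    for s in all_states:
        if s in known:
            continue
        for vname in rel.get(s, {}):
            if vname not in variable_names:
                variable_names.append(vname)

    def r_row(state: str) -> np.ndarray:
        row = np.zeros(len(variable_names))
        if state in known:
            return row
        for vname, w in rel.get(state, {}).items():
            row[variable_names.index(vname)] = float(w)
        return row

    blocks = []
    for (states, ref), idx in groups.items():
        states = list(states)
        R = np.array([r_row(s) for s in states]).reshape(len(states), len(variable_names))
        known_rows = [
            (pos, np.asarray(known[s], dtype=float))
            for pos, s in enumerate(states)
            if s in known
        ]
        blocks.append(SignalBlock(idx, states, ref, R, known_rows))

    # full-column-rank requirement on the stacked relationship matrix
    if variable_names:
        R_all = np.vstack([b.R for b in blocks])
        rank = np.linalg.matrix_rank(R_all)
        if rank < len(variable_names):
            # name the variables in the null space
            _u, sv, vt = np.linalg.svd(R_all)
            null = vt[rank:]
            bad = [
                variable_names[k]
                for k in range(len(variable_names))
                if np.any(np.abs(null[:, k]) > 1e-10)
            ]
            raise RankDeficiencyError(bad or ("<all>",))
    return ObservationMap(variable_names, blocks, obs.exchange, obs.nonnegative, signal_labels)
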