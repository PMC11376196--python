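"""Readers and writers.

File conventions (fixed, no locale sniffing): comma-separated UTF-8 CSV
with "." as the decimal point; concentrations in molar, volumes in litres.
Concentration cells accept plain numbers, ``?`` (optimise this value) and
``~value`` (optimise, starting from ``value``); both the ASCII tilde and
the typeset U+223C are accepted.

The model config is a JSON document with sections ``components`` /
``complexes`` / ``variables`` / ``constants`` / ``polymers`` / ``spectra``;
see :func:`read_model_config`.  A complex's composition may use ``"n"`` as
a coefficient to declare a homopolymer.

Vendor formats (spectrometer exports) are handled through a plugin
registry: :func:`register_converter` installs a callable returning a
:class:`~titrakit.data.TitrationData`, whose output is validated before
acceptance.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path
from typing import Callable

import numpy as np

from .data import (  # noqa: F401  (ConcentrationCell and its parser live here)
    ConcentrationCell,
    ConcentrationPlan,
    TitrationData,
    format_concentration_cell,
    parse_concentration_cell,
)
from .exceptions import ModelDefinitionError, ParseError
from .model import (
    Complex,
    ComponentSet,
    EquilibriumParameterisation,
    ObservationModel,
    Polymer,
    PolymerConstants,
    StoichiometryModel,
    Variable,
)

__all__ = [
    "ConcentrationCell",
    "parse_concentration_cell",
    "read_titration_csv",
    "write_titration_csv",
    "read_totals_csv",
    "read_stocks_csv",
    "write_totals_csv",
    "read_model_config",
    "write_model_config",
    "model_config_to_dict",
    "model_config_from_dict",
    "write_fit_result",
    "register_converter",
    "plugin_convert",
    "available_converters",
]


# ---------------------------------------------------------------------------
# titration data CSV
# ---------------------------------------------------------------------------


def _read_rows(path) -> list[list[str]]:
    with open(path, newline="", encoding="utf-8-sig") as fh:
        return [row for row in csv.reader(fh)]


def read_titration_csv(path) -> TitrationData:
    """Read a titration matrix: first row signal labels, first column
    addition labels, blank cells masked (missing)."""
    rows = _read_rows(path)
    if not rows:
        raise ParseError(f"{path}: empty file")
    header = rows[0]
    signal_labels = tuple(h.strip() for h in header[1:])
    body = rows[1:]
    if not body:
        raise ParseError(f"{path}: no additions (header-only file)")
    width = len(header)
    Y = np.full((len(body), len(signal_labels)), np.nan)
    addition_labels = []
    for i, row in enumerate(body):
        if len(row) != width:
            raise ParseError(f"{path}: ragged row", (i + 1, len(row)))
        addition_labels.append(row[0].strip())
        for j, cell in enumerate(row[1:]):
            cell = cell.strip()
            if cell == "":
                continue
            try:
                Y[i, j] = float(cell)
            except ValueError:
                raise ParseError(
                    f"{path}: non-numeric cell {cell!r}", (i + 1, j + 1)
                ) from None
    return TitrationData(Y, signal_labels, tuple(addition_labels))


def write_titration_csv(path, data: TitrationData):
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["addition", *data.signal_labels])
        for label, row in zip(data.addition_labels, data.Y):
            w.writerow([label] + ["" if not np.isfinite(v) else repr(float(v)) for v in row])


# ---------------------------------------------------------------------------
# concentrations CSV
# ---------------------------------------------------------------------------


def read_totals_csv(path) -> ConcentrationPlan:
    """Direct-totals layout: header ``addition,<comp>,<comp>...``, one row
    per addition; cells may be values, ``?`` or ``~guess`` (molar)."""
    rows = _read_rows(path)
    if len(rows) < 2:
        raise ParseError(f"{path}: need a header and at least one addition")
    components = tuple(h.strip() for h in rows[0][1:])
    cells = []
    for i, row in enumerate(rows[1:]):
        if len(row) != len(components) + 1:
            raise ParseError(f"{path}: ragged row", (i + 1, len(row)))
        cells.append([parse_concentration_cell(c, (i + 1, j + 1))
                      for j, c in enumerate(row[1:])])
    return ConcentrationPlan.from_totals(np.array(cells, dtype=object), components)


def read_stocks_csv(stocks_path, volumes_path) -> ConcentrationPlan:
    """Stocks + volumes layout.  ``stocks.csv``: header
    ``stock,<comp>,...``, one row per stock solution (cells may be ``?`` /
    ``~guess``).  ``volumes.csv``: header ``addition,<stock>,...``, one row
    per addition with aliquot volumes in litres; the first row is the
    initial cell contents."""
    srows = _read_rows(stocks_path)
    if len(srows) < 2:
        raise ParseError(f"{stocks_path}: need a header and at least one stock")
    components = tuple(h.strip() for h in srows[0][1:])
    stock_labels, cells = [], []
    for i, row in enumerate(srows[1:]):
        if len(row) != len(components) + 1:
            raise ParseError(f"{stocks_path}: ragged row", (i + 1, len(row)))
        stock_labels.append(row[0].strip())
        cells.append([parse_concentration_cell(c, (i + 1, j + 1))
                      for j, c in enumerate(row[1:])])
    vrows = _read_rows(volumes_path)
    if len(vrows) < 2:
        raise ParseError(f"{volumes_path}: need a header and at least one addition")
    vol_stocks = [h.strip() for h in vrows[0][1:]]
    if vol_stocks != stock_labels:
        raise ParseError(
            f"{volumes_path}: stock columns {vol_stocks} do not match {stock_labels}"
        )
    volumes = np.zeros((len(vrows) - 1, len(stock_labels)))
    for i, row in enumerate(vrows[1:]):
        if len(row) != len(stock_labels) + 1:
            raise ParseError(f"{volumes_path}: ragged row", (i + 1, len(row)))
        for j, cell in enumerate(row[1:]):
            try:
                volumes[i, j] = float(cell) if cell.strip() else 0.0
            except ValueError:
                raise ParseError(
                    f"{volumes_path}: non-numeric volume {cell!r}", (i + 1, j + 1)
                ) from None
    return ConcentrationPlan.from_stocks(
        np.array(cells, dtype=object), volumes, components, tuple(stock_labels)
    )


def write_totals_csv(path, plan: ConcentrationPlan):
    if plan.mode != "totals":
        raise ModelDefinitionError("write_totals_csv needs a totals-mode plan")
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["addition", *plan.component_names])
        for i in range(plan.n_additions):
            w.writerow([str(i)] + [format_concentration_cell(c) for c in plan.totals[i]])


# ---------------------------------------------------------------------------
# model config JSON
# ---------------------------------------------------------------------------


def model_config_from_dict(cfg: dict):
    """Build (StoichiometryModel, EquilibriumParameterisation,
    ObservationModel) from a config dictionary.

    Schema::

        components: ["H", "G"]
        complexes:  [{"label": "HG", "composition": {"H": 1, "G": 1}},
                     {"label": "Hn", "composition": {"H": "n"},
                      "isodesmic": false}]
        variables:  [{"name": "K1", "role": "optimised", "value": 1.0}]
        constants:  {"statistical_factors": {"HG": 2.0},
                     "exponents": {"HG": {"K1": 1}}}
        polymers:   {"Hn": {"k2": "K2", "kn": "Kn"}}
        spectra:    {"exchange": "slow", "active": [...],
                     "relationships": null | "additive" | {state: {var: w}},
                     "additive_host": "H", "reference": "H" | {signal: comp},
                     "known": {state: [per-signal values]},
                     "nonnegative": false,
                     "signal_states": {signal: [states]}}
    """
    try:
        components = ComponentSet(tuple(cfg["components"]))
    except KeyError:
        raise ParseError("model config: missing 'components'") from None
    complexes, polymers = [], []
    for entry in cfg.get("complexes", []):
        label = entry["label"]
        comp_map = entry["composition"]
        if any(v == "n" for v in comp_map.values()):
            if len(comp_map) != 1:
                raise ParseError(f"polymer {label!r} must contain a single component")
            (comp_name,) = comp_map
            polymers.append(
                Polymer(label, components.index(comp_name), bool(entry.get("isodesmic", False)))
            )
        else:
            coeff = tuple(int(comp_map.get(n, 0)) for n in components.names)
            complexes.append(Complex(label, coeff))
    model = StoichiometryModel(components, tuple(complexes), tuple(polymers))

    variables = tuple(
        Variable(v["name"], v.get("role", "optimised"), float(v.get("value", 1.0)))
        for v in cfg.get("variables", [])
    )
    var_names = [v.name for v in variables]
    constants = cfg.get("constants", {})
    exp_map = constants.get("exponents", {})
    sf_map = constants.get("statistical_factors", {})
    labels = [c.label for c in complexes]
    E = np.zeros((len(variables), len(labels)))
    for j, label in enumerate(labels):
        for vname, e in exp_map.get(label, {}).items():
            if vname not in var_names:
                raise ParseError(f"exponent references unknown variable {vname!r}")
            E[var_names.index(vname), j] = float(e)
    sf = np.array([float(sf_map.get(label, 1.0)) for label in labels])
    poly_cfg = cfg.get("polymers", {})
    polymer_constants = []
    for poly in polymers:
        entry = poly_cfg.get(poly.label)
        if entry is None:
            raise ParseError(f"no polymer constants declared for {poly.label!r}")
        k2, kn = entry["k2"], entry.get("kn", entry["k2"])
        if poly.isodesmic:
            kn = k2
        polymer_constants.append(PolymerConstants(k2, kn))
    param = EquilibriumParameterisation(variables, E, sf, tuple(polymer_constants))

    sp = cfg.get("spectra", {})
    rel = sp.get("relationships")
    obs = ObservationModel(
        exchange=sp.get("exchange", "slow"),
        active_states=tuple(sp.get("active", model.species_labels())),
        signals=tuple(sp["signals"]) if sp.get("signals") else None,
        reference=sp.get("reference"),
        relationships=rel,
        known_spectra={k: tuple(v) for k, v in sp.get("known", {}).items()},
        nonnegative=bool(sp.get("nonnegative", False)),
        additive_host=sp.get("additive_host"),
        signal_states={k: tuple(v) for k, v in sp["signal_states"].items()}
        if sp.get("signal_states")
        else None,
    )
    return model, param, obs


def model_config_to_dict(model, param, obs) -> dict:
    complexes = [
        {"label": c.label,
         "composition": {n: int(v) for n, v in zip(model.components.names, c.coefficients) if v}}
        for c in model.complexes
    ]
    for p in model.polymers:
        complexes.append({
            "label": p.label,
            "composition": {model.components.names[p.component]: "n"},
            "isodesmic": p.isodesmic,
        })
    exponents = {}
    for j, c in enumerate(model.complexes):
        col = {v.name: param.exponents[k, j]
               for k, v in enumerate(param.variables) if param.exponents[k, j] != 0}
        if col:
            exponents[c.label] = col
    cfg = {
        "components": list(model.components.names),
        "complexes": complexes,
        "variables": [
            {"name": v.name, "role": v.role, "value": v.value} for v in param.variables
        ],
        "constants": {
            "statistical_factors": {
                c.label: float(sf)
                for c, sf in zip(model.complexes, param.statistical_factors)
                if sf != 1.0
            },
            "exponents": exponents,
        },
        "polymers": {
            p.label: {"k2": pc.k2_variable, "kn": pc.kn_variable}
            for p, pc in zip(model.polymers, param.polymer_constants)
        },
        "spectra": {
            "exchange": obs.exchange,
            "active": list(obs.active_states),
            "signals": list(obs.signals) if obs.signals else None,
            "reference": obs.reference if isinstance(obs.reference, (str, type(None)))
            else dict(obs.reference),
            "relationships": obs.relationships
            if isinstance(obs.relationships, (str, type(None)))
            else {s: dict(m) for s, m in obs.relationships.items()},
            "known": {k: list(map(float, v)) for k, v in obs.known_spectra.items()},
            "nonnegative": obs.nonnegative,
            "additive_host": obs.additive_host,
            "signal_states": {k: list(v) for k, v in obs.signal_states.items()}
            if obs.signal_states
            else None,
        },
    }
    return cfg


def read_model_config(path):
    with open(path, encoding="utf-8") as fh:
        try:
            cfg = json.load(fh)
        except json.JSONDecodeError as exc:
            raise ParseError(f"{path}: invalid JSON ({exc})") from None
    return model_config_from_dict(cfg)


def write_model_config(path, model, param, obs):
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(model_config_to_dict(model, param, obs), fh, indent=2)
        fh.write("\n")


# ---------------------------------------------------------------------------
# fit result output
# ---------------------------------------------------------------------------


def write_fit_result(out_dir, result, data: TitrationData, model=None):
    """Write a fit as ``fit.json`` (variables, RMSE, convergence) plus
    CSVs: solved spectra, predicted signals, residuals, per-addition
    speciation.  Returns the output directory path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    payload = {
        "variables": {k: float(v) for k, v in result.variable_values.items()},
        "fixed": {k: float(v) for k, v in result.fixed_values.items()},
        "rmse": float(result.rmse),
        "converged": bool(result.converged),
        "n_outer_evaluations": int(result.n_outer_evaluations),
    }
    (out / "fit.json").write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")

    def _write_matrix(name, matrix, row_labels, col_labels, corner):
        with open(out / name, "w", newline="", encoding="utf-8") as fh:
            w = csv.writer(fh)
            w.writerow([corner, *col_labels])
            for label, row in zip(row_labels, matrix):
                w.writerow([label] + ["" if not np.isfinite(v) else repr(float(v)) for v in row])

    _write_matrix("spectra.csv", result.X, result.spectral_variable_names,
                  data.signal_labels, "variable")
    _write_matrix("predicted.csv", result.predicted, data.addition_labels,
                  data.signal_labels, "addition")
    _write_matrix("residuals.csv", result.residuals, data.addition_labels,
                  data.signal_labels, "addition")
    if model is not None:
        species = model.species_labels()
        conc = np.column_stack(
            [np.array([_species_conc(spec, model, s) for spec in result.speciation])
             for s in species]
        )
        _write_matrix("speciation.csv", conc, data.addition_labels, species, "addition")
    return out


def _species_conc(spec, model, label):
    if label in model.components.names:
        return spec.s[model.components.index(label)]
    for j, c in enumerate(model.complexes):
        if c.label == label:
            return spec.c[j]
    for p, poly in enumerate(model.polymers):
        if poly.label == label:
            return spec.polymer_totals[p]
    raise ModelDefinitionError(f"unknown species {label!r}")


# ---------------------------------------------------------------------------
# vendor-format plugin registry
# ---------------------------------------------------------------------------

_CONVERTERS: dict[str, Callable] = {}


def register_converter(name: str, func: Callable):
    """Register a vendor-format converter: a callable ``func(path) ->
    TitrationData`` (or anything accepted by the TitrationData
    constructor).  This is the supported extension point for spectrometer
    export formats."""
    _CONVERTERS[name] = func


def available_converters() -> tuple[str, ...]:
    return tuple(sorted(_CONVERTERS))


def plugin_convert(path, converter_name: str) -> TitrationData:
    """Convert a vendor file via a registered converter; the output is
    validated against the TitrationData invariants before acceptance."""
    try:
        func = _CONVERTERS[converter_name]
    except KeyError:
        raise ParseError(
            f"unknown converter {converter_name!r}; available: "
            f"{', '.join(available_converters()) or '(none)'}"
        ) from None
    out = func(path)
    if isinstance(out, TitrationData):
        # re-validate: plugins may have mutated fields
        return TitrationData(out.Y, out.signal_labels, out.addition_labels)
    try:
        return TitrationData(np.atleast_2d(np.asarray(out, dtype=float)))
    except Exception as exc:
        raise ParseError(f"converter {converter_name!r} returned invalid data: {exc}") from None
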