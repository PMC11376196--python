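"""Core data containers shared by the io and fitting layers.

Units are fixed package-wide: concentrations in molar (M), volumes in
litres (L).  Files and in-memory arrays use the same convention.
"""

from __future__ import annotations

import math
import re
import warnings
from dataclasses import dataclass, field

import numpy as np

from .exceptions import DomainError, ParseError

__all__ = [
    "TitrationData",
    "ConcentrationCell",
    "parse_concentration_cell",
    "format_concentration_cell",
    "ConcentrationPlan",
    "totals_from_additions",
]


@dataclass
class TitrationData:
    """Observed titration measurements.

    ``Y`` is (n_additions x n_signals); units are whatever the instrument
    reports (absorbance units, intensity, or ppm).  Missing cells are NaN
    and are excluded from the linear solve and the RMSE denominator.
    """

    Y: np.ndarray
    signal_labels: tuple[str, ...] = ()
    addition_labels: tuple[str, ...] = ()

    def __post_init__(self):
        Y = np.atleast_2d(np.asarray(self.Y, dtype=float))
        self.Y = Y
        if not self.signal_labels:
            self.signal_labels = tuple(f"signal{j}" for j in range(Y.shape[1]))
        if not self.addition_labels:
            self.addition_labels = tuple(str(k) for k in range(Y.shape[0]))
        self.signal_labels = tuple(self.signal_labels)
        self.addition_labels = tuple(self.addition_labels)
        if len(self.signal_labels) != Y.shape[1] or len(self.addition_labels) != Y.shape[0]:
            raise DomainError("label lengths do not match data shape")
        if Y.shape[0] < 2:
            raise DomainError("a titration needs at least 2 additions")
        if np.any(~np.isfinite(Y).any(axis=0)):
            bad = [self.signal_labels[j] for j in np.nonzero(~np.isfinite(Y).any(axis=0))[0]]
            raise DomainError(f"fully-missing signals: {bad}")

    @property
    def mask(self) -> np.ndarray:
        """True where a measurement is present."""
        return np.isfinite(self.Y)

    @property
    def n_additions(self) -> int:
        return self.Y.shape[0]

    @property
    def n_signals(self) -> int:
        return self.Y.shape[1]


# ---------------------------------------------------------------------------
# concentration cells: "?" unknown / "~value" guess / plain value
# ---------------------------------------------------------------------------

_TILDES = ("~", "∼")  # ASCII tilde and the typeset similarity sign


@dataclass(frozen=True)
class ConcentrationCell:
    """One concentration entry: a known value, an unknown to optimise
    ("?"), or an unknown with an initial guess ("~value")."""

    kind: str  # "value" | "unknown" | "guess"
    value: float | None = None

    def __post_init__(self):
        if self.kind not in ("value", "unknown", "guess"):
            raise DomainError(f"bad cell kind {self.kind!r}")
        if self.kind == "unknown":
            if self.value is not None:
                raise DomainError("unknown cells carry no value")
        else:
            if self.value is None or not (self.value >= 0 and math.isfinite(self.value)):
                raise DomainError("cell value must be a finite non-negative number")
            if self.kind == "guess" and not self.value > 0:
                raise DomainError("guess values must be positive")

    @property
    def is_free(self) -> bool:
        return self.kind in ("unknown", "guess")


def parse_concentration_cell(text: str, coordinates=None) -> ConcentrationCell:
    """Parse one concentration-cell string (total parsing: every string
    maps to exactly one cell kind or raises :class:`ParseError`).

    ``"1.11e-3"`` -> value; ``"?"`` -> unknown (optimised);
    ``"~2.5e-2"`` (ASCII tilde or U+223C) -> guess.
    """
    if not isinstance(text, str):
        text = "" if text is None else str(text)
    stripped = text.strip()
    if stripped == "?":
        return ConcentrationCell("unknown")
    kind = "value"
    if stripped[:1] in _TILDES:
        kind = "guess"
        stripped = stripped[1:].strip()
    if not stripped:
        raise ParseError(f"empty concentration cell {text!r}", coordinates)
    if not re.fullmatch(r"[+]?[\d.]+(?:[eE][+-]?\d+)?", stripped):
        raise ParseError(f"cannot parse concentration cell {text!r}", coordinates)
    try:
        value = float(stripped)
    except ValueError:
        raise ParseError(f"cannot parse concentration cell {text!r}", coordinates) from None
    if kind == "guess" and value <= 0:
        raise ParseError(f"guess must be positive: {text!r}", coordinates)
    return ConcentrationCell(kind, value)


def format_concentration_cell(cell: ConcentrationCell) -> str:
    if cell.kind == "unknown":
        return "?"
    if cell.kind == "guess":
        return f"~{float(cell.value)!r}"
    return repr(float(cell.value))


def _cell_grid(values, shape) -> np.ndarray:
    """Coerce an array of numbers / strings / cells into a cell grid."""
    grid = np.empty(shape, dtype=object)
    for idx in np.ndindex(shape):
        v = values[idx[0]][idx[1]] if not isinstance(values, np.ndarray) else values[idx]
        if isinstance(v, ConcentrationCell):
            grid[idx] = v
        elif isinstance(v, str):
            grid[idx] = parse_concentration_cell(v, idx)
        else:
            grid[idx] = ConcentrationCell("value", float(v))
    return grid


@dataclass
class ConcentrationPlan:
    """Per-addition total concentrations, given directly or via stock
    solutions and addition volumes.

    * ``mode="totals"``: ``totals`` is (n_additions x n_components) of
      :class:`ConcentrationCell`.
    * ``mode="stocks"``: ``stocks`` is (n_stocks x n_components) of cells
      and ``volumes`` is (n_additions x n_stocks) of aliquot volumes in L.
      Row 0 of ``volumes`` is the initial cell contents; a pure-solvent
      addition is a stock whose concentrations are all zero.  The total
      concentration at addition k is the cumulative amount of each
      component divided by the cumulative volume.
    """

    mode: str
    component_names: tuple[str, ...]
    totals: np.ndarray | None = None
    stocks: np.ndarray | None = None
    volumes: np.ndarray | None = None
    stock_labels: tuple[str, ...] = ()

    # -- constructors -------------------------------------------------------
    @classmethod
    def from_totals(cls, totals, component_names) -> "ConcentrationPlan":
        totals = np.asarray(totals, dtype=object)
        if totals.ndim != 2:
            totals = np.atleast_2d(totals)
        grid = _cell_grid(totals, totals.shape)
        return cls("totals", tuple(component_names), totals=grid)

    @classmethod
    def from_stocks(cls, stocks, volumes, component_names, stock_labels=()) -> "ConcentrationPlan":
        stocks = np.asarray(stocks, dtype=object)
        if stocks.ndim != 2:
            stocks = np.atleast_2d(stocks)
        grid = _cell_grid(stocks, stocks.shape)
        volumes = np.atleast_2d(np.asarray(volumes, dtype=float))
        if volumes.shape[1] != grid.shape[0]:
            raise DomainError(
                f"volumes has {volumes.shape[1]} stock columns for {grid.shape[0]} stocks"
            )
        if np.any(volumes < 0) or np.any(~np.isfinite(volumes)):
            raise DomainError("volumes must be finite and >= 0")
        if np.any(np.cumsum(volumes.sum(axis=1)) <= 0):
            raise DomainError("cumulative total volume must be > 0 at every addition")
        labels = tuple(stock_labels) or tuple(f"stock{i}" for i in range(grid.shape[0]))
        return cls("stocks", tuple(component_names), stocks=grid,
                   volumes=volumes, stock_labels=labels)

    # -- unknowns -----------------------------------------------------------
    def _cells(self) -> np.ndarray:
        return self.totals if self.mode == "totals" else self.stocks

    def unknown_variables(self) -> list[tuple[str, float | None]]:
        """(name, guess-or-None) for every "?"/"~" cell, in row-major order.

        Names are ``"total[<addition>,<component>]"`` or
        ``"stock[<label>,<component>]"``.
        """
        cells = self._cells()
        out = []
        for (i, j), cell in np.ndenumerate(cells):
            if cell.is_free:
                if self.mode == "totals":
                    name = f"total[{i},{self.component_names[j]}]"
                else:
                    name = f"stock[{self.stock_labels[i]},{self.component_names[j]}]"
                out.append((name, cell.value if cell.kind == "guess" else None))
        return out

    def n_unknowns(self) -> int:
        return len(self.unknown_variables())

    def resolve(self, values: dict[str, float] | None = None) -> "ConcentrationPlan":
        """Return a copy with every free cell replaced by its value from
        ``values`` (keyed by :meth:`unknown_variables` names)."""
        values = values or {}
        cells = self._cells().copy()
        names = iter(self.unknown_variables())
        for (i, j), cell in np.ndenumerate(cells):
            if cell.is_free:
                name, _ = next(names)
                if name not in values:
                    raise DomainError(f"no value supplied for unknown concentration {name}")
                cells[i, j] = ConcentrationCell("value", float(values[name]))
        if self.mode == "totals":
            return ConcentrationPlan("totals", self.component_names, totals=cells)
        return ConcentrationPlan("stocks", self.component_names, stocks=cells,
                                 volumes=self.volumes, stock_labels=self.stock_labels)

    @property
    def n_additions(self) -> int:
        return (self.totals if self.mode == "totals" else self.volumes).shape[0]

    def check_identifiability(self, tight_binding: bool = False):
        """Warn when more than n_components - 1 concentrations are free in a
        tight-binding system, where only relative values are determined."""
        if tight_binding and self.n_unknowns() > len(self.component_names) - 1:
            warnings.warn(
                "tight-binding system with more unknown concentrations than "
                "n_components - 1: only relative stock concentrations are "
                "identifiable", stacklevel=2,
            )


def totals_from_additions(plan: ConcentrationPlan) -> np.ndarray:
    """Per-addition total concentrations (n_additions x n_components, M)
    from exact dilution bookkeeping.  All cells must be resolved values."""
    cells = plan._cells()
    values = np.empty(cells.shape, dtype=float)
    for idx, cell in np.ndenumerate(cells):
        if cell.is_free:
            raise DomainError(
                "plan still contains unknown concentrations; resolve() them first"
            )
        values[idx] = cell.value
    if plan.mode == "totals":
        return values
    amounts = np.cumsum(plan.volumes, axis=0) @ values  # mol, per addition x component
    vol = np.cumsum(plan.volumes.sum(axis=1))  # L
    return amounts / vol[:, None]
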