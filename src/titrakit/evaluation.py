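"""Model evaluation and visualisation.

Rather than information criteria (whose assumptions — exactly known
concentrations, iid Gaussian noise, no unmodelled equilibria — rarely hold
for titration data), model comparison here is diagnostic:

* :func:`rmse_profile` fixes one parameter across a grid, re-optimises
  everything else, and plots best-achievable RMSE against the fixed value.
  A sharp minimum means the parameter is determined by the data; a flat
  plateau means compensating changes in the other variables make it
  unidentifiable.
* :func:`normalize_signals` rescales each signal by its total observed
  change, so signals that follow different isotherms (e.g. one dominated by
  a second binding event) visibly separate.
* :func:`population_table` reports, per addition, the fraction of a
  reference component's total in each species that contains it.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .exceptions import DomainError
from .fitting import FitResult, FitSession
from .model import StoichiometryModel, build_stoichiometry_matrix
from .speciation import SpeciationResult

__all__ = [
    "RmseProfile",
    "rmse_profile",
    "normalize_signals",
    "population_table",
    "plot_fit",
    "plot_normalized",
    "plot_populations",
    "plot_profile",
]


@dataclass
class RmseProfile:
    parameter: str
    grid: np.ndarray
    rmse_at: np.ndarray
    unconstrained_min: float
    failed: np.ndarray  # bool mask of grid points whose inner fit failed

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {self.parameter: self.grid, "rmse": self.rmse_at, "failed": self.failed}
        )


def _default_grid(center: float, n_points: int, span_decades: float) -> np.ndarray:
    return np.logspace(
        np.log10(center) - span_decades, np.log10(center) + span_decades, n_points
    )


def rmse_profile(
    fit_result: FitResult,
    parameter: str,
    grid: Sequence[float] | None = None,
    *,
    n_points: int = 25,
    span_decades: float = 2.0,
    maxfev: int | None = None,
) -> RmseProfile:
    """Best-achievable RMSE as ``parameter`` is fixed across ``grid``.

    Each grid point re-fits all remaining variables, warm-started from the
    neighbouring solution; the sweep runs left-to-right then right-to-left
    and keeps the lower RMSE of the two passes (guards against hysteresis
    of the derivative-free inner search).  The default grid is 25
    log-spaced points spanning two decades either side of the fitted value.
    """
    session = fit_result.session
    if session is None:
        raise DomainError("fit result carries no session; refit with FitSession.fit")
    if parameter not in session.outer_names:
        raise DomainError(f"{parameter!r} is not an optimised variable of this fit")
    p_idx = session.outer_names.index(parameter)
    fitted_value = 10.0 ** fit_result.theta[p_idx]
    grid = np.asarray(
        _default_grid(fitted_value, n_points, span_decades) if grid is None else grid,
        dtype=float,
    )
    rmse_fwd = np.full(grid.size, np.nan)
    rmse_bwd = np.full(grid.size, np.nan)
    failed = np.zeros(grid.size, dtype=bool)

    reduced_names = [n for n in session.outer_names if n != parameter]

    def sweep(order, out):
        warm = None
        for g_idx in order:
            sub = session.fixing(parameter, grid[g_idx])
            theta0 = warm
            if theta0 is None:
                theta0 = np.array([
                    fit_result.theta[session.outer_names.index(n)] for n in reduced_names
                ]) if reduced_names else np.zeros(0)
            try:
                res = sub.fit(theta0, maxfev=maxfev)
                out[g_idx] = res.rmse
                warm = res.theta
            except Exception:  # grid point failure is marked, not fatal
                failed[g_idx] = True
        return out

    sweep(range(grid.size), rmse_fwd)
    sweep(range(grid.size - 1, -1, -1), rmse_bwd)
    rmse_at = np.fmin(rmse_fwd, rmse_bwd)
    failed |= ~np.isfinite(rmse_at)
    return RmseProfile(parameter, grid, rmse_at, fit_result.rmse, failed)


def normalize_signals(
    observed: np.ndarray,
    predicted: np.ndarray | None = None,
    *,
    rel_tol: float = 1e-12,
):
    """Per-signal affine normalisation ``(y - y_first) / (y_last - y_first)``
    applied to observed (and, with the observed endpoints, to predicted)
    data.  Signals whose total change is below ``rel_tol`` times the data
    scale are flagged and returned as NaN columns.

    Returns ``(normalized_observed, normalized_predicted_or_None, degenerate)``
    where ``degenerate`` is a boolean mask over signals.
    """
    Y = np.atleast_2d(np.asarray(observed, dtype=float))
    first, last = Y[0], Y[-1]
    span = last - first
    scale = np.nanmax(np.abs(Y)) or 1.0
    degenerate = np.abs(span) <= rel_tol * scale
    safe_span = np.where(degenerate, 1.0, span)
    norm_obs = np.where(degenerate, np.nan, (Y - first) / safe_span)
    norm_pred = None
    if predicted is not None:
        P = np.atleast_2d(np.asarray(predicted, dtype=float))
        norm_pred = np.where(degenerate, np.nan, (P - first) / safe_span)
    return norm_obs, norm_pred, degenerate


def population_table(
    speciations: Sequence[SpeciationResult],
    model: StoichiometryModel,
    reference: str,
    totals: np.ndarray,
) -> pd.DataFrame:
    """Fraction of ``reference``'s total concentration in each species that
    contains it, one row per addition.  Rows sum to 1 (within the
    speciation tolerance); an addition with zero total gives a zero row.
    """
    r = model.components.index(reference)
    M = build_stoichiometry_matrix(model)
    cols = [reference]
    cols += [c.label for j, c in enumerate(model.complexes) if M[r, j] > 0]
    cols += [p.label for p in model.polymers if p.component == r]
    rows = np.zeros((len(speciations), len(cols)))
    for k, spec in enumerate(speciations):
        t_ref = totals[k, r]
        if t_ref <= 0:
            continue
        vals = [spec.s[r]]
        vals += [M[r, j] * spec.c[j] for j, c in enumerate(model.complexes) if M[r, j] > 0]
        vals += [spec.polymer_totals[p] for p, poly in enumerate(model.polymers)
                 if poly.component == r]
        rows[k] = np.asarray(vals) / t_ref
    return pd.DataFrame(rows, columns=cols)


# ---------------------------------------------------------------------------
# figures
# ---------------------------------------------------------------------------


def _axes(ax):
    if ax is not None:
        return ax.figure, ax
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots()
    return fig, ax


def plot_fit(data, result: FitResult, x=None, ax=None):
    """Observed points and calculated curves per signal against addition
    index (or a supplied x axis, e.g. guest equivalents)."""
    fig, ax = _axes(ax)
    x = np.arange(data.n_additions) if x is None else np.asarray(x)
    for j, label in enumerate(data.signal_labels):
        line, = ax.plot(x, result.predicted[:, j], label=label)
        ax.plot(x, data.Y[:, j], "o", ms=4, color=line.get_color())
    ax.set_xlabel("addition")
    ax.set_ylabel("signal")
    ax.legend(fontsize="small")
    return fig


def plot_normalized(data, result: FitResult, x=None, ax=None):
    fig, ax = _axes(ax)
    x = np.arange(data.n_additions) if x is None else np.asarray(x)
    norm_obs, norm_pred, degenerate = normalize_signals(data.Y, result.predicted)
    for j, label in enumerate(data.signal_labels):
        if degenerate[j]:
            continue
        line, = ax.plot(x, norm_pred[:, j], label=label)
        ax.plot(x, norm_obs[:, j], "o", ms=4, color=line.get_color())
    ax.set_xlabel("addition")
    ax.set_ylabel("normalised change")
    ax.legend(fontsize="small")
    return fig


def plot_populations(result: FitResult, model, reference, x=None, ax=None):
    fig, ax = _axes(ax)
    table = population_table(result.speciation, model, reference, result.totals)
    x = np.arange(len(table)) if x is None else np.asarray(x)
    ax.stackplot(x, table.to_numpy().T, labels=table.columns)
    ax.set_xlabel("addition")
    ax.set_ylabel(f"fraction of {reference}")
    ax.set_ylim(0, 1)
    ax.legend(fontsize="small")
    return fig


def plot_profile(profile: RmseProfile, ax=None):
    fig, ax = _axes(ax)
    ok = ~profile.failed
    ax.plot(profile.grid[ok], profile.rmse_at[ok], "-o", ms=3)
    ax.axhline(profile.unconstrained_min, ls="--", lw=0.8, color="grey")
    ax.set_xscale("log")
    ax.set_xlabel(profile.parameter)
    ax.set_ylabel("RMSE")
    return fig
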