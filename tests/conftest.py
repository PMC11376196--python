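import logging

import numpy as np
import pytest

from titrakit.data import ConcentrationPlan
from titrakit.model import (
    Complex,
    ComponentSet,
    EquilibriumParameterisation,
    ObservationModel,
    StoichiometryModel,
    Variable,
)

logging.getLogger("titrakit").setLevel(logging.ERROR)


@pytest.fixture
def hg_model():
    """Plain 1:1 host-guest system."""
    comps = ComponentSet(("H", "G"))
    return StoichiometryModel(comps, (Complex("HG", (1, 1)),))


@pytest.fixture
def hg2_model():
    """1:2 host-guest system (complexes HG, HG2)."""
    comps = ComponentSet(("H", "G"))
    return StoichiometryModel(comps, (Complex("HG", (1, 1)), Complex("HG2", (1, 2))))


@pytest.fixture
def hg_param():
    return EquilibriumParameterisation(
        (Variable("K1", "optimised", 1e3),), np.array([[1.0]])
    )


@pytest.fixture
def hg_obs():
    return ObservationModel(exchange="slow", active_states=("H", "HG"))


def make_1to1_titration(K=5e3, t_host=1e-4, n_add=12, max_guest=2e-3):
    """Totals plan for a standard guest-into-host titration."""
    t_h = np.full(n_add, t_host)
    t_g = np.concatenate([[0.0], np.geomspace(max_guest / 50, max_guest, n_add - 1)])
    return ConcentrationPlan.from_totals(np.column_stack([t_h, t_g]), ("H", "G"))
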