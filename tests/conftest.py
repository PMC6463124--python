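"""Shared fixtures: the hypercycle fixture network, its reference run, and
frozen expectations for the printed stoichiometric matrix and pathway table."""

import numpy as np
import pytest
from hypothesis import settings as hypothesis_settings

import efmentropy as ef

hypothesis_settings.register_profile("repro", derandomize=True, deadline=None)
hypothesis_settings.load_profile("repro")

# The 5×14 stoichiometric matrix of the two-replicator hypercycle + CSTR
# flows, rows {A, 2RD, 1RD, 1RL, 2RL}, columns = transformations 1..14.
NU_EXPECTED = np.array([
    [-1,  1, -1,  1,  0,  0, -1,  1, -1,  1,  0,  0,  1, -1],
    [ 0,  0,  1, -1,  0, -1,  0,  0,  0,  0,  0,  0,  0,  0],
    [ 1, -1,  0,  0, -1,  0,  0,  0,  0,  0,  0,  0,  0,  0],
    [ 0,  0,  0,  0,  0,  0,  1, -1,  0,  0, -1,  0,  0,  0],
    [ 0,  0,  0,  0,  0,  0,  0,  0,  1, -1,  0, -1,  0,  0],
])

# Supports of the nine extreme flux modes, in the conventional labelling
# (four internal reversible cycles, the A flow-through, four open
# productive pathways), plus the parity doublets among them.
EFM_SUPPORTS = {
    "E1": {9, 10},
    "E2": {7, 8},
    "E3": {1, 2},
    "E4": {3, 4},
    "E5": {13, 14},
    "E6": {13, 12, 9},
    "E7": {13, 11, 7},
    "E8": {13, 5, 1},
    "E9": {13, 6, 3},
}
PARITY_DOUBLETS = [("E1", "E4"), ("E2", "E3"), ("E6", "E9"), ("E7", "E8")]


@pytest.fixture(scope="session")
def fig_params():
    return ef.HypercycleParams()


@pytest.fixture(scope="session")
def hypercycle(fig_params):
    return ef.build_hypercycle_network(fig_params)


@pytest.fixture(scope="session")
def no_outflow(hypercycle):
    return ef.remove_enantiomer_outflows(hypercycle)


@pytest.fixture(scope="session")
def modes(hypercycle):
    return ef.enumerate_efms(hypercycle)


@pytest.fixture(scope="session")
def mode_by_label(modes):
    """Map conventional labels E1..E9 to enumerated mode positions."""
    return {
        label: modes.index(ef.find_mode(modes, support))
        for label, support in EFM_SUPPORTS.items()
    }


@pytest.fixture(scope="session")
def reference_traj(hypercycle, fig_params):
    """The full open-flow run: reference parameters, 1e9 s."""
    return ef.simulate(hypercycle, fig_params, t_end=1e9)


@pytest.fixture(scope="session")
def reference_ness(reference_traj):
    return ef.detect_ness(reference_traj)


@pytest.fixture(scope="session")
def reference_events(reference_traj):
    return ef.event_times(reference_traj)


@pytest.fixture(scope="session")
def equilibrium_ref(hypercycle, reference_ness):
    return ef.equilibrium_reference(hypercycle, reference_ness.concentrations)


@pytest.fixture(scope="session")
def reference_ledger(hypercycle, reference_traj, modes, equilibrium_ref):
    return ef.ledger_series(
        hypercycle, reference_traj.times, reference_traj.concentrations,
        modes, equilibrium_ref,
    )


@pytest.fixture(scope="session")
def reference_gec(reference_traj, hypercycle):
    return ef.gec_decomposition(reference_traj, hypercycle, check_grid=False)


@pytest.fixture(scope="session")
def coarse_grid():
    """Cheap grid for auxiliary runs that only need event-level resolution."""
    return ef.GridSpec(points_per_decade=40)


@pytest.fixture(scope="session")
def no_outflow_traj(no_outflow, fig_params, coarse_grid):
    return ef.simulate(no_outflow, fig_params, t_end=1e9, grid=coarse_grid)
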