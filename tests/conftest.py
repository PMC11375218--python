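"""Shared fixtures. The expensive PB computations are session-scoped so the
acceptance tests and the property tests reuse the same solves."""
import numpy as np
import pytest

from etekit import Electrolyte, RodModel, solve_rod
from etekit.pb_core import SolverOptions
from etekit.rod_inference import compute_qcalc_vs_b


@pytest.fixture(scope="session")
def elec06():
    return Electrolyte.monovalent(0.6e-3)


@pytest.fixture(scope="session")
def elec12():
    return Electrolyte.monovalent(1.2e-3)


@pytest.fixture(scope="session")
def elec5mM():
    return Electrolyte.monovalent(5e-3)


@pytest.fixture(scope="session")
def rod60_field(elec12):
    """Reference rod (r = 0.4 nm, b = 0.5 nm, n_b = 60) and its bulk field."""
    rod = RodModel(radius=0.4, b=0.5, n_b=60)
    return rod, solve_rod(rod, elec12)


@pytest.fixture(scope="session")
def rod_curve_r005(elec12):
    return compute_qcalc_vs_b(0.05, 60, elec12)


@pytest.fixture(scope="session")
def rod_curve_r04(elec12):
    return compute_qcalc_vs_b(0.4, 60, elec12)


@pytest.fixture(scope="session")
def half_helix_panel():
    """Short-fragment half-helix panel at 0.6 mM (five 3D PB solves)."""
    from etekit.workbench import run_half_helix_panel

    return run_half_helix_panel()


@pytest.fixture(scope="session")
def bd_events():
    """Brownian-dynamics escape events for a ladder of well depths."""
    from etekit.escape_time import TrapModel, bd_escape_simulate

    trap = TrapModel(r_h=3.0)
    sizes = {2.0: 500, 3.0: 400, 4.0: 300, 5.0: 200}
    out = {}
    for i, w in enumerate(sorted(sizes)):
        out[w] = (trap, bd_escape_simulate(trap, w, seed=100 + i,
                                           n_events=sizes[w]))
    return out


@pytest.fixture(scope="session")
def bd_ks_events():
    """A larger deep-well sample (wider rim, cheaper timestep) for
    distribution-shape tests."""
    from etekit.escape_time import TrapModel, bd_escape_simulate

    trap = TrapModel(r_h=3.0, rim_width=30.0)
    return trap, bd_escape_simulate(trap, 4.0, seed=104, n_events=5000)
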