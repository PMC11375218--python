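import math

import numpy as np
import pytest

from etekit.synthetic_data import (bond_correlation, generate_chain_ensemble,
                                   generate_device_fixture,
                                   generate_escape_events)


def frc_mean_square_r(n_bonds: int, b: float, c: float) -> float:
    """Closed form <R^2> of a freely rotating / discrete worm-like chain with
    bond length b and bond-correlation c (independent oracle)."""
    if c == 0:
        return n_bonds * b * b
    return b * b * (n_bonds * (1 + c) / (1 - c)
                    - 2 * c * (1 - c ** n_bonds) / (1 - c) ** 2)


# ---------------------------------------------------------------- events

def test_event_generation_deterministic_under_seed():
    a = generate_escape_events(10_000, seed=7, t_esc=100.0)
    b = generate_escape_events(10_000, seed=7, t_esc=100.0)
    assert np.array_equal(a.dt, b.dt)
    c = generate_escape_events(10_000, seed=8, t_esc=100.0)
    assert not np.array_equal(a.dt, c.dt)
    assert a.meta["seed"] == 7 and a.meta["true_t_esc"] == 100.0


def test_fit_recovers_generated_mean():
    from etekit.escape_time import fit_escape_time

    ev = generate_escape_events(10_000, seed=3, t_esc=80.0, frame_interval=0.4)
    fit = fit_escape_time(ev)
    assert abs(fit.t_esc - 80.0) < 3 * 80.0 / math.sqrt(10_000)


def test_one_kbt_depth_difference_gives_mean_ratio_e():
    """Two species separated by Delta(q_eff |phi_m|) = 1 kBT escape with
    mean times in the ratio e (Kramers identity), within sampling error."""
    t1 = 40.0
    t2 = t1 * math.e
    e1 = generate_escape_events(40_000, seed=5, t_esc=t1, frame_interval=0.05)
    e2 = generate_escape_events(40_000, seed=6, t_esc=t2, frame_interval=0.05)
    ratio = e2.dt.mean() / e1.dt.mean()
    assert ratio == pytest.approx(math.e, rel=0.03)


# ---------------------------------------------------------------- chains

def test_rigid_limit_chains_are_straight():
    ens = generate_chain_ensemble(n_b=20, b_c=0.5, l_p=5000.0, n_conformers=5,
                                  seed=1)
    for c in ens.conformers:
        assert c.end_to_end == pytest.approx(20 * 0.5, rel=0.01)


def test_freely_jointed_limit_mean_square_end_to_end():
    # l_p = b_c/2 corresponds to uncorrelated bonds: <R^2> = N b^2
    ens = generate_chain_ensemble(n_b=30, b_c=0.5, l_p=0.25, n_conformers=2000,
                                  seed=2)
    r2 = np.mean([c.end_to_end ** 2 for c in ens.conformers])
    assert r2 == pytest.approx(30 * 0.25, rel=0.05)


def test_wlc_mean_square_end_to_end_matches_closed_form():
    b, lp, nb = 0.5, 2.0, 60
    c = bond_correlation(lp, b)
    ens = generate_chain_ensemble(n_b=nb, b_c=b, l_p=lp, n_conformers=2000, seed=4)
    r2 = np.mean([x.end_to_end ** 2 for x in ens.conformers])
    assert r2 == pytest.approx(frc_mean_square_r(nb, b, c), rel=0.05)


def test_chain_invariants_and_determinism():
    e1 = generate_chain_ensemble(n_b=15, b_c=0.6, l_p=1.5, n_conformers=50, seed=9)
    e2 = generate_chain_ensemble(n_b=15, b_c=0.6, l_p=1.5, n_conformers=50, seed=9)
    for c1, c2 in zip(e1.conformers, e2.conformers):
        assert np.array_equal(c1.sites, c2.sites)
    for c in e1.conformers:
        assert c.end_to_end <= c.contour_length + 1e-9
        assert c.b_c == pytest.approx(0.6, rel=1e-9)   # fixed bond length
    with pytest.raises(ValueError, match="persistence"):
        generate_chain_ensemble(n_b=10, b_c=0.5, l_p=0.01)


# ---------------------------------------------------------------- fixtures

def test_device_fixture_values():
    dev, elec, meta = generate_device_fixture("fig1_device")
    assert dev.gap == pytest.approx(70.0)
    assert dev.phi_s == pytest.approx(-1.91)
    assert elec.c0 == pytest.approx(0.6e-3)
    # the printed kappa*h bookkeeping value is stored verbatim, not recomputed
    assert meta["printed_kappa_h"] == 5.5

    dev3, elec3, _ = generate_device_fixture("fig3_device")
    assert dev3.gap == pytest.approx(75.0)
    assert dev3.phi_s == pytest.approx(-2.24)
    # h / kappa^-1 ~ 4.3 with kappa^-1 = 8.78 nm at 1.2 mM
    assert dev3.half_height / elec3.debye == pytest.approx(4.3, abs=0.05)

    devc, elecc, _ = generate_device_fixture("fig1c_geometry")
    assert devc.half_height == 35.0 and devc.pocket_depth == 210.0


def test_unknown_fixture_rejected():
    with pytest.raises(KeyError, match="unknown device fixture"):
        generate_device_fixture("no_such_device")
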