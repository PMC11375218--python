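import math

import numpy as np
import pytest

from etekit import Electrolyte, RodModel, solve_rod
from etekit.effective_charge import (DyeSpec, add_dye_effective_charge,
                                     analytic_cylinder_qeff, counterion_excess,
                                     gamma_eta_fit, manning_limit, qcalc_farfield,
                                     renormalization_factor, solve_and_match)
from etekit.pb_core import SolverOptions

# ------------------------------------------------------- analytic cylinder

def test_analytic_cylinder_identity_at_manning_charge(elec12):
    # |q_str| = l/l_B makes the log argument unity, so |q_eff| = l/l_B exactly
    l = 30.0
    q = l / elec12.bjerrum
    assert analytic_cylinder_qeff(l, -q, 0.4, elec12) == pytest.approx(q, rel=1e-12)


def test_analytic_cylinder_frozen_arithmetic(elec12):
    # direct evaluation for l=30 nm, q_str=-61 e, R=0.4 nm, c0=1.2 mM
    lb, k = elec12.bjerrum, elec12.kappa
    ll = 30.0 / lb
    expect = ll * (1 - math.log(61.0 / ll) / (2 * math.log(k * 0.4)))
    got = analytic_cylinder_qeff(30.0, -61.0, 0.4, elec12)
    assert got == pytest.approx(expect, rel=1e-12)
    assert 44.0 < got < 50.0   # renormalized well below |q_str| = 61


def test_analytic_cylinder_approaches_manning_limit(elec12):
    l, q = 30.0, -61.0
    lim = manning_limit(l, elec12)
    vals = [analytic_cylinder_qeff(l, q, r, elec12) for r in (0.1, 1e-3, 1e-6, 1e-12)]
    rel = [abs(v - lim) / lim for v in vals]
    assert rel == sorted(rel, reverse=True)
    assert rel[-1] < 0.02


def test_analytic_cylinder_rejects_large_kappa_r(elec12):
    with pytest.raises(ValueError, match="kappa R"):
        analytic_cylinder_qeff(30.0, -61.0, 10.0, elec12)


def test_analytic_cylinder_tracks_numerical_rod_when_strongly_charged(
        rod60_field, elec12):
    """In the formula's regime (kappa R < 1, line density well above 1/l_B)
    the closed form agrees with the nonlinear far-field solution to ~10%;
    the agreement degrades as the rod approaches the unrenormalized limit."""
    rod, fld = rod60_field
    q_num = abs(qcalc_farfield(fld, rod, elec12).q_calc)
    q_ana = analytic_cylinder_qeff(rod.length, rod.q_str, rod.radius, elec12)
    assert q_ana == pytest.approx(q_num, rel=0.12)
    dense = RodModel(radius=0.4, b=0.35, n_b=60)
    q_num2 = abs(solve_and_match(dense, elec12).q_calc)
    q_ana2 = analytic_cylinder_qeff(dense.length, dense.q_str, dense.radius,
                                    elec12)
    assert q_ana2 == pytest.approx(q_num2, rel=0.10)


# ------------------------------------------------------------------- eta

def test_renormalization_factor_printed_examples():
    assert renormalization_factor(-44.1, -63.0) == pytest.approx(0.70, abs=0.005)
    assert renormalization_factor(-6.3, -6.7) == pytest.approx(0.94, abs=0.005)
    assert renormalization_factor(-5.0, -5.0) == 1.0
    with pytest.raises(ValueError):
        renormalization_factor(-1.0, 0.0)


# ------------------------------------------------------------------- dyes

def test_dye_bookkeeping():
    from etekit.effective_charge import EffectiveChargeResult

    core = EffectiveChargeResult(q_calc=-39.3, q_str=-61.0, method="far-field")
    tot = add_dye_effective_charge(core, DyeSpec(2))
    assert tot.q_calc == pytest.approx(-39.3 - 0.62)
    assert tot.q_str == pytest.approx(-63.0)      # -(n_b + 3) e with two dyes
    assert tot.components["dye"] == pytest.approx(-0.62)
    same = add_dye_effective_charge(core, DyeSpec(0))
    assert same.q_calc == core.q_calc and same.q_str == core.q_str
    with pytest.raises(ValueError):
        DyeSpec(-1)


# ----------------------------------------------------------- far-field fit

def test_weak_charge_farfield_recovers_structural_charge(elec5mM):
    rod = RodModel(radius=0.3, b=0.4, n_b=10, q_str=-0.02)
    res = solve_and_match(rod, elec5mM)
    assert res.q_calc / rod.q_str == pytest.approx(1.0, abs=0.01)


def test_qcalc_monotone_in_spacing(rod_curve_r04):
    assert np.all(np.diff(rod_curve_r04.q_abs) > 0)


# ------------------------------------------------------------ ion counting

def test_counterion_excess_closes_electroneutrality(rod60_field, elec12):
    rod, fld = rod60_field
    ion = counterion_excess(fld, elec12, n_phosphates=rod.n_b + 1)
    assert ion.total == pytest.approx(abs(rod.q_str), rel=0.02)
    assert ion.gamma_plus > 0 and ion.gamma_minus > 0
    assert ion.per_phosphate == pytest.approx(ion.gamma_plus / 61.0)


def test_denser_rod_binds_more_counterions_per_phosphate(elec12):
    out = {}
    for b in (0.35, 0.65):
        rod = RodModel(radius=0.4, b=b, n_b=30)
        fld = solve_rod(rod, elec12)
        out[b] = counterion_excess(fld, elec12, n_phosphates=31).per_phosphate
    assert out[0.35] > out[0.65]


def test_uncharged_object_has_no_ion_excess(elec5mM):
    rod = RodModel(radius=0.3, b=0.4, n_b=10, q_str=0.0)
    fld = solve_rod(rod, elec5mM)
    ion = counterion_excess(fld, elec5mM)
    assert abs(ion.gamma_plus) < 1e-9 and abs(ion.gamma_minus) < 1e-9


# ------------------------------------------------------------ Gamma vs eta

def test_gamma_eta_fit_exact_linear_recovery():
    eta = np.array([0.4, 0.5, 0.6, 0.7, 0.8])
    gamma = 2.5 - 1.75 * eta
    fit = gamma_eta_fit(gamma, eta)
    assert fit["a1"] == pytest.approx(2.5, abs=1e-10)
    assert fit["a2"] == pytest.approx(-1.75, abs=1e-10)
    assert fit["rms_residual"] < 1e-12


def test_gamma_eta_fit_constant_gives_zero_slope():
    fit = gamma_eta_fit([1.0] * 5, [0.4, 0.5, 0.6, 0.7, 0.8])
    assert fit["a2"] == pytest.approx(0.0, abs=1e-12)


def test_gamma_eta_fit_input_validation():
    with pytest.raises(ValueError, match="4"):
        gamma_eta_fit([1, 2, 3], [0.1, 0.2, 0.3])
    with pytest.raises(ValueError, match="degenerate"):
        gamma_eta_fit([1, 2, 3, 4], [0.5, 0.5, 0.5, 0.5])


def test_counterion_excess_decreases_with_eta_across_b_sweep(elec12):
    """Rods of decreasing charge density renormalize less (larger eta) and
    hold fewer excess counterions: the fitted slope a2 is negative."""
    gammas, etas = [], []
    for b in (0.35, 0.45, 0.55, 0.65):
        rod = RodModel(radius=0.4, b=b, n_b=30)
        fld = solve_rod(rod, elec12)
        res = qcalc_farfield(fld, rod, elec12)
        ion = counterion_excess(fld, elec12, n_phosphates=31)
        gammas.append(ion.per_phosphate)
        etas.append(res.eta)
    fit = gamma_eta_fit(gammas, etas)
    assert fit["a2"] < 0
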