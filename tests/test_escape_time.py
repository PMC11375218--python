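import math

import numpy as np
import pytest
from scipy import stats

from etekit.escape_time import (Calibration, EscapeEventTable, TrapModel,
                                bd_escape_simulate, calibrate_surface_potential,
                                confinement_entropy, fit_escape_time, infer_qeff,
                                kramers_ratio, model_escape_time)
from etekit.synthetic_data import generate_device_fixture, generate_escape_events


# ---------------------------------------------------------------- MLE fits

def test_mle_recovers_true_mean_within_three_sigma():
    ev = generate_escape_events(10_000, seed=7, t_esc=50.0, frame_interval=0.5)
    fit = fit_escape_time(ev, n_excluded_lags=0)
    assert abs(fit.t_esc - 50.0) < 3 * 50.0 / math.sqrt(10_000)
    assert fit.stderr == pytest.approx(fit.t_esc / math.sqrt(fit.n_events))


def test_truncated_fit_is_unbiased_by_memorylessness():
    """Keeping only events beyond a cut and fitting the truncation-aware MLE
    reproduces the underlying mean; the naive mean-minus-offset estimator
    agrees analytically."""
    rng = np.random.default_rng(3)
    dt = rng.exponential(50.0, 20_000)
    kept = dt[dt > 20.0]
    ev = EscapeEventTable(dt=kept, frame_interval=0.0)
    fit = fit_escape_time(ev, truncation=20.0, n_excluded_lags=0)
    se = 50.0 / math.sqrt(len(kept))
    assert abs(fit.t_esc - 50.0) < 3 * se
    assert fit.t_esc == pytest.approx(np.mean(kept - 20.0), rel=1e-12)


def test_lag_exclusion_suppresses_short_time_contaminant():
    """A 5% contaminant of fast events (transiently trapped weakly charged
    species) biases the naive mean but not the lag-excluded fit."""
    ev = generate_escape_events(40_000, seed=11, t_esc=50.0, frame_interval=1.0,
                                contaminant_fraction=0.05, contaminant_mean=1.0)
    naive = ev.dt.mean()
    fit = fit_escape_time(ev, n_excluded_lags=2)
    assert abs(naive - 50.0) / 50.0 > 0.02
    assert abs(fit.t_esc - 50.0) / 50.0 < 0.05


def test_fit_input_validation():
    with pytest.raises(ValueError, match="100 events"):
        fit_escape_time(EscapeEventTable(dt=np.full(50, 5.0), frame_interval=1.0))
    with pytest.raises(ValueError, match="single lag"):
        fit_escape_time(EscapeEventTable(dt=np.full(500, 5.0), frame_interval=1.0),
                        n_excluded_lags=0)
    with pytest.raises(ValueError):
        EscapeEventTable(dt=np.array([0.2, 5.0]), frame_interval=1.0)


# ------------------------------------------------------------- trap model

def test_kramers_ratio_closed_form():
    assert kramers_ratio(3.0, 3.0) == 1.0
    assert kramers_ratio(4.0, 3.0) == pytest.approx(math.e)


def test_flat_trap_mean_first_passage_is_a2_over_4d():
    trap = TrapModel(pocket_radius=300.0, r_h=3.0, absorb_radius=300.0)
    expect = 300.0 ** 2 / (4 * trap.diffusivity)
    assert trap.mean_escape_time(0.0) == pytest.approx(expect, rel=1e-4)


def test_bd_flat_landscape_matches_2d_first_passage():
    trap = TrapModel(pocket_radius=300.0, r_h=3.0, absorb_radius=300.0)
    ev = bd_escape_simulate(trap, depth=0.0, seed=5, n_events=3000)
    expect = 300.0 ** 2 / (4 * trap.diffusivity)
    se = ev.dt.std() / math.sqrt(len(ev.dt))
    assert abs(ev.dt.mean() - expect) < max(3 * se, 0.05 * expect)


def test_bd_residence_times_are_exponential(bd_ks_events):
    trap, ev = bd_ks_events
    scale = ev.dt.mean()
    ks = stats.kstest(ev.dt, "expon", args=(0, scale))
    # deep-well escapes lose memory of the start: exponential within KS noise
    assert ks.pvalue > 0.01


def test_trap_kramers_slope_near_unity(bd_events):
    """ln(mean escape time) grows with slope ~1 per kBT of well depth over
    W = 2-5; asserted on the exact first-passage quadrature, with the BD
    samples agreeing pointwise within their sampling error."""
    ws = sorted(bd_events)
    trap = bd_events[ws[0]][0]
    t_quad = [trap.mean_escape_time(w) for w in ws]
    slope = np.polyfit(ws, np.log(t_quad), 1)[0]
    assert slope == pytest.approx(1.0, abs=0.1)
    for w, tq in zip(ws, t_quad):
        ev = bd_events[w][1]
        se = ev.dt.std() / math.sqrt(len(ev.dt))
        assert abs(ev.dt.mean() - tq) < 3.5 * se


def test_bd_ratio_matches_kramers_in_deep_wells(bd_events):
    trap = bd_events[4.0][0]
    t4 = trap.mean_escape_time(4.0)
    t6 = trap.mean_escape_time(6.0)
    assert t6 / t4 == pytest.approx(kramers_ratio(6.0, 4.0), rel=0.1)
    # and the BD mean at W=4 agrees with the quadrature
    ev = bd_events[4.0][1]
    assert ev.dt.mean() == pytest.approx(t4, rel=0.15)


def test_bd_reproducible_and_timestep_guarded():
    trap = TrapModel(pocket_radius=300.0, r_h=3.0)
    e1 = bd_escape_simulate(trap, 1.0, seed=42, n_events=50)
    e2 = bd_escape_simulate(trap, 1.0, seed=42, n_events=50)
    assert np.array_equal(e1.dt, e2.dt)
    with pytest.raises(ValueError, match="timestep"):
        bd_escape_simulate(trap, 1.0, seed=1, n_events=10,
                           dt=0.02 * trap.rim_width ** 2 / trap.diffusivity)


# ------------------------------------------------------------- calibration

@pytest.fixture(scope="module")
def device_and_trap():
    dev, elec, _ = generate_device_fixture("fig3_device")
    trap = TrapModel(r_h=7.0, dF_trans=confinement_entropy(dev, 7.0))
    return dev, elec, trap


def test_calibration_round_trip_recovers_phi_s(device_and_trap):
    dev, elec, trap = device_and_trap
    t_true = model_escape_time(-45.6, -2.24, dev, elec, trap)
    ev = generate_escape_events(30_000, seed=9, t_esc=t_true, frame_interval=0.5)
    fit = fit_escape_time(ev)
    cal = calibrate_surface_potential(-45.6, fit, dev, elec, trap)
    assert cal.phi_s == pytest.approx(-2.24, rel=0.02)


def test_longer_escape_time_implies_stronger_surface_potential(device_and_trap):
    dev, elec, trap = device_and_trap
    t0 = model_escape_time(-45.6, -2.0, dev, elec, trap)
    fits = [fit_escape_time(generate_escape_events(20_000, seed=s, t_esc=t,
                                                   frame_interval=0.2))
            for s, t in ((1, t0), (2, 2 * t0))]
    cals = [calibrate_surface_potential(-45.6, f, dev, elec, trap) for f in fits]
    assert abs(cals[1].phi_s) > abs(cals[0].phi_s)


def test_calibrator_species_is_a_fixed_point(device_and_trap):
    dev, elec, trap = device_and_trap
    from etekit.escape_time import EscapeFit

    fit = EscapeFit(t_esc=model_escape_time(-45.6, -2.24, dev, elec, trap),
                    stderr=1.0, n_events=10_000, n_excluded_lags=2)
    cal = calibrate_surface_potential(-45.6, fit, dev, elec, trap)
    q, dq = infer_qeff(fit, cal)
    assert q == pytest.approx(-45.6, rel=1e-6)


def test_qeff_round_trip_and_monotonicity(device_and_trap):
    dev, elec, trap = device_and_trap
    cal_fit_t = model_escape_time(-45.6, -2.24, dev, elec, trap)
    from etekit.escape_time import EscapeFit

    cal = calibrate_surface_potential(
        -45.6, EscapeFit(cal_fit_t, 1.0, 10_000, 2), dev, elec, trap)
    t_prev = 0.0
    for i, q_true in enumerate((-20.0, -30.0, -40.0, -44.3, -50.0)):
        t_true = model_escape_time(q_true, cal.phi_s, dev, elec, trap)
        assert t_true > t_prev     # larger |q_eff| traps longer
        t_prev = t_true
        ev = generate_escape_events(20_000, seed=20 + i, t_esc=t_true,
                                    frame_interval=min(0.2, t_true / 50))
        fit = fit_escape_time(ev)
        q, dq = infer_qeff(fit, cal)
        assert abs(q - q_true) < 3 * max(dq, 1e-3 * abs(q_true))


def test_escape_time_below_prefactor_rejected(device_and_trap):
    dev, elec, trap = device_and_trap
    with pytest.raises(ValueError, match="attempt-time"):
        trap.well_depth(1e-9)
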