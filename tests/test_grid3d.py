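import numpy as np
import pytest

from etekit import Electrolyte
from etekit.molecular_models import AtomicStructure
from etekit.pb_core import SolverOptions, ionic_charge_integral, solve_atomistic_grid


@pytest.fixture(scope="module")
def point_charge_field(elec5mM):
    st = AtomicStructure([[0.0, 0.0, 0.0]], [-1.0], [0.2], w=0.2)
    opt = SolverOptions(fine_spacing=0.1, padding_debye=7.0)
    return st, solve_atomistic_grid(st, elec5mM, opt)


def test_single_charge_matches_screened_coulomb(point_charge_field, elec5mM):
    """Far from the seed the potential follows q l_B exp(-kappa rho)/rho."""
    st, fld = point_charge_field
    k, lb, kd = elec5mM.kappa, elec5mM.bjerrum, elec5mM.debye
    for rho in (0.5 * kd, kd, 2 * kd, 3 * kd):
        p = float(fld.interpolate([(rho / np.sqrt(3),) * 3])[0])
        dh = -lb * np.exp(-k * rho) / rho
        assert p == pytest.approx(dh, rel=0.03)


def test_single_charge_electroneutrality(point_charge_field):
    _, fld = point_charge_field
    assert ionic_charge_integral(fld) == pytest.approx(1.0, rel=0.02)


def test_zero_charges_give_zero_field(elec5mM):
    st = AtomicStructure([[0, 0, 0], [0.5, 0, 0]], [0.0, 0.0], [0.2, 0.2], w=0.2)
    fld = solve_atomistic_grid(st, elec5mM, SolverOptions(padding_debye=6.0))
    assert np.allclose(fld.psi, 0.0, atol=1e-12)


def test_structure_outside_grid_rejected(elec5mM):
    from etekit.pb_core import TensorGrid

    st = AtomicStructure([[30.0, 0, 0]], [-1.0], [0.2], w=0.2)
    e = np.linspace(-10, 10, 21)
    with pytest.raises(ValueError, match="beyond the grid"):
        solve_atomistic_grid(st, elec5mM, grid=TensorGrid(e, e, e))


def test_unassigned_radii_rejected(elec5mM):
    with pytest.raises(ValueError):
        AtomicStructure([[0, 0, 0]], [-1.0], [0.0], w=0.2)


def test_short_helix_far_field_becomes_isotropic(elec06):
    """A 12-base half-helix at 0.6 mM is smaller than the Debye length, so
    its equipotential surfaces become sphere-like a short distance away:
    the psi = -0.05 contour radius varies by less than 20% over directions."""
    from etekit.molecular_models import build_half_helix
    from etekit.pb_core import solve_atomistic_grid

    hh = build_half_helix(12)
    fld = solve_atomistic_grid(hh, elec06,
                               SolverOptions(fine_spacing=0.125, padding_debye=6.0))
    center = hh.positions.mean(axis=0)
    rng = np.random.default_rng(1)
    dirs = rng.standard_normal((16, 3))
    dirs /= np.linalg.norm(dirs, axis=1)[:, None]
    radii = []
    for d in dirs:
        lo, hi = 2.0, 5.0 * elec06.debye
        for _ in range(40):
            mid = 0.5 * (lo + hi)
            psi = float(fld.interpolate([center + mid * d])[0])
            if psi < -0.05:       # still inside the contour
                lo = mid
            else:
                hi = mid
        radii.append(0.5 * (lo + hi))
    radii = np.asarray(radii)
    assert np.ptp(radii) / radii.mean() < 0.20


def test_field_serialization_round_trip(point_charge_field, tmp_path):
    import h5py

    from etekit.pb_core import save_field_h5, save_profile_txt

    _, fld = point_charge_field
    p = tmp_path / "field.h5"
    save_field_h5(fld, p)
    with h5py.File(p) as f:
        assert np.allclose(f["psi"][...], fld.psi)
        assert f.attrs["geometry"] == "cartesian-3d"
        assert np.allclose(f["edges_x"][...], fld.grid.edges[0])
    txt = tmp_path / "profile.tsv"
    ix = fld.psi.shape[0] // 2
    save_profile_txt(txt, fld.grid.centers[2], fld.psi[ix, ix, :])
    arr = np.loadtxt(txt)
    assert np.allclose(arr[:, 1], fld.psi[ix, ix, :], atol=1e-12)


def test_linearized_free_energy_agreement(elec5mM):
    """For |psi| << 1 the full osmotic term reduces to -psi^2/2, so F_el
    matches the linearized functional within 2%."""
    from etekit.pb_core import free_energy

    st = AtomicStructure([[0, 0, 0]], [-0.02], [0.2], w=0.2)
    fld = solve_atomistic_grid(st, elec5mM, SolverOptions(padding_debye=6.0))
    f_full = free_energy(fld)
    # linearized ionic term computed directly from the same field
    el = elec5mM
    m = fld.electrolyte_mask
    pc = fld.psi[m]
    osm_full = -(np.cosh(pc) - pc * np.sinh(pc) - 1.0)
    osm_lin = 0.5 * pc ** 2
    corr = el.kappa ** 2 / (4 * np.pi * el.bjerrum) * np.sum(
        (osm_lin - osm_full) * fld.vol[m])
    f_lin = f_full + corr
    assert f_full == pytest.approx(f_lin, rel=0.02)
    assert f_full > 0
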