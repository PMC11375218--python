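import io
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from etekit.molecular_models import (AtomicStructure, Conformer, Ensemble,
                                     adjust_terminal_charges, build_half_helix,
                                     conformer_metrics, ias_voxelize,
                                     load_structure, select_representatives,
                                     write_pqr)

# ---------------------------------------------------------------- structures

PQR_3ATOM = """\
ATOM      1  P   MOL     1       1.000   2.000   3.000 -1.0000 1.8000
ATOM      2  O1  MOL     1       2.500   2.000   3.000 -0.5000 1.5200
ATOM      3  H5T MOL     1       4.000   2.000   3.000  0.3000 1.2000
"""


def test_hand_written_pqr_round_trip(tmp_path):
    p = tmp_path / "three.pqr"
    p.write_text(PQR_3ATOM)
    st_ = load_structure(p)
    assert st_.n_atoms == 3
    # Angstrom -> nm
    assert st_.positions[0] == pytest.approx([0.1, 0.2, 0.3])
    assert st_.charges == pytest.approx([-1.0, -0.5, 0.3])
    assert st_.radii == pytest.approx([0.18, 0.152, 0.12])
    out = tmp_path / "rt.pqr"
    write_pqr(st_, out)
    st2 = load_structure(out)
    assert np.allclose(st2.positions, st_.positions, atol=1e-4)
    assert np.allclose(st2.charges, st_.charges, atol=1e-4)
    assert np.allclose(st2.radii, st_.radii, atol=1e-4)


def test_pdb_positions_with_bundled_radii(tmp_path):
    pdb = ("ATOM      1  P   DT  A   1       1.000   2.000   3.000  1.00  0.00"
           "           P\n")
    p = tmp_path / "one.pdb"
    p.write_text(pdb)
    st_ = load_structure(p)
    assert st_.positions[0] == pytest.approx([0.1, 0.2, 0.3])
    assert st_.radii[0] == pytest.approx(0.18)
    assert st_.charges[0] == 0.0
    assert "Bondi" in st_.provenance["radii"]


def test_terminal_charge_adjustment_bookkeeping():
    # a mock forcefield 30-mer: raw total -(n_b - 1) = -29 e
    n = 32
    charges = np.full(n, -29.0 / n)
    names = ["H5T"] + [f"A{i}" for i in range(n - 2)] + ["H3T"]
    st_ = AtomicStructure(np.random.default_rng(0).normal(size=(n, 3)),
                          charges, np.full(n, 0.15), names=names)
    adj = adjust_terminal_charges(st_)
    assert adj.total_charge == pytest.approx(-31.0, abs=1e-9)
    with pytest.raises(ValueError, match="already adjusted"):
        adjust_terminal_charges(adj)
    bad = AtomicStructure([[0, 0, 0]], [-1.0], [0.2], names=["P"])
    with pytest.raises(ValueError, match="H5T/H3T"):
        adjust_terminal_charges(bad)


# ---------------------------------------------------------------- half-helix

def test_half_helix_site_count_and_charge():
    hh = build_half_helix(12)
    assert hh.n_atoms == 13
    assert hh.total_charge == pytest.approx(-13.0, abs=1e-12)
    for n_b in (1, 5, 30, 100):
        assert build_half_helix(n_b).total_charge == -(n_b + 1)
    with pytest.raises(ValueError):
        build_half_helix(0)


def test_half_helix_consecutive_spacing_matches_chord_oracle():
    # chord of a helix: sqrt(rise^2 + (2 R sin(twist/2))^2)
    rise, twist, rad = 0.338, math.radians(36.0), 0.89
    chord = math.sqrt(rise ** 2 + (2 * rad * math.sin(twist / 2)) ** 2)
    hh = build_half_helix(12)
    d = np.linalg.norm(np.diff(hh.positions, axis=0), axis=1)
    assert d == pytest.approx(chord, abs=1e-12)
    assert chord == pytest.approx(0.6455, abs=5e-4)


def test_half_helix_size_grows_with_length():
    r5 = Conformer(build_half_helix(5).positions).r_g
    r12 = Conformer(build_half_helix(12).positions).r_g
    assert r5 < r12


# ---------------------------------------------------------------- voxelizer

def test_voxelized_sphere_volume():
    st_ = AtomicStructure([[0, 0, 0]], [-1.0], [0.2], w=0.2)
    mask, edges = ias_voxelize(st_, spacing=0.05)
    vol = mask.sum() * 0.05 ** 3
    assert vol == pytest.approx(4 / 3 * math.pi * 0.4 ** 3, rel=0.05)


def test_voxelizer_w_zero_is_vdw_union_and_monotone_in_w():
    pos = [[0, 0, 0], [0.25, 0, 0]]
    vols = []
    for w in (0.0, 0.1, 0.2):
        st_ = AtomicStructure(pos, [0, 0], [0.2, 0.2], w=w)
        mask, _ = ias_voxelize(st_, spacing=0.05) if w else ias_voxelize(
            AtomicStructure(pos, [0, 0], [0.2, 0.2], w=0.0), spacing=0.05)
        vols.append(mask.sum() * 0.05 ** 3)
    assert vols[0] < vols[1] < vols[2]
    # union of two overlapping spheres is smaller than the sum of volumes
    single = 4 / 3 * math.pi * 0.4 ** 3
    st2 = AtomicStructure(pos, [0, 0], [0.2, 0.2], w=0.2)
    mask, _ = ias_voxelize(st2, spacing=0.05)
    assert mask.sum() * 0.05 ** 3 < 2 * single


def test_voxelizer_rejects_coarse_grid():
    st_ = AtomicStructure([[0, 0, 0]], [-1.0], [0.2], w=0.2)
    with pytest.raises(ValueError, match="spacing"):
        ias_voxelize(st_, spacing=0.3)


# ---------------------------------------------------------------- conformers

def test_straight_chain_metrics():
    z = np.arange(31) * 0.5
    c = Conformer(np.column_stack([np.zeros(31), np.zeros(31), z]))
    m = conformer_metrics(c)
    assert m["l_c"] == pytest.approx(15.0)
    assert m["R"] == pytest.approx(15.0)
    assert m["b_c"] == pytest.approx(0.5)
    # R_g of a discrete rod from the brute-force second moment
    rg_brute = math.sqrt(np.mean((z - z.mean()) ** 2))
    assert m["R_g"] == pytest.approx(rg_brute, rel=1e-12)


def test_folded_chain_has_small_end_to_end():
    up = np.column_stack([np.zeros(10), np.zeros(10), np.arange(10) * 0.5])
    down = up[::-1] + [0.05, 0, 0]
    c = Conformer(np.vstack([up, down]))
    assert c.end_to_end < 0.1
    assert c.contour_length > 9.0


@settings(deadline=None, max_examples=30, derandomize=True)
@given(st.integers(min_value=2, max_value=40), st.integers(min_value=0, max_value=2 ** 31))
def test_conformer_invariants_random_chains(n, seed):
    rng = np.random.default_rng(seed)
    sites = np.cumsum(rng.normal(size=(n, 3)), axis=0) * 0.3
    c = Conformer(sites)
    assert c.end_to_end <= c.contour_length + 1e-9
    # R_g^2 equals the brute-force mean squared distance from the centroid
    cen = sites.mean(axis=0)
    brute = np.mean(((sites - cen) ** 2).sum(axis=1))
    assert c.r_g ** 2 == pytest.approx(brute, rel=1e-12, abs=1e-15)


# ------------------------------------------------------------ representatives

def test_mode_of_gaussian_cloud_near_true_mean():
    rng = np.random.default_rng(42)
    n = 400
    rg = 2.0 + 0.2 * rng.standard_normal(n)
    r = 6.0 + 0.8 * rng.standard_normal(n)
    confs = [_FakeConformer(rg[i], r[i]) for i in range(n)]
    ens = Ensemble(confs)
    mode, cmax, cmin = select_representatives(ens)
    # the density mode of the sample sits within half a sigma of the mean
    assert abs(mode.r_g - 2.0) < 0.5 * 0.2
    assert abs(mode.end_to_end - 6.0) < 0.5 * 0.8
    assert cmax.end_to_end >= cmin.end_to_end


class _FakeConformer:
    """Minimal stand-in exposing only the metrics used for selection."""

    def __init__(self, rg, r):
        self._rg, self._r = rg, r

    @property
    def r_g(self):
        return self._rg

    @property
    def end_to_end(self):
        return self._r


def test_identical_ensemble_returns_single_conformer_with_warning():
    c = _FakeConformer(1.0, 3.0)
    ens = Ensemble([c, c, c])
    with pytest.warns(UserWarning, match="degenerate"):
        mode, cmax, cmin = select_representatives(ens)
    assert mode is cmax is cmin


def test_three_point_mode_matches_brute_force():
    """With two coincident points and one outlier, the densest-neighbourhood
    member (brute force) is one of the coincident pair."""
    pts = [_FakeConformer(1.0, 3.0), _FakeConformer(1.001, 3.001),
           _FakeConformer(5.0, 12.0)]
    ens = Ensemble(pts)
    mode, _, _ = select_representatives(ens)
    assert mode in pts[:2]
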