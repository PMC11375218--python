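"""Molecular inputs: rods, half-helices, atomistic structures and ensembles.

Two levels of description are supported, mirroring how effective-charge
calculations are set up in practice: full-atom structures read from PQR/PDB
files that keep forcefield partial charges, and bead models (ideal
half-helices, converted coarse-grained chains) that carry one -1 e site per
phosphate. Coordinates are nanometres internally; PQR/PDB I/O is Angstrom.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "RodModel", "AtomicStructure", "Conformer", "Ensemble",
    "load_structure", "write_pqr", "write_xyz", "adjust_terminal_charges",
    "build_half_helix", "ias_voxelize", "conformer_metrics",
    "select_representatives", "ensemble_metrics_table",
    "HALF_HELIX_RISE", "HALF_HELIX_TWIST_DEG", "HALF_HELIX_RADIUS",
]

#: Canonical B-form geometry used for ideal single-strand half-helices.
HALF_HELIX_RISE = 0.338       # nm per residue
HALF_HELIX_TWIST_DEG = 36.0   # degrees per residue
HALF_HELIX_RADIUS = 0.89      # nm, phosphate radial distance

#: Bondi van der Waals radii (nm) used when a PDB file carries no radii.
VDW_RADII_NM = {"H": 0.120, "C": 0.170, "N": 0.155, "O": 0.152,
                "P": 0.180, "S": 0.180}
DEFAULT_VDW_NM = 0.170

#: Default ion-exclusion width w (nm) and charge-seed radius (nm).
DEFAULT_W = 0.2
DEFAULT_SEED_RADIUS = 0.02


@dataclass(frozen=True)
class RodModel:
    """Uniformly charged rigid rod standing in for an ssNA backbone.

    radius r and axial charge spacing b in nm; the rod has length
    l = n_b * b and carries q_str (default -(n_b+1) e) uniformly on its
    side surface.
    """

    radius: float
    b: float
    n_b: int
    q_str: Optional[float] = None

    def __post_init__(self):
        if self.radius <= 0 or self.b <= 0 or self.n_b < 1:
            raise ValueError("rod radius, spacing and base count must be positive")
        if self.q_str is None:
            object.__setattr__(self, "q_str", -(self.n_b + 1.0))

    @property
    def length(self) -> float:
        return self.n_b * self.b

    @property
    def surface_charge_density(self) -> float:
        """q_str / (2 pi r l), e/nm^2."""
        return self.q_str / (2 * np.pi * self.radius * self.length)

    def charge_sites(self) -> np.ndarray:
        """(n_b+1, 3) point-charge positions along the axis (z), spacing b."""
        z = np.linspace(-self.length / 2, self.length / 2, self.n_b + 1)
        return np.column_stack([np.zeros_like(z), np.zeros_like(z), z])


@dataclass
class AtomicStructure:
    """Per-atom positions (nm), partial charges (e) and vdW radii (nm).

    ``w`` is the ion-exclusion width added to every radius when building the
    ion-accessible surface; ``seed_radius`` records the nominal charge-seed
    size (charges are deposited as sub-grid point sources by the solvers).
    """

    positions: np.ndarray
    charges: np.ndarray
    radii: np.ndarray
    names: Sequence[str] = None
    w: float = DEFAULT_W
    seed_radius: float = DEFAULT_SEED_RADIUS
    q_str: Optional[float] = None
    dye_count: int = 0
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        self.positions = np.asarray(self.positions, float).reshape(-1, 3)
        self.charges = np.asarray(self.charges, float)
        self.radii = np.asarray(self.radii, float)
        n = len(self.positions)
        if len(self.charges) != n or len(self.radii) != n:
            raise ValueError("positions, charges and radii must have equal length")
        if np.any(self.radii <= 0):
            raise ValueError("all atomic radii must be positive")
        if self.names is None:
            self.names = [f"X{i}" for i in range(n)]
        if self.q_str is not None and abs(self.total_charge - self.q_str) > 1e-3:
            raise ValueError(
                f"total charge {self.total_charge:.4f} e does not match the "
                f"declared q_str {self.q_str:.4f} e")

    @property
    def n_atoms(self) -> int:
        return len(self.positions)

    @property
    def total_charge(self) -> float:
        return float(self.charges.sum())


def load_structure(path: str, fmt: Optional[str] = None) -> AtomicStructure:
    """Read a PQR (positions/charges/radii) or PDB (positions only) file.

    PQR units are Angstrom and elementary charges; coordinates are converted
    to nm. For PDB input, radii come from a bundled Bondi table and charges
    default to zero; the provenance dict records where each field came from.
    """
    import MDAnalysis as mda

    fmt = (fmt or str(path).rsplit(".", 1)[-1]).lower()
    if fmt not in ("pqr", "pdb"):
        raise ValueError(f"unsupported structure format: {fmt}")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe(str(path))
    atoms = u.atoms
    pos = atoms.positions / 10.0
    names = list(atoms.names)
    if fmt == "pqr":
        charges = atoms.charges.astype(float)
        radii = atoms.radii.astype(float) / 10.0
        prov = {"file": str(path), "charges": "pqr", "radii": "pqr"}
    else:
        charges = np.zeros(len(atoms))
        try:
            elements = [e.capitalize() for e in atoms.elements]
        except Exception:
            elements = [n[0].upper() for n in names]
        radii = np.array([VDW_RADII_NM.get(e, DEFAULT_VDW_NM) for e in elements])
        prov = {"file": str(path), "charges": "zero (pdb carries none)",
                "radii": "bundled Bondi table"}
    return AtomicStructure(pos, charges, radii, names=names, provenance=prov)


def write_pqr(structure: AtomicStructure, path: str):
    """Write a structure as PQR (Angstrom / e), round-tripping all fields."""
    import MDAnalysis as mda

    n = structure.n_atoms
    u = mda.Universe.empty(n, trajectory=True)
    u.add_TopologyAttr("names", list(structure.names))
    u.add_TopologyAttr("charges", structure.charges)
    u.add_TopologyAttr("radii", structure.radii * 10.0)
    u.add_TopologyAttr("resids", [1])
    u.add_TopologyAttr("resnames", ["MOL"])
    u.atoms.positions = structure.positions * 10.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u.atoms.write(str(path))


def write_xyz(structure: AtomicStructure, path: str):
    """Plain XYZ (Angstrom) for bead models."""
    with open(path, "w") as f:
        f.write(f"{structure.n_atoms}\n")
        f.write("etekit bead model (Angstrom)\n")
        for name, p in zip(structure.names, structure.positions * 10.0):
            f.write(f"{name} {p[0]:.4f} {p[1]:.4f} {p[2]:.4f}\n")


def adjust_terminal_charges(structure: AtomicStructure) -> AtomicStructure:
    """Apply the -1 e corrections to the terminal hydrogens H5T and H3T.

    Forcefield chains carry a raw total of -(n_b - 1) e because the terminal
    residues are fractionally charged; shifting each terminus by -1 e
    restores the -(n_b + 1) e structural charge of the fully ionized chain.
    Raises if the termini are absent or the correction was already applied.
    """
    if structure.provenance.get("termini_adjusted"):
        raise ValueError("terminal charges were already adjusted")
    names = list(structure.names)
    try:
        i5, i3 = names.index("H5T"), names.index("H3T")
    except ValueError as exc:
        raise ValueError("structure has no H5T/H3T terminal atoms; refusing to "
                         "guess the termini") from exc
    charges = structure.charges.copy()
    charges[i5] -= 1.0
    charges[i3] -= 1.0
    prov = dict(structure.provenance, termini_adjusted=True)
    new_q = structure.q_str - 2.0 if structure.q_str is not None else None
    return replace(structure, charges=charges, q_str=new_q, provenance=prov)


def build_half_helix(n_b: int, sequence_label: str = "ssDNA",
                     rise: float = HALF_HELIX_RISE,
                     twist_deg: float = HALF_HELIX_TWIST_DEG,
                     radius: float = HALF_HELIX_RADIUS,
                     bead_radius: float = 0.2, w: float = DEFAULT_W) -> AtomicStructure:
    """Ideal single-strand 'half-helix' bead model.

    One -1 e site per phosphate plus a terminal site are laid on the
    canonical B-form helix (rise 0.338 nm, twist 36 deg, radial distance
    0.89 nm), giving n_b + 1 sites and a total charge of -(n_b + 1) e.
    """
    if n_b < 1:
        raise ValueError("n_b must be at least 1")
    i = np.arange(n_b + 1)
    theta = np.deg2rad(twist_deg) * i
    pos = np.column_stack([radius * np.cos(theta), radius * np.sin(theta), rise * i])
    charges = np.full(n_b + 1, -1.0)
    radii = np.full(n_b + 1, bead_radius)
    return AtomicStructure(pos, charges, radii,
                           names=[f"P{j}" for j in i], w=w,
                           q_str=-(n_b + 1.0), dye_count=0,
                           provenance={"builder": "half-helix",
                                       "sequence": sequence_label, "n_b": n_b})


def ias_voxelize(structure: AtomicStructure, spacing: float,
                 margin: float = 0.5, probe: float = 0.1):
    """Ion-accessible region labels on a uniform grid.

    Cells within (vdW radius + w) of any atom are molecular interior; a
    morphological closing with a spherical element of the probe radius
    smooths crevices narrower than the probe. Returns (mask, edges).
    """
    if spacing > structure.w and structure.w > 0:
        raise ValueError("grid spacing must not exceed the exclusion width w")
    pos = structure.positions
    rad = structure.radii + structure.w
    lo = pos.min(axis=0) - rad.max() - margin
    hi = pos.max(axis=0) + rad.max() + margin
    edges = [np.arange(lo[ax], hi[ax] + spacing, spacing) for ax in range(3)]
    centers = [0.5 * (e[:-1] + e[1:]) for e in edges]
    X, Y, Z = np.meshgrid(*centers, indexing="ij")
    mask = np.zeros(X.shape, bool)
    for p, r in zip(pos, rad):
        mask |= (X - p[0]) ** 2 + (Y - p[1]) ** 2 + (Z - p[2]) ** 2 < r * r
    n_probe = int(probe / spacing)
    if n_probe >= 1:
        from scipy import ndimage

        ball = _ball_element(n_probe)
        mask = ndimage.binary_closing(mask, structure=ball)
    return mask, edges


def _ball_element(n: int) -> np.ndarray:
    ax = np.arange(-n, n + 1)
    X, Y, Z = np.meshgrid(ax, ax, ax, indexing="ij")
    return X ** 2 + Y ** 2 + Z ** 2 <= n * n


@dataclass(frozen=True)
class Conformer:
    """Backbone charge-site coordinates (phosphate positions), nm."""

    sites: np.ndarray
    label: str = ""

    def __post_init__(self):
        object.__setattr__(self, "sites", np.asarray(self.sites, float).reshape(-1, 3))
        if len(self.sites) < 2:
            raise ValueError("a conformer needs at least two charge sites")

    @property
    def r_g(self) -> float:
        c = self.sites - self.sites.mean(axis=0)
        return float(np.sqrt((c ** 2).sum(axis=1).mean()))

    @property
    def end_to_end(self) -> float:
        return float(np.linalg.norm(self.sites[-1] - self.sites[0]))

    @property
    def contour_length(self) -> float:
        return float(np.linalg.norm(np.diff(self.sites, axis=0), axis=1).sum())

    @property
    def b_c(self) -> float:
        """Contour length per base: mean consecutive inter-site distance."""
        return self.contour_length / (len(self.sites) - 1)

    def as_structure(self, bead_radius: float = 0.2, w: float = DEFAULT_W) -> AtomicStructure:
        n = len(self.sites)
        return AtomicStructure(self.sites, np.full(n, -1.0), np.full(n, bead_radius),
                               w=w, q_str=-float(n),
                               provenance={"builder": "conformer", "label": self.label})


def conformer_metrics(conformer: Conformer) -> dict:
    """{R_g, R, l_c, b_c} with unit site weights."""
    return {"R_g": conformer.r_g, "R": conformer.end_to_end,
            "l_c": conformer.contour_length, "b_c": conformer.b_c}


@dataclass
class Ensemble:
    """A collection of conformers with (R_g, R) density machinery."""

    conformers: list
    label: str = ""

    def __post_init__(self):
        if not self.conformers:
            raise ValueError("empty ensemble")

    @property
    def rg_r(self) -> np.ndarray:
        return np.array([[c.r_g, c.end_to_end] for c in self.conformers])

    def density(self):
        """Gaussian KDE over (R_g, R) with the scipy plug-in bandwidth."""
        from scipy.stats import gaussian_kde

        pts = self.rg_r.T
        return gaussian_kde(pts)


def select_representatives(ensemble: Ensemble, percentile: float = 25.0):
    """(mode, max-R-on-contour, min-R-on-contour) representative conformers.

    The mode is the ensemble member with the highest kernel density in
    (R_g, R); the stated-percentile contour is the highest-density region
    containing that mass fraction of members, and the other two
    representatives are the members of largest and smallest end-to-end
    distance within it.
    """
    pts = ensemble.rg_r
    if len(ensemble.conformers) < 3:
        raise ValueError("need at least 3 conformers")
    if np.allclose(pts, pts[0], atol=1e-12):
        warnings.warn("degenerate ensemble: all conformers identical", stacklevel=2)
        c = ensemble.conformers[0]
        return c, c, c
    if len(pts) >= 20:
        try:
            dens = ensemble.density()(pts.T)
        except np.linalg.LinAlgError:
            dens = _neighbour_density(pts)
    else:
        # tiny or nearly collinear clouds: KDE bandwidths are unreliable
        dens = _neighbour_density(pts)
    mode = ensemble.conformers[int(np.argmax(dens))]
    level = np.percentile(dens, 100.0 - percentile)
    in_hdr = dens >= level
    rs = pts[:, 1]
    idx = np.where(in_hdr)[0]
    c_max = ensemble.conformers[int(idx[np.argmax(rs[idx])])]
    c_min = ensemble.conformers[int(idx[np.argmin(rs[idx])])]
    return mode, c_max, c_min


def _neighbour_density(pts: np.ndarray) -> np.ndarray:
    """Brute-force nearest-neighbour density estimate."""
    from scipy.spatial import cKDTree

    d, _ = cKDTree(pts).query(pts, k=min(5, len(pts)))
    return 1.0 / (d[:, 1:].mean(axis=1) + 1e-300)


def ensemble_metrics_table(ensemble: Ensemble):
    """Per-conformer metrics as a pandas DataFrame (id, R_g, R, l_c, b_c)."""
    import pandas as pd

    rows = [{"id": i, **conformer_metrics(c)} for i, c in enumerate(ensemble.conformers)]
    return pd.DataFrame(rows)
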