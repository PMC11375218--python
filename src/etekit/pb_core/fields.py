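"""Potential-field containers and serialization.

Each solver returns a field object exposing the nondimensional potential
psi = e*phi/kBT on its grid together with region labels, the converged
residual, and geometry-aware integration helpers used by the free-energy
and ion-counting routines.
"""
from __future__ import annotations

from dataclasses import dataclass, field as dfield
from typing import Optional

import numpy as np

REGION_ELECTROLYTE = 0
REGION_INTERIOR = 1
REGION_WALL = 2

__all__ = [
    "PlanarField", "SlitPocketField", "RodField", "Field3D",
    "save_field_h5", "save_profile_txt",
    "REGION_ELECTROLYTE", "REGION_INTERIOR", "REGION_WALL",
]


@dataclass
class _FieldBase:
    psi: np.ndarray
    regions: np.ndarray          # per-cell labels
    residual: float
    tol: float
    electrolyte: object = dfield(repr=False, default=None)

    @property
    def converged(self) -> bool:
        return self.residual <= self.tol

    def require_converged(self):
        if not self.converged:
            raise RuntimeError(
                f"field not converged: residual {self.residual:.2e} > tol {self.tol:.2e}")


@dataclass
class PlanarField(_FieldBase):
    """1D solution across the slit gap; coordinate z in nm, walls at the ends."""
    z: np.ndarray = None
    dz: np.ndarray = None
    geometry: str = "planar-1d"

    @property
    def wall_potential(self) -> float:
        return float(self.psi[0])

    @property
    def midplane_potential(self) -> float:
        return float(np.interp(0.0, self.z, self.psi))


@dataclass
class SlitPocketField(_FieldBase):
    """2D cross-section (x lateral, z across the gap) of the slit-pocket device."""
    x: np.ndarray = None
    z: np.ndarray = None
    vol: np.ndarray = None
    device: object = None
    geometry: str = "slit-pocket-2d"

    def potential_at(self, x: float, z: float) -> float:
        ix = int(np.argmin(np.abs(self.x - x)))
        iz = int(np.argmin(np.abs(self.z - z)))
        return float(self.psi[ix, iz])

    @property
    def slit_midplane(self) -> float:
        """Midplane potential in the slit region far from the pocket."""
        xs = self.x[-1] - 0.05 * (self.x[-1] - self.x[0])
        return self.potential_at(xs, 0.0)

    @property
    def pocket_midplane(self) -> float:
        """Potential at the local midplane of the pocket gap, above pocket centre."""
        zmid = 0.5 * (self.z[0] + self.device.half_height) if self.device else self.z[0]
        return self.potential_at(self.x[0], zmid)

    @property
    def delta_phi_mid(self) -> float:
        return self.slit_midplane - self.pocket_midplane


@dataclass
class RodField(_FieldBase):
    """Axisymmetric solution (rho, z) around a finite charged rod in bulk."""
    rho_edges: np.ndarray = None
    z_edges: np.ndarray = None
    rod: object = None
    geometry: str = "axisymmetric-2d"

    @property
    def rho(self):
        return 0.5 * (self.rho_edges[:-1] + self.rho_edges[1:])

    @property
    def z(self):
        return 0.5 * (self.z_edges[:-1] + self.z_edges[1:])

    @property
    def vol(self):
        return (2 * np.pi * self.rho * np.diff(self.rho_edges))[:, None] * \
            np.diff(self.z_edges)[None, :]

    @property
    def electrolyte_mask(self):
        return self.regions == REGION_ELECTROLYTE

    def surface_potential(self, include_caps: bool = False) -> float:
        """Area-averaged potential on the rod surface.

        Quadratic extrapolation of the first three electrolyte cells onto the
        cylinder side surface; optionally includes the (uncharged) end caps.
        """
        rod = self.rod
        rho_c, z_c = self.rho, self.z
        i0 = int(np.searchsorted(rho_c, rod.radius))
        mz = np.abs(z_c) < rod.length / 2 - 1e-12
        x0, x1, x2 = rho_c[i0], rho_c[i0 + 1], rho_c[i0 + 2]
        r = rod.radius
        L0 = ((r - x1) * (r - x2)) / ((x0 - x1) * (x0 - x2))
        L1 = ((r - x0) * (r - x2)) / ((x1 - x0) * (x1 - x2))
        L2 = ((r - x0) * (r - x1)) / ((x2 - x0) * (x2 - x1))
        psis = L0 * self.psi[i0, mz] + L1 * self.psi[i0 + 1, mz] + L2 * self.psi[i0 + 2, mz]
        wz = np.diff(self.z_edges)[mz]
        side = float(np.sum(psis * wz) / np.sum(wz))
        if not include_caps:
            return side
        j0 = int(np.searchsorted(z_c, rod.length / 2))
        mr = rho_c < rod.radius
        z0, z1, z2 = z_c[j0], z_c[j0 + 1], z_c[j0 + 2]
        zh = rod.length / 2
        M0 = ((zh - z1) * (zh - z2)) / ((z0 - z1) * (z0 - z2))
        M1 = ((zh - z0) * (zh - z2)) / ((z1 - z0) * (z1 - z2))
        M2 = ((zh - z0) * (zh - z1)) / ((z2 - z0) * (z2 - z1))
        psic = M0 * self.psi[mr, j0] + M1 * self.psi[mr, j0 + 1] + M2 * self.psi[mr, j0 + 2]
        wr = self.rho_edges[1:][mr] ** 2 - self.rho_edges[:-1][mr] ** 2
        cap = float(np.sum(psic * wr) / np.sum(wr))
        a_side = 2 * np.pi * rod.radius * rod.length
        a_cap = 2 * np.pi * rod.radius ** 2
        return (side * a_side + cap * a_cap) / (a_side + a_cap)


@dataclass
class Field3D(_FieldBase):
    """3D Cartesian solution on a nonuniform tensor grid."""
    grid: object = None
    vol: np.ndarray = None
    sources: object = None       # (positions (N,3), charges (N,))
    wall_sigma: Optional[float] = None
    geometry: str = "cartesian-3d"

    @property
    def electrolyte_mask(self):
        return self.regions == REGION_ELECTROLYTE

    def interpolate(self, points):
        from scipy.interpolate import RegularGridInterpolator

        itp = RegularGridInterpolator(self.grid.centers, self.psi,
                                      bounds_error=False, fill_value=0.0)
        return itp(np.atleast_2d(points))


def save_field_h5(field, path: str):
    """Write a field and its grid to an HDF5 file."""
    import h5py

    with h5py.File(path, "w") as f:
        f.attrs["geometry"] = field.geometry
        f.attrs["residual"] = field.residual
        f.create_dataset("psi", data=field.psi)
        f.create_dataset("regions", data=np.asarray(field.regions, dtype=np.int8))
        if hasattr(field, "grid") and field.grid is not None:
            for ax, e in enumerate(field.grid.edges):
                f.create_dataset(f"edges_{'xyz'[ax]}", data=e)
        for name in ("z", "x", "rho_edges", "z_edges"):
            arr = getattr(field, name, None)
            if arr is not None:
                f.create_dataset(name, data=np.asarray(arr))


def save_profile_txt(path: str, coord: np.ndarray, psi: np.ndarray,
                     coord_name: str = "z_nm"):
    """Two-column delimited text profile (coordinate nm, psi kBT/e)."""
    arr = np.column_stack([coord, psi])
    np.savetxt(path, arr, header=f"{coord_name}\tpsi_kBT_per_e", delimiter="\t")
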