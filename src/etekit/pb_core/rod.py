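"""Axisymmetric nonlinear PB around a finite, uniformly surface-charged rod."""
from __future__ import annotations

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .electrolyte import Electrolyte
from .fields import RodField, REGION_ELECTROLYTE, REGION_INTERIOR
from .grids import stretched
from .options import SolverOptions

__all__ = ["solve_rod"]

FOUR_PI = 4.0 * np.pi


def _rod_grid(radius: float, length: float, electrolyte: Electrolyte,
              options: SolverOptions):
    kd = electrolyte.debye
    h_srf = min(options.fine_spacing, max(radius / 8.0, 0.01))
    hmax = kd * options.far_spacing_debye * 0.5
    ratio = min(options.stretch_ratio, 1.12)
    r_max = radius + options.padding_debye * kd
    z_max = length / 2 + options.padding_debye * kd
    n_in = max(4, int(round(radius / h_srf)))
    rho_in = np.linspace(0.0, radius, n_in + 1)
    rho_out = stretched(h_srf, hmax, ratio, radius, r_max)
    rho_e = np.concatenate([rho_in, rho_out[1:]])
    z_half_in = stretched(2 * h_srf, min(hmax, max(length / 8, 2 * h_srf)),
                          ratio, length / 2, 0.0)[::-1]
    z_half_out = stretched(h_srf, hmax, ratio, length / 2, z_max)
    zp = np.concatenate([z_half_in, z_half_out[1:]])
    z_e = np.concatenate([-zp[::-1], zp[1:]])
    return rho_e, z_e


def solve_rod(rod, electrolyte: Electrolyte,
              options: SolverOptions | None = None) -> RodField:
    """Solve the nonlinear PB equation around a finite rod in bulk electrolyte.

    The rod (radius r, length l, total charge q_str) carries a uniform
    charge density q_str/(2 pi r l) on its side surface, imposed as a
    constant-charge Neumann condition; the end caps are uncharged and the
    ion-free interior is excluded from the electrolyte region. The far
    boundary (at ``options.padding_debye`` Debye lengths) is clamped to zero.
    """
    options = options or SolverOptions()
    r, length, q_str = rod.radius, rod.length, rod.q_str
    if length <= 0:
        raise ValueError("rod length must be positive")
    kd = electrolyte.debye
    if r >= options.padding_debye * kd:
        raise ValueError("rod radius exceeds the domain padding")
    k = electrolyte.kappa
    lb = electrolyte.bjerrum

    rho_e, z_e = _rod_grid(r, length, electrolyte, options)
    rho_c = 0.5 * (rho_e[:-1] + rho_e[1:])
    z_c = 0.5 * (z_e[:-1] + z_e[1:])
    nr, nz = len(rho_c), len(z_c)
    drho, dz = np.diff(rho_e), np.diff(z_e)
    RC, ZC = np.meshgrid(rho_c, z_c, indexing="ij")
    inside = (RC < r) & (np.abs(ZC) < length / 2)
    elec = ~inside
    vol = (2 * np.pi * rho_c * drho)[:, None] * dz[None, :]
    idx = np.arange(nr * nz).reshape(nr, nz)
    dr_c, dz_c = np.diff(rho_c), np.diff(z_c)

    b = np.zeros(nr * nz)
    rows, cols, vals = [], [], []

    # radial faces (area 2 pi rho_f dz)
    a_r = (2 * np.pi * rho_e[1:-1])[:, None] * dz[None, :]
    g_r = a_r / dr_c[:, None]
    both = elec[:-1, :] & elec[1:, :]
    i1, i2 = idx[:-1, :][both], idx[1:, :][both]
    gv = g_r[both]
    rows += [i1, i2, i1, i2]
    cols += [i1, i2, i2, i1]
    vals += [gv, gv, -gv, -gv]
    # charged side surface: faces with rod inside, electrolyte outside
    sigma = q_str / (2 * np.pi * r * length)
    srf = inside[:-1, :] & elec[1:, :]
    b[idx[1:, :][srf]] += FOUR_PI * lb * sigma * a_r[srf]

    # axial faces (area 2 pi rho_c drho); caps are uncharged (zero flux)
    a_z = (2 * np.pi * rho_c * drho)[:, None] * np.ones((1, nz - 1))
    g_z = a_z / dz_c[None, :]
    both = elec[:, :-1] & elec[:, 1:]
    i1, i2 = idx[:, :-1][both], idx[:, 1:][both]
    gv = g_z[both]
    rows += [i1, i2, i1, i2]
    cols += [i1, i2, i2, i1]
    vals += [gv, gv, -gv, -gv]

    # Dirichlet psi=0 on the open outer boundaries
    diag_extra = np.zeros(nr * nz)
    diag_extra[idx[-1, :]] += 2 * np.pi * rho_e[-1] * dz / (rho_e[-1] - rho_c[-1])
    a_cap = 2 * np.pi * rho_c * drho
    diag_extra[idx[:, 0]] += a_cap / (z_c[0] - z_e[0])
    diag_extra[idx[:, -1]] += a_cap / (z_e[-1] - z_c[-1])

    A = sp.csr_matrix((np.concatenate(vals),
                       (np.concatenate(rows), np.concatenate(cols))),
                      shape=(nr * nz, nr * nz))
    A = A + sp.diags(diag_extra) + sp.diags(inside.ravel().astype(float))

    volf, elecf = vol.ravel(), elec.ravel()
    k2 = k * k
    psi = np.zeros(nr * nz)
    bnorm = max(np.linalg.norm(b), 1e-300)
    res = np.inf
    for _ in range(options.max_iterations):
        s = np.where(elecf, k2 * np.sinh(np.clip(psi, -40, 40)) * volf, 0.0)
        F = A @ psi + s - b
        res = np.linalg.norm(F) / bnorm
        if res < options.tol:
            break
        J = A + sp.diags(np.where(elecf, k2 * np.cosh(np.clip(psi, -40, 40)) * volf, 0.0))
        d = spla.spsolve(J.tocsc(), -F)
        lam, Fn = 1.0, np.linalg.norm(F)
        while lam > 1e-4:
            pn = psi + lam * d
            sn = np.where(elecf, k2 * np.sinh(np.clip(pn, -40, 40)) * volf, 0.0)
            if np.linalg.norm(A @ pn + sn - b) < (1 - 0.25 * lam) * Fn:
                break
            lam *= 0.5
        psi = psi + lam * d
    if res > options.tol:
        raise RuntimeError(f"rod PB solve did not converge (residual {res:.2e})")
    regions = np.where(inside, REGION_INTERIOR, REGION_ELECTROLYTE)
    return RodField(psi=psi.reshape(nr, nz), regions=regions, residual=res,
                    tol=options.tol, electrolyte=electrolyte,
                    rho_edges=rho_e, z_edges=z_e, rod=rod)
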