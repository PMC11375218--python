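"""2D nonlinear PB over the slit-pocket cross-section."""
from __future__ import annotations

import warnings

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .device import SlitDevice
from .electrolyte import Electrolyte
from .fields import SlitPocketField, REGION_ELECTROLYTE, REGION_WALL
from .options import SolverOptions

__all__ = ["solve_slit_pocket_2d"]

FOUR_PI = 4.0 * np.pi


def solve_slit_pocket_2d(device: SlitDevice, electrolyte: Electrolyte,
                         options: SolverOptions | None = None) -> SlitPocketField:
    """Solve the device cross-section: slit of gap 2h with a pocket recess.

    Geometry (x lateral from the pocket axis, z across the gap): the top
    wall sits at z = +h for all x; for x < pocket_radius the bottom wall is
    recessed to z = -(h + d), else it is at z = -h. All wall faces carry the
    same constant charge density. x = 0 is a symmetry plane and the far
    lateral edge is treated as an unperturbed slit (zero flux).

    The key output is ``delta_phi_mid``: slit midplane potential minus the
    potential at the local midplane of the pocket gap.
    """
    options = options or SolverOptions()
    kd = electrolyte.debye
    if device.pocket_depth < 3.0 * kd:
        warnings.warn("pocket depth below 3 Debye lengths: pocket and slit "
                      "midplane potentials may not decouple", stacklevel=2)
    sigma = device.wall_sigma(electrolyte)
    k = electrolyte.kappa
    lb = electrolyte.bjerrum

    h, d, prad = device.half_height, device.pocket_depth, device.pocket_radius
    span = max(device.channel_span, prad + 12.0 * kd)
    hx = min(1.0, kd / 6.0)
    xe = np.unique(np.concatenate([
        np.arange(0.0, prad + 20.0, hx),
        np.arange(prad + 20.0, span + 1e-9, 2.0 * hx)]))
    hz = min(1.0, kd / 8.0)
    ze = np.unique(np.concatenate([
        np.arange(-(h + d), -h - 15.0, 2.0 * hz),
        np.arange(-h - 15.0, h + 1e-9, hz)]))
    ze[-1] = h
    xc, zc = 0.5 * (xe[:-1] + xe[1:]), 0.5 * (ze[:-1] + ze[1:])
    nx, nz = len(xc), len(zc)
    dx, dz = np.diff(xe), np.diff(ze)
    X, Z = np.meshgrid(xc, zc, indexing="ij")
    solid = (Z < -h) & (X > prad)
    elec = ~solid
    idx = np.arange(nx * nz).reshape(nx, nz)
    dxc, dzc = np.diff(xc), np.diff(zc)

    b = np.zeros(nx * nz)
    rows, cols, vals = [], [], []

    # x faces
    both = elec[:-1, :] & elec[1:, :]
    gv = (dz[None, :] / dxc[:, None])[both]
    i1, i2 = idx[:-1, :][both], idx[1:, :][both]
    rows += [i1, i2, i1, i2]; cols += [i1, i2, i2, i1]; vals += [gv, gv, -gv, -gv]
    wf = elec[:-1, :] & solid[1:, :]   # pocket side wall
    b[idx[:-1, :][wf]] += FOUR_PI * lb * sigma * np.broadcast_to(dz, wf.shape)[wf]

    # z faces
    both = elec[:, :-1] & elec[:, 1:]
    gv = (dx[:, None] / dzc[None, :])[both]
    i1, i2 = idx[:, :-1][both], idx[:, 1:][both]
    rows += [i1, i2, i1, i2]; cols += [i1, i2, i2, i1]; vals += [gv, gv, -gv, -gv]
    wf = elec[:, 1:] & solid[:, :-1]   # slit bottom wall edge above solid
    b[idx[:, 1:][wf]] += FOUR_PI * lb * sigma * np.broadcast_to(dx[:, None], wf.shape)[wf]

    # domain-boundary walls: top wall everywhere, pocket bottom where open
    b[idx[:, -1]] += FOUR_PI * lb * sigma * dx
    m0 = elec[:, 0]
    b[idx[m0, 0]] += FOUR_PI * lb * sigma * dx[m0]
    # x = 0 symmetry and far lateral edge: natural zero-flux (nothing to add)

    A = sp.csr_matrix((np.concatenate(vals),
                       (np.concatenate(rows), np.concatenate(cols))),
                      shape=(nx * nz, nx * nz))
    A = A + sp.diags(solid.ravel().astype(float))
    b[solid.ravel()] = 0.0

    vol = (dx[:, None] * dz[None, :])
    volf, elecf = vol.ravel(), elec.ravel()
    k2 = k * k
    psi = np.zeros(nx * nz)
    bnorm = max(np.linalg.norm(b), 1e-300)
    res = np.inf
    for _ in range(options.max_iterations):
        s = np.where(elecf, k2 * np.sinh(np.clip(psi, -40, 40)) * volf, 0.0)
        F = A @ psi + s - b
        res = np.linalg.norm(F) / bnorm
        if res < options.tol:
            break
        J = A + sp.diags(np.where(elecf, k2 * np.cosh(np.clip(psi, -40, 40)) * volf, 0.0))
        dlt = spla.spsolve(J.tocsc(), -F)
        lam, Fn = 1.0, np.linalg.norm(F)
        while lam > 1e-4:
            pn = psi + lam * dlt
            sn = np.where(elecf, k2 * np.sinh(np.clip(pn, -40, 40)) * volf, 0.0)
            if np.linalg.norm(A @ pn + sn - b) < (1 - 0.25 * lam) * Fn:
                break
            lam *= 0.5
        psi = psi + lam * dlt
    if res > options.tol and bnorm > 1e-200:
        raise RuntimeError(f"slit-pocket solve did not converge (residual {res:.2e})")
    regions = np.where(solid, REGION_WALL, REGION_ELECTROLYTE)
    return SlitPocketField(psi=psi.reshape(nx, nz), regions=regions,
                           residual=res if bnorm > 1e-200 else 0.0,
                           tol=options.tol, electrolyte=electrolyte,
                           x=xc, z=zc, vol=vol, device=device)
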