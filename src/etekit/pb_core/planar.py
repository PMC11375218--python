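"""1D nonlinear PB between two charged plates."""
from __future__ import annotations

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from scipy.optimize import brentq

from .device import SlitDevice
from .electrolyte import Electrolyte
from .fields import PlanarField, REGION_ELECTROLYTE
from .options import SolverOptions

__all__ = ["solve_planar_slit", "wall_charge_for_potential", "grahame_sigma"]

FOUR_PI = 4.0 * np.pi


def _solve_1d(sigma_w: float, half_height: float, electrolyte: Electrolyte,
              n_cells: int, tol: float, max_iter: int):
    k = electrolyte.kappa
    lb = electrolyte.bjerrum
    ze = np.linspace(-half_height, half_height, n_cells + 1)
    zc = 0.5 * (ze[:-1] + ze[1:])
    dz = np.diff(ze)
    g = 1.0 / np.diff(zc)
    b = np.zeros(n_cells)
    b[0] = FOUR_PI * lb * sigma_w
    b[-1] = FOUR_PI * lb * sigma_w
    psi = np.zeros(n_cells)
    bnorm = max(np.linalg.norm(b), 1e-300)
    res = np.inf
    for _ in range(max_iter):
        flux = g * (psi[1:] - psi[:-1])
        F = np.zeros(n_cells)
        F[:-1] -= flux
        F[1:] += flux
        F += k * k * np.sinh(np.clip(psi, -40, 40)) * dz - b
        res = np.linalg.norm(F) / bnorm
        if res < tol:
            break
        diag = np.zeros(n_cells)
        diag[:-1] += g
        diag[1:] += g
        diag += k * k * np.cosh(np.clip(psi, -40, 40)) * dz
        J = sp.diags([diag, -g, -g], [0, -1, 1], format="csc")
        d = spla.spsolve(J, -F)
        lam, Fn = 1.0, np.linalg.norm(F)
        while lam > 1e-4:
            pn = psi + lam * d
            flux = g * (pn[1:] - pn[:-1])
            Fn2 = np.zeros(n_cells)
            Fn2[:-1] -= flux
            Fn2[1:] += flux
            Fn2 += k * k * np.sinh(np.clip(pn, -40, 40)) * dz - b
            if np.linalg.norm(Fn2) < (1 - 0.25 * lam) * Fn:
                break
            lam *= 0.5
        psi = psi + lam * d
    return zc, dz, psi, res


def solve_planar_slit(device: SlitDevice, electrolyte: Electrolyte,
                      options: SolverOptions | None = None) -> PlanarField:
    """Nonlinear PB between constant-charge plates at z = +-h.

    Returns a :class:`PlanarField`; its ``wall_potential`` and
    ``midplane_potential`` are the quantities of interest. With uncharged
    walls the solution is identically zero.
    """
    options = options or SolverOptions()
    sigma = device.wall_sigma(electrolyte)
    n = max(400, int(device.gap / min(options.fine_spacing, 0.1)))
    n = min(n, 4000)
    zc, dz, psi, res = _solve_1d(sigma, device.half_height, electrolyte, n,
                                 options.tol, options.max_iterations)
    if res > options.tol:
        raise RuntimeError(
            f"planar PB solve did not converge (residual {res:.2e}); "
            "check grid spacing and tolerance")
    return PlanarField(psi=psi, regions=np.full(n, REGION_ELECTROLYTE),
                       residual=res, tol=options.tol, electrolyte=electrolyte,
                       z=zc, dz=dz)


def grahame_sigma(phi_s: float, electrolyte: Electrolyte) -> float:
    """Isolated-wall (Gouy-Chapman) charge density for surface potential phi_s.

    sigma = kappa sinh(phi_s/2) / (2 pi l_B), in e/nm^2; used as a bracket
    seed when tuning the wall charge of the interacting two-plate problem.
    """
    return electrolyte.kappa * np.sinh(phi_s / 2.0) / (2.0 * np.pi * electrolyte.bjerrum)


def wall_charge_for_potential(phi_s: float, device: SlitDevice,
                              electrolyte: Electrolyte,
                              options: SolverOptions | None = None) -> float:
    """Wall charge density whose two-plate solution has wall potential phi_s."""
    if phi_s == 0.0:
        return 0.0
    options = options or SolverOptions()
    dev = device.with_sigma(0.0)

    def f(sig):
        fld = solve_planar_slit(dev.with_sigma(sig), electrolyte, options)
        return fld.wall_potential - phi_s

    s0 = grahame_sigma(phi_s, electrolyte)
    lo, hi = (2.5 * s0, s0 / 4.0) if s0 < 0 else (s0 / 4.0, 2.5 * s0)
    return brentq(f, lo, hi, xtol=1e-10, rtol=1e-10)
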