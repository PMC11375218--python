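"""Electrostatic free energy and ion-atmosphere integrals.

The free-energy functional integrates, over the solvent region only,

    F_el = int [ eps eps0/2 |E|^2 - 2 c0 N_A kBT (cosh psi - psi sinh psi - 1) ] dV

expressed here in k_BT with lengths in nm:

    F_el/kBT = int [ |grad psi|^2 / (8 pi l_B)
                     - kappa^2/(4 pi l_B) (cosh psi - psi sinh psi - 1) ] dV.

The gradient term is accumulated face-by-face with the same finite-volume
metric as the solver, so energy differences between solves on identical
grids benefit from cancellation of discretization error.
"""
from __future__ import annotations

import numpy as np

from .fields import Field3D, RodField

__all__ = ["free_energy", "ionic_charge_integral", "ion_excess_integrals"]


def _osmotic(psi):
    pc = np.clip(psi, -40, 40)
    return np.cosh(pc) - pc * np.sinh(pc) - 1.0


def _free_energy_rod(field: RodField) -> float:
    el = field.electrolyte
    lb, k = el.bjerrum, el.kappa
    psi = field.psi
    rho_e, z_e = field.rho_edges, field.z_edges
    rho_c, z_c = field.rho, field.z
    dz, drho = np.diff(z_e), np.diff(rho_e)
    solv = field.electrolyte_mask
    grad2 = 0.0
    # radial faces
    a = (2 * np.pi * rho_e[1:-1])[:, None] * dz[None, :]
    dcc = np.diff(rho_c)[:, None]
    m = solv[:-1, :] & solv[1:, :]
    grad2 += np.sum((((psi[1:] - psi[:-1]) / dcc) ** 2 * a * dcc)[m])
    # axial faces
    a = (2 * np.pi * rho_c * drho)[:, None] * np.ones((1, len(z_c) - 1))
    dcc = np.diff(z_c)[None, :]
    m = solv[:, :-1] & solv[:, 1:]
    grad2 += np.sum((((psi[:, 1:] - psi[:, :-1]) / dcc) ** 2 * a * dcc)[m])
    # charged rod surface faces: |grad psi| fixed by the Neumann condition
    rod = field.rod
    sigma = rod.q_str / (2 * np.pi * rod.radius * rod.length)
    i0 = int(np.searchsorted(rho_c, rod.radius))
    mz = np.abs(z_c) < rod.length / 2
    half = rho_c[i0] - rod.radius
    grad2 += np.sum((4 * np.pi * lb * sigma) ** 2 * 2 * np.pi * rod.radius * dz[mz] * half)
    F1 = grad2 / (8 * np.pi * lb)
    F2 = -k * k / (4 * np.pi * lb) * np.sum(_osmotic(psi)[solv] * field.vol[solv])
    return float(F1 + F2)


def _free_energy_3d(field: Field3D) -> float:
    el = field.electrolyte
    lb, k = el.bjerrum, el.kappa
    g = field.grid
    psi = field.psi
    solv = field.electrolyte_mask
    dx, dy, dz = g.widths
    grad2 = 0.0
    dcc = np.diff(g.centers[0])[:, None, None]
    a = dy[None, :, None] * dz[None, None, :]
    m = solv[:-1] & solv[1:]
    grad2 += np.sum((((psi[1:] - psi[:-1]) / dcc) ** 2 * a * dcc)[m])
    dcc = np.diff(g.centers[1])[None, :, None]
    a = dx[:, None, None] * dz[None, None, :]
    m = solv[:, :-1] & solv[:, 1:]
    grad2 += np.sum((((psi[:, 1:] - psi[:, :-1]) / dcc) ** 2 * a * dcc)[m])
    dcc = np.diff(g.centers[2])[None, None, :]
    a = dx[:, None, None] * dy[None, :, None]
    m = solv[:, :, :-1] & solv[:, :, 1:]
    grad2 += np.sum((((psi[:, :, 1:] - psi[:, :, :-1]) / dcc) ** 2 * a * dcc)[m])
    if field.wall_sigma is not None:
        # wall faces carry the imposed gradient over the adjacent half-cell
        slope = 4 * np.pi * lb * field.wall_sigma
        a = dx[:, None] * dy[None, :]
        for iz, edge in ((0, g.edges[2][0]), (-1, g.edges[2][-1])):
            half = abs(g.centers[2][iz] - edge)
            grad2 += np.sum(slope ** 2 * a[solv[:, :, iz]] * half)
    F1 = grad2 / (8 * np.pi * lb)
    F2 = -k * k / (4 * np.pi * lb) * np.sum(_osmotic(psi)[solv] * field.vol[solv])
    return float(F1 + F2)


def free_energy(field) -> float:
    """Electrostatic free energy F_el of a converged field, in k_BT.

    Integration is restricted to the electrolyte region; zero field gives
    exactly zero. Raises on unconverged input.
    """
    field.require_converged()
    if isinstance(field, RodField):
        return _free_energy_rod(field)
    if isinstance(field, Field3D):
        return _free_energy_3d(field)
    raise TypeError(f"free_energy does not support {type(field).__name__}")


def ionic_charge_integral(field) -> float:
    """Net ion-atmosphere charge (e): volume integral of the Boltzmann ion
    density over the electrolyte region. Equals minus the object charge for
    an isolated object in bulk (electroneutrality)."""
    field.require_converged()
    el = field.electrolyte
    pc = np.clip(field.psi, -40, 40)
    m = field.electrolyte_mask
    return float(-el.kappa ** 2 / (4 * np.pi * el.bjerrum) *
                 np.sum(np.sinh(pc)[m] * field.vol[m]))


def ion_excess_integrals(field) -> tuple[float, float]:
    """(counterion excess, coion deficit) in ions per molecule, both positive
    for a negatively charged object in a 1:1 electrolyte."""
    field.require_converged()
    el = field.electrolyte
    n0 = el.number_density(el.species[0])
    pc = np.clip(field.psi, -40, 40)
    m = field.electrolyte_mask
    gamma_plus = n0 * np.sum((np.exp(-pc) - 1.0)[m] * field.vol[m])
    gamma_minus_deficit = n0 * np.sum((1.0 - np.exp(pc))[m] * field.vol[m])
    return float(gamma_plus), float(gamma_minus_deficit)
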