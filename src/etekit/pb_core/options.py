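"""Solver configuration."""
from __future__ import annotations

from dataclasses import dataclass

from ..constants import EPS_MOL

__all__ = ["SolverOptions"]


@dataclass(frozen=True)
class SolverOptions:
    """Tunables of the nonlinear PB solvers.

    fine_spacing : grid spacing (nm) in the fine window around the molecule.
    far_spacing_debye : far-field spacing as a fraction of the Debye length.
    stretch_ratio : geometric growth factor between the two regimes.
    padding_debye : distance (in Debye lengths) from the object to the open
        boundaries, where the potential is clamped to zero; at least 6 is
        required for converged free energies and far fields.
    tol : relative nonlinear residual at convergence.
    max_iterations : Newton iteration cap.
    eps_mol : relative permittivity of the ion-free molecular interior.
    """

    fine_spacing: float = 0.1
    far_spacing_debye: float = 1.0 / 3.0
    stretch_ratio: float = 1.18
    padding_debye: float = 8.0
    tol: float = 1e-8
    max_iterations: int = 40
    eps_mol: float = EPS_MOL

    def __post_init__(self):
        if self.tol <= 0:
            raise ValueError("tolerance must be positive")
        if self.padding_debye < 6.0:
            raise ValueError("padding must be at least 6 Debye lengths")
        if self.fine_spacing <= 0 or self.far_spacing_debye <= 0:
            raise ValueError("grid spacings must be positive")
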