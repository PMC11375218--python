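"""Nanoslit trap device geometry and wall-charge bookkeeping."""
from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

__all__ = ["SlitDevice"]


@dataclass(frozen=True)
class SlitDevice:
    """Parallel-plate nanoslit with a cylindrical pocket recess.

    half_height : slit half-gap h (nm); the plates sit at z = +-h.
    pocket_depth : additional recess depth d (nm); the local gap in the
        pocket region is 2h + d.
    pocket_radius : in-plane pocket radius (nm).
    channel_span : lateral extent of the modelled cross-section (nm).
    Exactly one of ``sigma_w`` (wall charge density, e/nm^2) or ``phi_s``
    (effective wall surface potential, k_BT/e) is given; the other is derived
    from the 1D slit solution for a given electrolyte (see
    :func:`etekit.pb_core.planar.wall_charge_for_potential`).
    """

    half_height: float
    pocket_depth: float
    pocket_radius: float = 300.0
    channel_span: float = 600.0
    sigma_w: Optional[float] = None
    phi_s: Optional[float] = None

    def __post_init__(self):
        if self.half_height <= 0 or self.pocket_depth <= 0:
            raise ValueError("slit half-height and pocket depth must be positive")
        if (self.sigma_w is None) == (self.phi_s is None):
            raise ValueError("exactly one of sigma_w and phi_s must be specified")

    @property
    def gap(self) -> float:
        """Slit gap 2h (nm)."""
        return 2.0 * self.half_height

    @property
    def pocket_gap(self) -> float:
        """Total gap in the pocket region, 2h + d (nm)."""
        return self.gap + self.pocket_depth

    def with_sigma(self, sigma_w: float) -> "SlitDevice":
        return replace(self, sigma_w=sigma_w, phi_s=None)

    def wall_sigma(self, electrolyte) -> float:
        """Wall charge density (e/nm^2), deriving it from phi_s if needed."""
        if self.sigma_w is not None:
            return self.sigma_w
        from .planar import wall_charge_for_potential

        return wall_charge_for_potential(self.phi_s, self, electrolyte)

    def surface_potential(self, electrolyte) -> float:
        """Wall surface potential (k_BT/e), deriving it from sigma_w if needed."""
        if self.phi_s is not None:
            return self.phi_s
        from .planar import solve_planar_slit

        return solve_planar_slit(self, electrolyte).wall_potential

    def midplane_potential(self, electrolyte) -> float:
        """Slit midplane potential phi_m ~ 2 phi_s exp(-kappa h), k_BT/e.

        Uses the printed closed-form estimate; the nonlinear value is
        available from :func:`etekit.pb_core.planar.solve_planar_slit`.
        """
        import math

        return 2.0 * self.surface_potential(electrolyte) * math.exp(
            -electrolyte.kappa * self.half_height)
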