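"""Electrolyte composition and derived screening properties."""
from __future__ import annotations

import math
from dataclasses import dataclass

from ..constants import AVOGADRO, EPS_WATER, TEMPERATURE, bjerrum_length

__all__ = ["IonSpecies", "Electrolyte", "debye_length"]


@dataclass(frozen=True)
class IonSpecies:
    valence: int
    concentration: float  # bulk, mol/L

    def __post_init__(self):
        if self.concentration <= 0:
            raise ValueError("ion concentration must be positive")
        if self.valence == 0:
            raise ValueError("ion valence must be nonzero")


@dataclass(frozen=True)
class Electrolyte:
    """Bulk electrolyte: ionic species, temperature and solvent permittivity.

    The derived Debye length kappa^-1 and Bjerrum length l_B are exposed as
    properties. Bulk electroneutrality (sum z_i c_i = 0) is enforced at
    construction.
    """

    species: tuple[IonSpecies, ...]
    temperature: float = TEMPERATURE
    eps_r: float = EPS_WATER

    def __post_init__(self):
        if not self.species:
            raise ValueError("electrolyte requires at least one ionic species")
        net = sum(s.valence * s.concentration for s in self.species)
        scale = sum(abs(s.valence) * s.concentration for s in self.species)
        if abs(net) > 1e-9 * scale:
            raise ValueError("bulk electrolyte is not electroneutral")

    @classmethod
    def monovalent(cls, c0: float, temperature: float = TEMPERATURE,
                   eps_r: float = EPS_WATER) -> "Electrolyte":
        """Symmetric 1:1 salt (e.g. NaCl) at concentration ``c0`` mol/L."""
        return cls((IonSpecies(1, c0), IonSpecies(-1, c0)), temperature, eps_r)

    @property
    def bjerrum(self) -> float:
        """Bjerrum length l_B in nm."""
        return bjerrum_length(self.temperature, self.eps_r)

    @property
    def ionic_strength(self) -> float:
        """(1/2) sum z_i^2 c_i in mol/L."""
        return 0.5 * sum(s.valence ** 2 * s.concentration for s in self.species)

    @property
    def kappa(self) -> float:
        """Inverse Debye length in nm^-1 from the full ionic-strength definition."""
        # kappa^2 = 4 pi l_B sum_i z_i^2 n_i with n_i in nm^-3
        zsq_n = 2.0 * self.ionic_strength * 1e3 * AVOGADRO * 1e-27
        return math.sqrt(4.0 * math.pi * self.bjerrum * zsq_n)

    @property
    def debye(self) -> float:
        """Debye length kappa^-1 in nm."""
        return 1.0 / self.kappa

    @property
    def is_monovalent_symmetric(self) -> bool:
        zs = sorted(s.valence for s in self.species)
        cs = [s.concentration for s in self.species]
        return zs == [-1, 1] and abs(cs[0] - cs[1]) < 1e-12 * max(cs)

    @property
    def c0(self) -> float:
        """Salt concentration (mol/L) for a symmetric 1:1 electrolyte."""
        if not self.is_monovalent_symmetric:
            raise ValueError("c0 is only defined for a symmetric 1:1 electrolyte")
        return self.species[0].concentration

    def number_density(self, species: IonSpecies) -> float:
        """Bulk number density in nm^-3."""
        return species.concentration * 1e3 * AVOGADRO * 1e-27


def debye_length(electrolyte: Electrolyte) -> float:
    """Screening length kappa^-1 in nm.

    For a pure 1:1 salt this matches the familiar 0.304/sqrt(c0) nm
    approximation to better than 1 percent at room temperature.
    """
    return electrolyte.debye
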