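"""Physical constants and default solvent properties.

Lengths are nanometres, charges elementary charges, energies k_BT and
potentials k_BT/e throughout the package unless a name says otherwise.
"""

ELEMENTARY_CHARGE = 1.602176634e-19   # C
VACUUM_PERMITTIVITY = 8.8541878128e-12  # F/m
BOLTZMANN = 1.380649e-23              # J/K
AVOGADRO = 6.02214076e23              # 1/mol

#: Default absolute temperature (K).
TEMPERATURE = 298.15
#: Default relative permittivity of the aqueous electrolyte.
EPS_WATER = 78.5
#: Default relative permittivity of the ion-free molecular interior.
EPS_MOL = 2.0
#: Dynamic viscosity of water at 298 K (Pa s), for Stokes-Einstein diffusivities.
WATER_VISCOSITY = 8.9e-4


def bjerrum_length(temperature: float = TEMPERATURE, eps_r: float = EPS_WATER) -> float:
    """Bjerrum length l_B = e^2 / (4 pi eps0 eps_r kB T) in nm.

    The separation at which two elementary charges interact with one k_BT;
    about 0.71 nm in water at room temperature.
    """
    e2 = ELEMENTARY_CHARGE ** 2
    denom = 4.0 * 3.141592653589793 * VACUUM_PERMITTIVITY * eps_r * BOLTZMANN * temperature
    return e2 / denom * 1e9
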