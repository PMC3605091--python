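"""Physical constants in eV-denominated units.

Couplings, site energies, driving forces and reorganization energies are
carried in eV throughout the package, so the constants live in eV·s and
eV/K rather than SI.
"""

from __future__ import annotations

from dataclasses import dataclass

#: Reduced Planck constant, eV·s.
HBAR_EV_S = 6.582120e-16

#: Boltzmann constant, eV/K.
K_B_EV_PER_K = 8.617333e-5

#: Default absolute temperature, K.
T_DEFAULT_K = 298.15


@dataclass(frozen=True)
class PhysicalConstants:
    """Constants entering the nonadiabatic rate expression.

    Attributes
    ----------
    hbar : float
        Reduced Planck constant in eV·s.
    k_b : float
        Boltzmann constant in eV/K.
    temperature : float
        Absolute temperature in K.
    """

    hbar: float = HBAR_EV_S
    k_b: float = K_B_EV_PER_K
    temperature: float = T_DEFAULT_K

    def __post_init__(self) -> None:
        if self.hbar <= 0 or self.k_b <= 0 or self.temperature <= 0:
            raise ValueError("physical constants must be positive")

    @property
    def kbt(self) -> float:
        """Thermal energy k_B·T in eV."""
        return self.k_b * self.temperature


DEFAULT_CONSTANTS = PhysicalConstants()
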