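"""Thermodynamic constants and unit conventions.

Internal units throughout the package: length in Å, time in ns, energy in
kcal/mol, temperature in K.  The standard concentration C° = 1 mol/L
corresponds to one molecule per 1661 Å³.
"""

from dataclasses import dataclass

#: Boltzmann constant in kcal/mol/K.
KB_KCAL_MOL_K = 0.0019872041

#: Volume per molecule at the standard concentration of 1 mol/L, in Å³.
STANDARD_VOLUME_A3 = 1661.0


@dataclass(frozen=True)
class ThermoConstants:
    """Bundle of thermodynamic constants used by the free-energy bookkeeping.

    Parameters
    ----------
    temperature:
        Absolute temperature in K.  Defaults to 310 K (physiological).
    """

    temperature: float = 310.0
    kB: float = KB_KCAL_MOL_K
    c_standard: float = 1.0 / STANDARD_VOLUME_A3  # Å^-3

    def __post_init__(self):
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")

    @property
    def kT(self) -> float:
        """Thermal energy kB*T in kcal/mol."""
        return self.kB * self.temperature

    @property
    def beta(self) -> float:
        """Inverse thermal energy 1/(kB*T) in mol/kcal."""
        return 1.0 / self.kT
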