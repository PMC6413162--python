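"""Thermodynamic state: temperature and Boltzmann constant.

All energies in the package are kcal/mol, temperatures in kelvin, so
``kT`` is kcal/mol.  The default state is a 300 K canonical bath, the
condition under which gas-phase connection legs between an MM and an
SQM description are typically evaluated.
"""

from __future__ import annotations

from dataclasses import dataclass

#: Boltzmann constant in kcal/mol/K (CODATA value as used by CHARMM-family codes).
KB_KCAL_MOL_K = 0.0019872041


@dataclass(frozen=True)
class Thermo:
    """Temperature and Boltzmann constant defining the canonical ensemble.

    Parameters
    ----------
    temperature : float
        Bath temperature in kelvin; must be positive.
    boltzmann_constant : float
        kB in kcal/mol/K.
    """

    temperature: float = 300.0
    boltzmann_constant: float = KB_KCAL_MOL_K

    def __post_init__(self) -> None:
        if not self.temperature > 0:
            raise ValueError(f"temperature must be positive, got {self.temperature}")
        if not self.boltzmann_constant > 0:
            raise ValueError("boltzmann_constant must be positive")

    @property
    def kt(self) -> float:
        """Thermal energy kB*T in kcal/mol."""
        return self.boltzmann_constant * self.temperature


#: The package-wide default ensemble (300 K).
DEFAULT_THERMO = Thermo()
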