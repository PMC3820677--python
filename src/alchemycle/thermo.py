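"""Thermodynamic context shared by every stage of the pipeline.

All energies in this package are in kcal/mol, lengths in Å, times in ns and
concentrations in molar unless a name says otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

#: Boltzmann constant in kcal/mol/K.
KB_KCAL_MOL_K = 0.0019872041

#: Avogadro's number, 1/mol.
AVOGADRO = 6.02214076e23

#: 1 mol/L expressed in molecules per Å^3 (1 L = 1e27 Å^3).
MOLAR_PER_A3 = AVOGADRO / 1.0e27


@dataclass(frozen=True)
class ThermoContext:
    """Temperature and standard-state bookkeeping.

    Parameters
    ----------
    temperature : float
        Absolute temperature in kelvin. 298.15 K is the default used for
        converting experimental dissociation constants; simulated toy
        ensembles conventionally use 300 K.
    C0_molar : float
        Standard concentration in mol/L. The standard state for binding
        constants is 1 M.
    """

    temperature: float = 298.15
    C0_molar: float = 1.0

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ValueError(f"temperature must be positive, got {self.temperature}")
        if self.C0_molar <= 0:
            raise ValueError(f"C0_molar must be positive, got {self.C0_molar}")

    @property
    def kT(self) -> float:
        """Thermal energy k_B·T in kcal/mol."""
        return KB_KCAL_MOL_K * self.temperature

    @property
    def C0(self) -> float:
        """Standard concentration in molecules per Å^3."""
        return self.C0_molar * MOLAR_PER_A3


#: Context for converting experimental IC50 values (lab temperature).
EXPERIMENTAL = ThermoContext(temperature=298.15)

#: Context matching the simulated-ensemble temperature of 300 K.
SIMULATION = ThermoContext(temperature=300.0)
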