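"""The CO2/HCO3-/H+ chemical-equilibrium backbone.

Throughout the package the carbonate system is described by the first
apparent dissociation constant of carbonic acid,

    K1' = [H+][HCO3-] / [CO2],

so that at a given pH the bicarbonate-to-CO2 ratio is

    R = [HCO3-]/[CO2] = 10**(pH - pK1').

The default pK1' of 6.07 puts R at ~17 for pH 7.3, the value the
18O-exchange kinetics are calibrated against, and the default uncatalysed
hydration rate constant k_h = 0.131 1/s gives the net CO2-hydration
reaction at clamped pH 7.3 a half-time of 5 s at 37 degC.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

from .errors import InvalidInputError

#: CO2 molar gas volume at STPD, ml gas per mmol (real-gas value for CO2).
CO2_ML_PER_MMOL = 22.26

#: Water concentration, mM. The solvent oxygen pool that absorbs the label.
WATER_MM = 55_500.0

#: Default uncatalysed CO2 hydration rate constant at 37 degC, 1/s.
K_H_UNCAT_37C = 0.131

#: Default apparent pK1' of carbonic acid (ionic strength ~0.15).
PK1_PRIME = 6.07


@dataclass(frozen=True)
class CarbonateSystem:
    """An equilibrated CO2/HCO3- solution.

    Parameters
    ----------
    pH : float
        Solution pH.
    K1prime : float
        First apparent dissociation constant of carbonic acid, in M.
    total_carbonate : float
        [CO2] + [HCO3-], in mM.
    k_h_uncat : float
        Uncatalysed CO2 hydration rate constant, 1/s.
    temperature : str
        Informational tag only; the rate constants carry the physics.
    """

    pH: float = 7.40
    K1prime: float = 10.0 ** (-PK1_PRIME)
    total_carbonate: float = 25.0
    k_h_uncat: float = K_H_UNCAT_37C
    temperature: str = "37C"

    def __post_init__(self):
        if self.total_carbonate <= 0:
            raise InvalidInputError("total_carbonate must be > 0")
        if self.K1prime <= 0 or self.k_h_uncat <= 0:
            raise InvalidInputError("K1prime and k_h_uncat must be > 0")

    @property
    def pK1prime(self) -> float:
        import math

        return -math.log10(self.K1prime)

    @property
    def ratio(self) -> float:
        """[HCO3-]/[CO2] at this pH."""
        return 10.0 ** (self.pH - self.pK1prime)

    @property
    def co2(self) -> float:
        """Equilibrium [CO2], mM."""
        return self.total_carbonate / (1.0 + self.ratio)

    @property
    def hco3(self) -> float:
        """Equilibrium [HCO3-], mM."""
        return self.total_carbonate - self.co2

    def at_pH(self, pH: float) -> "CarbonateSystem":
        """Same chemistry re-equilibrated at a different pH, keeping [CO2].

        Used for the intracellular compartment: CO2 equilibrates across the
        membrane, so intracellular [CO2] equals the extracellular value
        while [HCO3-] follows the intracellular pH.
        """
        ratio = 10.0 ** (pH - self.pK1prime)
        total = self.co2 * (1.0 + ratio)
        return replace(self, pH=pH, total_carbonate=total)


def carbonate_equilibrium(system: CarbonateSystem) -> tuple[float, float]:
    """Equilibrium ([CO2], [HCO3-]) in mM for *system*.

    The ratio is 10**(pH - pK1') and the two species sum to the total
    carbonate concentration.
    """
    return system.co2, system.hco3


def buffer_protonated_fraction(h: float, Ka: float) -> float:
    """Fraction of a monoprotic buffer in the protonated form at [H+] = h."""
    return h / (h + Ka)
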