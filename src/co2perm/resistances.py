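"""Closed-form diffusion-resistance calculations.

Units are fixed at cm, s, mmHg and mM throughout. Solubilities are in gas
volume per tissue/solution volume per mmHg (cm3/cm3/mmHg); release rates
convert to the physiologist's ml gas per cm3 tissue per minute, with
tissue density taken as 1 g/cm3 so that per-gram and per-cm3 rates
coincide.

The calculations implemented here:

* the solubility-diffusion permeability P = D_M * K_P / d;
* partition-coefficient scaling of a reference permeability (assumes
  equal intramembrane diffusivity between gases);
* series resistance chains of water layers (d/D terms) and membranes
  (1/P terms), as apply to unstirred layers in front of a membrane;
* the steady-state CO2 release rate from a cell modelled as a plane
  sheet with a cytoplasmic diffusion path in series with the membrane;
* the "effective solubility" of a buffered closed volume (CO2 plus the
  HCO3- formed when the released protons are absorbed by a buffer);
* the sphere uptake-time estimate D' * t / r^2 = criterion, with the
  free-solution diffusivity retarded by the ratio of effective to
  physical solubility.

Infinite membrane permeability is represented by ``INFINITE_PERMEABILITY``
(= ``math.inf``), whose resistance contribution 1/P is exactly zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

from scipy.optimize import brentq

from .carbonate import CO2_ML_PER_MMOL, buffer_protonated_fraction
from .errors import ConvergenceError, InvalidInputError

#: Sentinel for a membrane that offers no diffusion resistance.
INFINITE_PERMEABILITY = math.inf


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PartitionEntry:
    """Solubility behaviour of one gas in water and lipid.

    Solubilities in umol/l/mmHg; the partition coefficient is the
    lipid-to-water solubility ratio.
    """

    gas_name: str
    solubility_water: float | None = None
    solubility_lipid: float | None = None
    partition_coefficient: float | None = None

    def __post_init__(self):
        for v in (self.solubility_water, self.solubility_lipid):
            if v is not None and v <= 0:
                raise InvalidInputError(f"{self.gas_name}: solubilities must be > 0")
        if (
            self.solubility_water is not None
            and self.solubility_lipid is not None
            and self.partition_coefficient is not None
        ):
            implied = self.solubility_lipid / self.solubility_water
            # consistency to 2 significant figures
            if abs(implied - self.partition_coefficient) > 0.05 * abs(implied) + 1e-12:
                raise InvalidInputError(
                    f"{self.gas_name}: partition coefficient {self.partition_coefficient} "
                    f"inconsistent with solubility ratio {implied:.3g}"
                )


@dataclass(frozen=True)
class LayerStack:
    """A series chain of stagnant water layers and membranes.

    water_layers : sequence of (thickness_cm, diffusion_coefficient_cm2_s)
    membranes    : sequence of permeabilities (cm/s); ``INFINITE_PERMEABILITY``
                   contributes zero resistance.
    """

    water_layers: Sequence[tuple[float, float]] = field(default_factory=tuple)
    membranes: Sequence[float] = field(default_factory=tuple)

    def __post_init__(self):
        for d, D in self.water_layers:
            if d <= 0 or D <= 0:
                raise InvalidInputError("water layer thickness and D must be > 0")
        for P in self.membranes:
            if P <= 0:
                raise InvalidInputError("membrane permeability must be > 0")

    def __add__(self, other: "LayerStack") -> "LayerStack":
        return LayerStack(
            tuple(self.water_layers) + tuple(other.water_layers),
            tuple(self.membranes) + tuple(other.membranes),
        )


@dataclass(frozen=True)
class CellReleaseModel:
    """Plane-sheet cell releasing CO2 through cytoplasm and membrane in series.

    diffusion_path_d : cytoplasmic diffusion path (half-thickness), cm
    cytoplasmic_D    : cytoplasmic CO2 diffusion coefficient, cm2/s
    tissue_solubility_alpha : CO2 solubility of tissue, cm3 gas/cm3/mmHg
    membrane_P       : membrane CO2 permeability, cm/s (may be infinite)
    delta_p          : CO2 partial-pressure difference source -> sink, mmHg
    """

    diffusion_path_d: float
    cytoplasmic_D: float
    tissue_solubility_alpha: float
    membrane_P: float = INFINITE_PERMEABILITY
    delta_p: float | None = None

    def __post_init__(self):
        if min(self.diffusion_path_d, self.cytoplasmic_D, self.tissue_solubility_alpha) <= 0:
            raise InvalidInputError("geometry, diffusivity and solubility must be > 0")
        if self.membrane_P <= 0:
            raise InvalidInputError("membrane permeability must be > 0")


@dataclass(frozen=True)
class SphereUptakeSpec:
    """Inputs for the sphere uptake-time estimate.

    The uptake of a reacting, buffered species by a sphere is treated as
    simple diffusion with a retarded diffusivity D' = D * alpha /
    alpha_effective; the stated criterion D' * t / r^2 (default 0.6,
    corresponding to ~95% completion) then yields the uptake time.
    """

    radius_r: float
    D_free: float
    alpha: float
    alpha_effective: float
    completion_criterion: float = 0.6

    def __post_init__(self):
        if self.radius_r <= 0 or self.D_free <= 0:
            raise InvalidInputError("radius and D must be > 0")
        if not (self.alpha_effective >= self.alpha > 0):
            raise InvalidInputError("need alpha_effective >= alpha > 0")


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def solubility_diffusion_permeability(D_M: float, K_P: float, d: float) -> float:
    """Membrane permeability P = D_M * K_P / d (cm/s).

    D_M is the intramembrane diffusion coefficient (cm2/s), K_P the
    lipid-water partition coefficient and d the membrane thickness (cm).
    """
    if d <= 0:
        raise InvalidInputError("membrane thickness must be > 0")
    if D_M < 0 or K_P < 0:
        raise InvalidInputError("D_M and K_P must be >= 0")
    return D_M * K_P / d


def partition_scaled_permeability(P_ref: float, K_ref: float, K_target: float) -> float:
    """Predict a gas permeability from a reference gas by partition scaling.

    Assumes identical intramembrane diffusion coefficients, so permeability
    scales with the partition coefficient: P = P_ref * K_target / K_ref.
    """
    if K_ref <= 0:
        raise InvalidInputError("reference partition coefficient must be > 0")
    return P_ref * K_target / K_ref


def series_total_resistance(stack: LayerStack) -> tuple[float, float]:
    """Total diffusion resistance (s/cm) and apparent permeability (cm/s).

    Resistances add in series: each water layer contributes d/D and each
    membrane 1/P. An empty stack has zero resistance and infinite apparent
    permeability.
    """
    resistance = sum(d / D for d, D in stack.water_layers)
    resistance += sum(1.0 / P for P in stack.membranes)
    apparent = math.inf if resistance == 0 else 1.0 / resistance
    return resistance, apparent


def cardiomyocyte_release_rate(model: CellReleaseModel) -> float:
    """Steady-state CO2 release rate, ml gas / cm3 tissue / min.

    rate = (d/D + 1/P)^-1 * alpha * delta_p / d, i.e. the series
    conductance of cytoplasm and membrane driving gas down the partial-
    pressure gradient, referred to the cell volume d*A. Increases
    monotonically with P and saturates at D*alpha*delta_p/d^2 as P -> inf.
    """
    if model.delta_p is None:
        raise InvalidInputError("delta_p is required to compute a release rate")
    if model.delta_p < 0:
        raise InvalidInputError("delta_p must be >= 0")
    d, D, P = model.diffusion_path_d, model.cytoplasmic_D, model.membrane_P
    resistance = d / D + (0.0 if math.isinf(P) else 1.0 / P)
    rate_per_s = (1.0 / resistance) * model.tissue_solubility_alpha * model.delta_p / d
    return rate_per_s * 60.0


def required_gradient_for_flux(target_rate: float, model: CellReleaseModel) -> float:
    """CO2 partial-pressure difference (mmHg) needed for *target_rate*.

    Exact inverse of :func:`cardiomyocyte_release_rate` (the model is
    linear in delta_p). *target_rate* is in ml gas / cm3 tissue / min.
    """
    if target_rate < 0:
        raise InvalidInputError("target rate must be >= 0")
    if target_rate == 0:
        return 0.0
    d, D, P = model.diffusion_path_d, model.cytoplasmic_D, model.membrane_P
    resistance = d / D + (0.0 if math.isinf(P) else 1.0 / P)
    return (target_rate / 60.0) * d * resistance / model.tissue_solubility_alpha


def effective_solubility(
    alpha: float,
    buffer_total: float,
    buffer_pKa: float = 7.5,
    pH_start: float = 7.4,
    p1: float = 1.0,
    p2: float = 40.0,
    K1prime: float = 10.0 ** (-6.07),
) -> float:
    """Effective CO2 solubility alpha' of a buffered closed volume.

    alpha' is the amount of CO2 plus HCO3- taken up per unit increase in
    CO2 partial pressure: raising pCO2 from p1 to p2 in a closed,
    buffered volume forms HCO3-, whose protons are absorbed by the buffer,
    so the volume stores far more CO2 than physical solubility alone
    predicts.

    Parameters: *alpha* in cm3/cm3/mmHg, *buffer_total* in mM (monoprotic
    buffer with dissociation constant 10**-buffer_pKa), pressures in mmHg,
    *K1prime* in M. Returns alpha' in cm3/cm3/mmHg.
    """
    if not (p2 > p1 > 0):
        raise InvalidInputError("need p2 > p1 > 0")
    if buffer_total < 0:
        raise InvalidInputError("buffer_total must be >= 0")
    alpha_M = alpha / (CO2_ML_PER_MMOL * 1e-3) * 1e-3  # mol/l per mmHg
    Ka = 10.0 ** (-buffer_pKa)
    h1 = 10.0 ** (-pH_start)
    c1, c2 = alpha_M * p1, alpha_M * p2
    b1 = K1prime * c1 / h1

    def proton_balance(pH2: float) -> float:
        h2 = 10.0 ** (-pH2)
        hco3_formed = K1prime * c2 / h2 - b1
        absorbed = buffer_total * 1e-3 * (
            buffer_protonated_fraction(h2, Ka) - buffer_protonated_fraction(h1, Ka)
        ) + (h2 - h1)
        return hco3_formed - absorbed

    try:
        pH2 = brentq(proton_balance, 2.0, 12.0, xtol=1e-12)
    except ValueError as exc:  # pragma: no cover - no root bracketed
        raise ConvergenceError(f"no equilibrium root in pH [2, 12]: {exc}")
    h2 = 10.0 ** (-pH2)
    delta_hco3 = K1prime * c2 / h2 - b1  # mol/l
    return alpha + delta_hco3 * CO2_ML_PER_MMOL / (p2 - p1)


def crank_uptake_time(spec: SphereUptakeSpec) -> float:
    """Uptake time (s) for a sphere from D' * t / r^2 = criterion.

    D' = D_free * alpha / alpha_effective is the diffusivity retarded by
    reversible storage as HCO3-.
    """
    D_prime = spec.D_free * spec.alpha / spec.alpha_effective
    return spec.completion_criterion * spec.radius_r**2 / D_prime
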