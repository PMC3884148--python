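"""Unstirred-layer estimation.

A stagnant water film of thickness delta in front of a membrane adds a
diffusive resistance delta/D in series with the membrane, so the
measured (apparent) permeability obeys

    1/P_app = 1/P_true + delta/D.

Hydrodynamics makes delta proportional to the kinematic viscosity nu of
the suspending medium at fixed stirring, so plotting 1/P_app against nu
over a dextran series is linear and its extrapolation to nu = 0 gives
the true membrane permeability; the slope is the proportionality
constant C in delta/D = C * nu. A second hydrodynamic relation,
delta ~ sqrt(d), rescales delta across cell or vesicle sizes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .errors import InvalidInputError

__all__ = [
    "ViscositySeries",
    "ViscosityExtrapolation",
    "USLResult",
    "apparent_from_true",
    "delta_from_permeabilities",
    "delta_sqrt_scaling",
]

CST_TO_M2_S = 1e-6


@dataclass(frozen=True)
class ViscositySeries:
    """Apparent permeabilities measured across a viscosity series.

    viscosities : kinematic viscosities; unit "m2/s" (default) or "cSt"
    P_apparent  : apparent permeabilities, cm/s
    D           : diffusion coefficient of the solute in water, cm2/s
    """

    viscosities: Sequence[float]
    P_apparent: Sequence[float]
    D: float = 2.0e-5
    viscosity_unit: str = "m2/s"

    def __post_init__(self):
        if len(self.viscosities) != len(self.P_apparent):
            raise InvalidInputError("viscosities and P_apparent must have equal length")
        if len(set(self.viscosities)) < 2:
            raise InvalidInputError("need at least 2 distinct viscosities")
        if any(p <= 0 for p in self.P_apparent):
            raise InvalidInputError("P_apparent must be > 0")
        if self.viscosity_unit not in ("m2/s", "cSt"):
            raise InvalidInputError("viscosity_unit must be 'm2/s' or 'cSt'")

    @property
    def nu_m2_s(self) -> np.ndarray:
        nu = np.asarray(self.viscosities, dtype=float)
        return nu * CST_TO_M2_S if self.viscosity_unit == "cSt" else nu


@dataclass
class USLResult:
    """Result of the viscosity extrapolation."""

    P_true: float
    slope_C: float
    deltas: np.ndarray  # unstirred-layer thickness per series point, cm
    P_true_stderr: float | None = None
    slope_stderr: float | None = None
    r_squared: float | None = None

    def summary(self) -> str:
        lines = [
            "Viscosity-series unstirred-layer fit",
            "=" * 40,
            f"P_true (cm/s)     : {self.P_true:.4g}"
            + (f" +/- {self.P_true_stderr:.2g}" if self.P_true_stderr else ""),
            f"slope C (s/cm per m2/s) : {self.slope_C:.4g}",
            f"delta range (um)  : {1e4 * self.deltas.min():.3g} - {1e4 * self.deltas.max():.3g}",
        ]
        if self.r_squared is not None:
            lines.append(f"R^2               : {self.r_squared:.4f}")
        return "\n".join(lines)


class ViscosityExtrapolation:
    """OLS of 1/P_apparent on kinematic viscosity; intercept -> P_true."""

    def __init__(self, series: ViscositySeries):
        self.series = series

    def fit(self) -> USLResult:
        nu = self.series.nu_m2_s
        inv_p = 1.0 / np.asarray(self.series.P_apparent, dtype=float)
        res = stats.linregress(nu, inv_p)
        if res.intercept <= 0:
            raise InvalidInputError(
                "negative or zero intercept: the series implies an unphysical "
                "(non-positive) membrane resistance"
            )
        P_true = 1.0 / res.intercept
        deltas = self.series.D * np.clip(inv_p - res.intercept, 0.0, None)
        stderr_int = getattr(res, "intercept_stderr", None)
        P_stderr = P_true**2 * stderr_int if stderr_int is not None else None
        return USLResult(
            P_true=P_true,
            slope_C=res.slope,
            deltas=deltas,
            P_true_stderr=P_stderr,
            slope_stderr=res.stderr,
            r_squared=res.rvalue**2 if not math.isnan(res.rvalue) else None,
        )


def delta_from_permeabilities(P_app: float, P_true: float, D: float) -> float:
    """Unstirred-layer thickness delta = D * (1/P_app - 1/P_true), cm."""
    if not (0 < P_app <= P_true):
        raise InvalidInputError("need 0 < P_app <= P_true")
    if D <= 0:
        raise InvalidInputError("D must be > 0")
    return D * (1.0 / P_app - 1.0 / P_true)


def apparent_from_true(P_true: float, delta: float, D: float) -> float:
    """Apparent permeability behind an unstirred layer of thickness delta."""
    if P_true <= 0 or D <= 0 or delta < 0:
        raise InvalidInputError("need P_true > 0, D > 0, delta >= 0")
    return 1.0 / (1.0 / P_true + delta / D)


def delta_sqrt_scaling(delta_ref: float, d_ref: float, d_new: float) -> float:
    """Rescale delta across characteristic cell sizes via delta ~ sqrt(d)."""
    if min(delta_ref, d_ref, d_new) <= 0:
        raise InvalidInputError("all inputs must be > 0")
    return delta_ref * math.sqrt(d_new / d_ref)
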