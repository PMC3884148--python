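"""1-D reaction-diffusion model of transepithelial CO2 flux.

The geometry is a stack of three water compartments — back unstirred
layer | cell layer | front unstirred layer — separated by two membranes
that are permeable to CO2 only (default P_CO2 = 0.01 cm/s) and bounded on
both outer edges by fixed (Dirichlet) bulk conditions. Raising the
back-side bulk [HCO3-] from 25 to 50 mM at fixed pH 7.4 raises back-side
pCO2, drives a CO2 flux across the cell layer, and acidifies the front
unstirred layer; a pH microelectrode traversing that layer reads the
resulting profile, whose initial slope is the experimental observable.

Species and transport. In every volume element the model carries CO2,
HCO3- and a proton load x = [H+] + [buffer-bound H+]; the monoprotic
buffer (HEPES) equilibrates instantaneously, so the free [H+] follows
from x by a closed-form quadratic, and protons move both as free H+
(diffusivity D_H) and piggy-backed on the buffer (diffusivity D_B) —
buffer-facilitated proton diffusion. The CO2 hydration/dehydration
reaction runs in every element with the rate constants multiplied by
(A + 1), where A is the local carbonic-anhydrase activity: A_i inside
the cell layer, A_e throughout the extracellular unstirred layers, and
an optional surface-bound A_s confined to the single element adjacent to
the membrane. Because both directions are accelerated equally,
equilibria are unchanged by CA.

The steady state is obtained by stiff time integration until the fields
stop changing; at steady state the total carbon flux (CO2 + HCO3-) is
the same through every grid interface, which the result object verifies.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.integrate import solve_ivp

from .carbonate import K_H_UNCAT_37C, PK1_PRIME
from .errors import ConvergenceError, InvalidInputError

__all__ = [
    "MonolayerGeometry",
    "CAProfile",
    "MonolayerChemistry",
    "MonolayerBoundary",
    "MonolayerModel",
    "MonolayerResult",
    "buffer_factor",
    "flux_from_ph_slope",
    "monolayer_preset",
    "equilibrate_closed",
]

MM_TO_MMOL_PER_CM3 = 1e-3  # 1 mM = 1e-3 mmol/cm3 ... times cm/s gives mmol/cm2/s? no:
# 1 mM = 1e-6 mol/cm3 = 1e-3 mmol/cm3; a flux in mM*cm/s is 1e-3 mmol/cm2/s.


@dataclass(frozen=True)
class MonolayerGeometry:
    """Thicknesses (cm) and grid resolution of the three compartments."""

    back_usl_thickness: float = 130e-4
    cell_thickness: float = 10e-4
    front_usl_thickness: float = 130e-4
    elements_per_compartment: int = 50

    def __post_init__(self):
        if min(self.back_usl_thickness, self.cell_thickness, self.front_usl_thickness) <= 0:
            raise InvalidInputError("all thicknesses must be > 0")
        if self.elements_per_compartment < 2:
            raise InvalidInputError("need at least 2 elements per compartment")


@dataclass(frozen=True)
class CAProfile:
    """Carbonic-anhydrase activities by location.

    A_i  : intracellular activity (cell-layer elements)
    A_e  : bulk extracellular activity (all unstirred-layer elements)
    A_s  : surface-bound activity, applied only in the one unstirred-layer
           element immediately adjacent to the membrane
    A_s_side : which membrane face carries A_s ("front", "back" or "both")
    """

    A_i: float = 0.0
    A_e: float = 0.0
    A_s: float = 0.0
    A_s_side: Literal["front", "back", "both"] = "front"

    def __post_init__(self):
        if min(self.A_i, self.A_e, self.A_s) < 0:
            raise InvalidInputError("CA activities must be >= 0")


@dataclass(frozen=True)
class MonolayerChemistry:
    """Rate constants, diffusivities and buffer of the reacting solution.

    k_h_uncat : uncatalysed CO2 hydration rate constant, 1/s
    K1prime   : apparent first dissociation constant of carbonic acid, M
    D_CO2, D_HCO3, D_H, D_B : diffusion coefficients, cm2/s
    buffer_total : total HEPES, mM; buffer_pKa its pKa
    BF_fixed  : buffer factor (mM per pH unit) used by the slope-based
                flux estimator; None derives it from the buffer curve at
                the bulk pH.
    """

    k_h_uncat: float = K_H_UNCAT_37C
    K1prime: float = 10.0 ** (-PK1_PRIME)
    D_CO2: float = 1.8e-5
    D_HCO3: float = 1.1e-5
    D_H: float = 9.0e-5
    D_B: float = 5.0e-6
    buffer_total: float = 25.0
    buffer_pKa: float = 7.5

    def __post_init__(self):
        if min(self.k_h_uncat, self.K1prime, self.D_CO2, self.D_HCO3,
               self.D_H, self.D_B) <= 0:
            raise InvalidInputError("rate constants and diffusivities must be > 0")
        if self.buffer_total < 0:
            raise InvalidInputError("buffer_total must be >= 0")

    @property
    def Ka(self) -> float:
        return 10.0 ** (-self.buffer_pKa)


@dataclass(frozen=True)
class MonolayerBoundary:
    """Dirichlet bulk conditions and membrane permeability.

    Membranes are impermeable to HCO3-, H+ and buffer; only CO2 crosses,
    with permeability P_CO2 (cm/s).
    """

    bulk_pH_back: float = 7.4
    bulk_pH_front: float = 7.4
    bulk_HCO3_back: float = 50.0
    bulk_HCO3_front: float = 25.0
    P_CO2: float = 0.01

    def __post_init__(self):
        if self.P_CO2 <= 0:
            raise InvalidInputError("membrane P_CO2 must be > 0")
        if min(self.bulk_HCO3_back, self.bulk_HCO3_front) <= 0:
            raise InvalidInputError("bulk [HCO3-] must be > 0")


def buffer_factor(buffer_total: float, buffer_pKa: float, pH: float) -> float:
    """Buffering power (mM of protons absorbed per pH unit) at *pH*."""
    Ka = 10.0 ** (-buffer_pKa)
    h = 10.0 ** (-pH)
    return math.log(10.0) * buffer_total * Ka * h / (Ka + h) ** 2


def flux_from_ph_slope(D_B: float, BF: float, slope: float) -> float:
    """Slope-based transepithelial CO2 flux estimate, mmol/cm2/s.

    flux ~= buffer-facilitated proton flux in the unstirred layer
    = D_B * BF * dpH/dx, with D_B in cm2/s, BF in mM/pH and the slope in
    pH/cm. The estimate is only close to the true flux when the
    extracellular CA activity is high enough to keep the layer near
    chemical equilibrium; otherwise it underestimates badly.
    """
    return D_B * BF * slope * MM_TO_MMOL_PER_CM3


def _h_from_x(x_mM: np.ndarray, B_mM: float, Ka: float) -> np.ndarray:
    """Free [H+] (M) from the proton load x = 1e3*[H+] + B*f_prot (mM)."""
    x = np.asarray(x_mM, dtype=float) * 1e-3
    B = B_mM * 1e-3
    q = Ka + B - x
    return (-q + np.sqrt(q * q + 4.0 * x * Ka)) / 2.0


def _x_from_pH(pH: float, B_mM: float, Ka: float) -> float:
    h = 10.0 ** (-pH)
    return 1e3 * h + B_mM * h / (h + Ka)


class MonolayerModel:
    """Finite-difference reaction-diffusion model of the monolayer setup."""

    def __init__(
        self,
        geometry: MonolayerGeometry = MonolayerGeometry(),
        chemistry: MonolayerChemistry = MonolayerChemistry(),
        ca_profile: CAProfile = CAProfile(),
        boundary: MonolayerBoundary = MonolayerBoundary(),
    ):
        self.geometry = geometry
        self.chemistry = chemistry
        self.ca = ca_profile
        self.boundary = boundary

        n = geometry.elements_per_compartment
        self.n = n
        self.N = 3 * n
        self.dx = np.concatenate([
            np.full(n, geometry.back_usl_thickness / n),
            np.full(n, geometry.cell_thickness / n),
            np.full(n, geometry.front_usl_thickness / n),
        ])
        # element-centre x, measured from the back outer edge
        edges = np.concatenate([[0.0], np.cumsum(self.dx)])
        self.centres = 0.5 * (edges[:-1] + edges[1:])
        # centre-to-centre gaps for the N-1 internal interfaces
        self.gaps = 0.5 * (self.dx[:-1] + self.dx[1:])

        A = np.empty(self.N)
        A[:n] = ca_profile.A_e
        A[n: 2 * n] = ca_profile.A_i
        A[2 * n:] = ca_profile.A_e
        if ca_profile.A_s_side in ("front", "both"):
            A[2 * n] += ca_profile.A_s
        if ca_profile.A_s_side in ("back", "both"):
            A[n - 1] += ca_profile.A_s
        self.A = A

        ch, bd = chemistry, boundary
        self._bulk = {}
        for side, pH, hco3 in (
            ("back", bd.bulk_pH_back, bd.bulk_HCO3_back),
            ("front", bd.bulk_pH_front, bd.bulk_HCO3_front),
        ):
            h = 10.0 ** (-pH)
            self._bulk[side] = {
                "c": h * hco3 / ch.K1prime,
                "b": hco3,
                "x": _x_from_pH(pH, ch.buffer_total, ch.Ka),
                "h": h,
            }
        # membrane interfaces sit between elements (n-1, n) and (2n-1, 2n)
        self._membrane_after = (n - 1, 2 * n - 1)

    # -- right-hand side ---------------------------------------------
    def rhs(self, t: float, y: np.ndarray) -> np.ndarray:
        n, N = self.n, self.N
        ch = self.chemistry
        c, b, x = y[:N], y[N: 2 * N], y[2 * N:]
        h = _h_from_x(x, ch.buffer_total, ch.Ka)
        HA = ch.buffer_total * h / (h + ch.Ka)
        hf = 1e3 * h  # free protons in mM

        bulk_b, bulk_f = self._bulk["back"], self._bulk["front"]
        P = self.boundary.P_CO2

        # interface fluxes, positive toward the front; length N+1
        def species_flux(field, D, bulk_back, bulk_front, crosses_membrane):
            F = np.empty(N + 1)
            F[1:N] = D * (field[:-1] - field[1:]) / self.gaps
            F[0] = D * (bulk_back - field[0]) / (self.dx[0] / 2.0)
            F[N] = D * (field[-1] - bulk_front) / (self.dx[-1] / 2.0)
            for i in self._membrane_after:
                F[i + 1] = P * (field[i] - field[i + 1]) if crosses_membrane else 0.0
            return F

        Fc = species_flux(c, ch.D_CO2, bulk_b["c"], bulk_f["c"], True)
        Fb = species_flux(b, ch.D_HCO3, bulk_b["b"], bulk_f["b"], False)
        # proton load moves as free H+ plus buffer-bound H+
        Fx = species_flux(hf, ch.D_H, 1e3 * bulk_b["h"], 1e3 * bulk_f["h"], False)
        Fx += species_flux(
            HA, ch.D_B,
            ch.buffer_total * bulk_b["h"] / (bulk_b["h"] + ch.Ka),
            ch.buffer_total * bulk_f["h"] / (bulk_f["h"] + ch.Ka),
            False,
        )

        r = (self.A + 1.0) * ch.k_h_uncat * (c - h * b / ch.K1prime)
        dc = (Fc[:-1] - Fc[1:]) / self.dx - r
        db = (Fb[:-1] - Fb[1:]) / self.dx + r
        dx_ = (Fx[:-1] - Fx[1:]) / self.dx + r
        return np.concatenate([dc, db, dx_])

    def _jac_sparsity(self) -> sparse.csr_matrix:
        N = self.N
        tri = sparse.diags([1.0, 1.0, 1.0], [-1, 0, 1], shape=(N, N))
        eye = sparse.eye(N)
        # species couple locally through the reaction and h(x); transport is
        # nearest-neighbour, so every block is at most tridiagonal
        blocks = [[tri, eye, eye], [eye, tri, eye], [eye, eye, tri]]
        return sparse.bmat(blocks, format="csr")

    def initial_state(self) -> np.ndarray:
        bf = self._bulk["front"]
        c = np.full(self.N, bf["c"])
        b = np.full(self.N, bf["b"])
        x = np.full(self.N, bf["x"])
        return np.concatenate([c, b, x])

    # -- steady state -------------------------------------------------
    def steady_state(
        self,
        t_initial: float = 2000.0,
        max_time: float = 16000.0,
        rtol_change: float = 1e-7,
    ) -> "MonolayerResult":
        """Integrate to steady state with a stiff (BDF) solver.

        One long integration settles the fields (the slowest scale is
        uncatalysed HCO3- turnover, ~160 s); a confirmation chunk then
        verifies that the maximum relative field change has fallen below
        *rtol_change*, doubling the horizon until it has.
        Non-convergence within *max_time* raises
        :class:`ConvergenceError` with the residual.
        """
        sparsity = self._jac_sparsity()

        def integrate(y0, span):
            sol = solve_ivp(self.rhs, (0.0, span), y0, method="BDF",
                            rtol=1e-7, atol=1e-10, jac_sparsity=sparsity)
            if not sol.success:  # pragma: no cover
                raise ConvergenceError(f"BDF failure: {sol.message}")
            return sol.y[:, -1]

        t_confirm = 200.0
        y = integrate(self.initial_state(), t_initial)
        t_done, span = t_initial, t_initial
        while t_done < max_time:
            y_new = integrate(y, t_confirm)
            change = float(np.max(np.abs(y_new - y) / (np.abs(y_new) + 1e-6)))
            y = y_new
            t_done += t_confirm
            if change < rtol_change:
                return MonolayerResult(self, y, t_done, change)
            y = integrate(y, span)  # not settled: double the horizon
            t_done += span
            span *= 2.0
        raise ConvergenceError(
            f"no steady state within {max_time} s (residual {change:.2e})",
            residual=change,
        )


class MonolayerResult:
    """Steady-state fields and flux diagnostics of a monolayer model."""

    def __init__(self, model: MonolayerModel, y: np.ndarray, t_elapsed: float,
                 residual: float):
        self.model = model
        self.y = y
        self.t_elapsed = t_elapsed
        self.residual = residual
        N = model.N
        self.co2 = y[:N]
        self.hco3 = y[N: 2 * N]
        self.x = y[2 * N:]
        self.h = _h_from_x(self.x, model.chemistry.buffer_total, model.chemistry.Ka)
        self.pH = -np.log10(self.h)

    # -- fields --------------------------------------------------------
    def ph_profile(self) -> pd.DataFrame:
        """pH vs distance (cm) from the back outer edge, per element."""
        return pd.DataFrame({"distance_cm": self.model.centres, "pH": self.pH})

    def front_usl_profile(self) -> pd.DataFrame:
        """pH vs distance (cm) from the *front membrane*, front USL only."""
        m = self.model
        sel = slice(2 * m.n, 3 * m.n)
        membrane_x = float(np.sum(m.dx[: 2 * m.n]))
        return pd.DataFrame({
            "distance_cm": m.centres[sel] - membrane_x,
            "pH": self.pH[sel],
        })

    # -- fluxes --------------------------------------------------------
    def carbon_flux_profile(self) -> np.ndarray:
        """Total carbon flux (mmol/cm2/s) through each of the N+1 interfaces."""
        m, ch = self.model, self.model.chemistry
        c, b = self.co2, self.hco3
        N = m.N
        P = m.boundary.P_CO2
        bulk_b, bulk_f = m._bulk["back"], m._bulk["front"]
        Fc = np.empty(N + 1)
        Fb = np.empty(N + 1)
        Fc[1:N] = ch.D_CO2 * (c[:-1] - c[1:]) / m.gaps
        Fb[1:N] = ch.D_HCO3 * (b[:-1] - b[1:]) / m.gaps
        Fc[0] = ch.D_CO2 * (bulk_b["c"] - c[0]) / (m.dx[0] / 2)
        Fb[0] = ch.D_HCO3 * (bulk_b["b"] - b[0]) / (m.dx[0] / 2)
        Fc[N] = ch.D_CO2 * (c[-1] - bulk_f["c"]) / (m.dx[-1] / 2)
        Fb[N] = ch.D_HCO3 * (b[-1] - bulk_f["b"]) / (m.dx[-1] / 2)
        for i in m._membrane_after:
            Fc[i + 1] = P * (c[i] - c[i + 1])
            Fb[i + 1] = 0.0
        return (Fc + Fb) * MM_TO_MMOL_PER_CM3

    def true_transmembrane_flux(self) -> float:
        """CO2 flux through the front membrane, P * ([CO2]in - [CO2]out),
        in mmol/cm2/s (equal on both membranes at steady state)."""
        m = self.model
        i = m._membrane_after[1]
        return m.boundary.P_CO2 * (self.co2[i] - self.co2[i + 1]) * MM_TO_MMOL_PER_CM3

    def flux_divergence(self) -> float:
        """Max relative deviation of the carbon flux across interfaces."""
        F = self.carbon_flux_profile()
        mean = float(np.mean(F))
        if mean == 0.0:
            return float(np.max(np.abs(F)))
        return float(np.max(np.abs(F - mean) / abs(mean)))

    # -- observables ---------------------------------------------------
    def initial_surface_slope(self, window: float = 0.2) -> float:
        """Initial pH slope (pH/cm) in the front unstirred layer.

        Least-squares slope of pH vs distance from the membrane over the
        first *window* fraction of the front USL, excluding the
        membrane-adjacent element (which may carry surface-bound CA).
        Positive slope = acidified at the membrane, recovering toward
        the bulk.
        """
        prof = self.front_usl_profile()
        lim = window * self.model.geometry.front_usl_thickness
        sel = (prof["distance_cm"] <= lim).to_numpy()
        sel[0] = False  # surface-CA element excluded
        if sel.sum() < 3:
            raise InvalidInputError("slope window smaller than 3 elements")
        coef = np.polyfit(prof["distance_cm"][sel], prof["pH"][sel], 1)
        return float(coef[0])

    def estimated_flux_from_slope(self, BF: float | None = None) -> float:
        """The slope-based flux estimate applied to this model's own profile."""
        ch = self.model.chemistry
        if BF is None:
            BF = buffer_factor(ch.buffer_total, ch.buffer_pKa,
                               self.model.boundary.bulk_pH_front)
        return flux_from_ph_slope(ch.D_B, BF, self.initial_surface_slope())

    def summary(self) -> str:
        ca = self.model.ca
        lines = [
            "Monolayer reaction-diffusion steady state",
            "=" * 45,
            f"CA activities (A_i, A_e, A_s)   : {ca.A_i:g}, {ca.A_e:g}, {ca.A_s:g}",
            f"membrane P_CO2 (cm/s)           : {self.model.boundary.P_CO2:g}",
            f"initial front-USL pH slope      : {self.initial_surface_slope():.3g} pH/cm",
            f"true transmembrane CO2 flux     : {self.true_transmembrane_flux():.3g} mmol/cm2/s",
            f"slope-estimated flux            : {self.estimated_flux_from_slope():.3g} mmol/cm2/s",
            f"carbon-flux divergence          : {self.flux_divergence():.2e}",
            f"settling time integrated        : {self.t_elapsed:g} s",
        ]
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# presets and small helpers
# ---------------------------------------------------------------------------

_PRESETS = {
    # acetazolamide in everything: no CA anywhere
    "curve1": CAProfile(A_i=0.0, A_e=0.0, A_s=0.0),
    # endogenous intracellular CA plus a little membrane-bound surface CA
    "curve2": CAProfile(A_i=800.0, A_e=0.0, A_s=100.0, A_s_side="front"),
    # intracellular CA plus a large excess of dissolved extracellular CA
    "curve3": CAProfile(A_i=800.0, A_e=10000.0, A_s=0.0),
}


def monolayer_preset(
    name: str,
    geometry: MonolayerGeometry = MonolayerGeometry(),
    chemistry: MonolayerChemistry = MonolayerChemistry(),
    boundary: MonolayerBoundary = MonolayerBoundary(),
) -> MonolayerModel:
    """The three canonical CA configurations of the monolayer experiment."""
    if name not in _PRESETS:
        raise InvalidInputError(f"unknown preset {name!r}; choose from {sorted(_PRESETS)}")
    return MonolayerModel(geometry, chemistry, _PRESETS[name], boundary)


def equilibrate_closed(
    c0: float, b0: float, pH0: float,
    chemistry: MonolayerChemistry = MonolayerChemistry(),
    A: float = 0.0,
    t_end: float = 5000.0,
) -> tuple[float, float, float]:
    """Equilibrate a closed, well-mixed box; returns (CO2, HCO3-, pH).

    Used to verify that CA (scaling both rate constants by A + 1) leaves
    the chemical equilibrium unchanged.
    """
    ch = chemistry
    x0 = _x_from_pH(pH0, ch.buffer_total, ch.Ka)

    def rhs(t, y):
        c, b, x = y
        h = float(_h_from_x(np.array([x]), ch.buffer_total, ch.Ka)[0])
        r = (A + 1.0) * ch.k_h_uncat * (c - h * b / ch.K1prime)
        return [-r, r, r]

    sol = solve_ivp(rhs, (0.0, t_end), [c0, b0, x0], method="BDF",
                    rtol=1e-11, atol=1e-13)
    c, b, x = sol.y[:, -1]
    h = float(_h_from_x(np.array([x]), ch.buffer_total, ch.Ka)[0])
    return float(c), float(b), float(-math.log10(h))
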