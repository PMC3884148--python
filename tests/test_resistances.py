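"""Closed-form resistance arithmetic against hand-computed oracles."""

import math
from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from co2perm.errors import InvalidInputError
from co2perm.resistances import (
    INFINITE_PERMEABILITY,
    CellReleaseModel,
    LayerStack,
    PartitionEntry,
    SphereUptakeSpec,
    cardiomyocyte_release_rate,
    crank_uptake_time,
    effective_solubility,
    partition_scaled_permeability,
    required_gradient_for_flux,
    series_total_resistance,
    solubility_diffusion_permeability,
)

CARDIO = dict(diffusion_path_d=7e-4, cytoplasmic_D=1.3e-5,
              tissue_solubility_alpha=7.2e-4, delta_p=0.35)


class TestSolubilityDiffusion:
    @pytest.mark.parametrize(
        "D_M, K_P, d, expected",
        [
            (1e-5, 0.0, 4e-7, 0.0),       # zero partition -> zero permeability
            (1e-5, 2.0, 4e-7, 50.0),      # hand arithmetic
        ],
    )
    def test_values(self, D_M, K_P, d, expected):
        assert solubility_diffusion_permeability(D_M, K_P, d) == pytest.approx(expected)

    def test_doubling_thickness_halves_permeability(self):
        p1 = solubility_diffusion_permeability(1e-5, 1.0, 4e-7)
        p2 = solubility_diffusion_permeability(1e-5, 1.0, 8e-7)
        assert p1 == pytest.approx(2 * p2)

    def test_nonpositive_thickness_rejected(self):
        with pytest.raises(InvalidInputError):
            solubility_diffusion_permeability(1e-5, 1.0, 0.0)


class TestPartitionScaling:
    @pytest.mark.parametrize(
        "K_ref, K_target, expected",
        [(0.95, 3.9, 4.1), (0.95, 4.4, 4.6), (1.6, 4.5, 2.8)],
    )
    def test_gas_predictions_from_reference(self, K_ref, K_target, expected):
        # permeabilities predicted from a 1 cm/s reference membrane
        assert partition_scaled_permeability(1.0, K_ref, K_target) == pytest.approx(
            expected, abs=0.05
        )

    def test_identity_and_bad_reference(self):
        assert partition_scaled_permeability(0.7, 2.0, 2.0) == 0.7
        with pytest.raises(InvalidInputError):
            partition_scaled_permeability(1.0, 0.0, 1.0)

    def test_partition_entry_consistency_enforced(self):
        PartitionEntry("CO2", 45.0, 74.0, 1.6)  # consistent to 2 sig figs
        with pytest.raises(InvalidInputError):
            PartitionEntry("CO2", 45.0, 74.0, 2.5)


class TestSeriesResistance:
    def test_single_usl_plus_bilayer(self):
        # printed as 5.6 + 0.3 = 5.9 s/cm; exact arithmetic gives 5.87
        R, P = series_total_resistance(LayerStack([(1e-4, 1.8e-5)], [3.2]))
        assert R == pytest.approx(5.9, rel=0.01)
        assert P == pytest.approx(1 / R)

    def test_thick_water_path_drowns_fast_membranes(self):
        R, _ = series_total_resistance(LayerStack([(190e-4, 1.5e-5)], [3.2, 3.2]))
        assert R == pytest.approx(1271, rel=0.005)

    def test_slow_membranes_add_visibly(self):
        R, _ = series_total_resistance(LayerStack([(190e-4, 1.5e-5)], [0.017, 0.017]))
        assert R == pytest.approx(1390, rel=0.005)

    def test_empty_stack(self):
        R, P = series_total_resistance(LayerStack())
        assert R == 0.0 and math.isinf(P)

    def test_infinite_permeability_contributes_exactly_zero(self):
        R0, _ = series_total_resistance(LayerStack([(1e-4, 1.8e-5)], []))
        R1, _ = series_total_resistance(
            LayerStack([(1e-4, 1.8e-5)], [INFINITE_PERMEABILITY])
        )
        assert R0 == R1

    @settings(derandomize=True, max_examples=50)
    @given(
        d=st.floats(1e-6, 1e-2), D=st.floats(1e-6, 1e-4),
        p1=st.floats(1e-4, 10.0), p2=st.floats(1e-4, 10.0),
    )
    def test_additivity_and_bottleneck_bound(self, d, D, p1, p2):
        a = LayerStack([(d, D)], [p1])
        b = LayerStack([], [p2])
        Ra, Pa = series_total_resistance(a)
        Rb, _ = series_total_resistance(b)
        Rab, Pab = series_total_resistance(a + b)
        assert Rab == pytest.approx(Ra + Rb, rel=1e-12)  # additive in series
        assert Pab <= min(p1, p2) * (1 + 1e-12)


class TestCellRelease:
    def test_no_membrane_limit_is_maximal_cardiac_output(self):
        rate = cardiomyocyte_release_rate(CellReleaseModel(**CARDIO))
        assert rate == pytest.approx(0.4, abs=0.005)

    @pytest.mark.parametrize("P, factor", [(0.01, 3), (0.001, 20)])
    def test_low_permeability_reduction_factors(self, P, factor):
        full = cardiomyocyte_release_rate(CellReleaseModel(**CARDIO))
        limited = cardiomyocyte_release_rate(CellReleaseModel(**CARDIO, membrane_P=P))
        assert round(full / limited) == factor

    def test_saturation_limit(self):
        # release(P -> inf) approaches D*alpha*dp/d^2 to better than 1e-9
        big = cardiomyocyte_release_rate(CellReleaseModel(**CARDIO, membrane_P=1e9))
        closed = 60 * 1.3e-5 * 7.2e-4 * 0.35 / 7e-4**2
        assert big == pytest.approx(closed, rel=1e-9)

    def test_monotone_in_permeability(self):
        rates = [cardiomyocyte_release_rate(CellReleaseModel(**CARDIO, membrane_P=P))
                 for P in (1e-3, 1e-2, 1e-1, 1.0)]
        assert all(a < b for a, b in zip(rates, rates[1:]))

    def test_required_gradient_inverse(self):
        model = CellReleaseModel(**{**CARDIO, "delta_p": None})
        dp = required_gradient_for_flux(0.4, model)
        assert dp == pytest.approx(0.35, abs=0.005)
        # exact round trip
        rate = cardiomyocyte_release_rate(replace(model, delta_p=dp))
        assert required_gradient_for_flux(rate, model) == pytest.approx(dp, rel=1e-12)
        # linearity and degenerate cases
        assert required_gradient_for_flux(0.8, model) == pytest.approx(2 * dp, rel=1e-12)
        assert required_gradient_for_flux(0.0, model) == 0.0
        with pytest.raises(InvalidInputError):
            required_gradient_for_flux(-1.0, model)


class TestEffectiveSolubility:
    def test_unbuffered_limit_is_physical_solubility(self):
        assert effective_solubility(9.8e-4, 0.0) == pytest.approx(9.8e-4, rel=0.05)

    def test_hepes_buffered_vesicle_value(self):
        # 25 mM HEPES, pCO2 1 -> 40 mmHg; the printed 53e-4 depends on the
        # unstated starting pH and pKa, so only approximate agreement holds
        assert effective_solubility(9.8e-4, 25.0) == pytest.approx(53e-4, rel=0.25)

    def test_monotone_in_buffer(self):
        vals = [effective_solubility(9.8e-4, B) for B in (0.0, 5.0, 25.0, 100.0)]
        assert all(a < b for a, b in zip(vals, vals[1:]))

    def test_matches_dense_pH_grid_scan(self):
        # independent oracle: brute-force scan of the proton balance over pH
        import numpy as np

        from co2perm.carbonate import CO2_ML_PER_MMOL, buffer_protonated_fraction

        alpha, B, pKa, pH1, p1, p2 = 9.8e-4, 25.0, 7.5, 7.4, 1.0, 40.0
        K1, Ka = 10 ** -6.07, 10 ** -pKa
        aM = alpha / CO2_ML_PER_MMOL
        h1 = 10 ** -pH1
        b1 = K1 * aM * p1 / h1
        grid = np.linspace(2, 12, 2_000_001)
        h = 10.0 ** -grid
        resid = (K1 * aM * p2 / h - b1
                 - B * 1e-3 * (buffer_protonated_fraction(h, Ka)
                               - buffer_protonated_fraction(h1, Ka))
                 - (h - h1))
        i = int(np.argmin(np.abs(resid)))
        expected = alpha + (K1 * aM * p2 / h[i] - b1) * CO2_ML_PER_MMOL / (p2 - p1)
        got = effective_solubility(alpha, B, pKa, pH1, p1, p2, K1)
        assert got == pytest.approx(expected, rel=0.005)


class TestCrankUptake:
    def test_buffered_vesicle_uptake_time(self):
        t = crank_uptake_time(SphereUptakeSpec(75e-7, 1.8e-5, 9.8e-4, 53e-4))
        assert t == pytest.approx(1e-5, rel=0.02)

    def test_unbuffered_identity_and_r2_scaling(self):
        t1 = crank_uptake_time(SphereUptakeSpec(75e-7, 1.8e-5, 9.8e-4, 9.8e-4))
        assert t1 == pytest.approx(0.6 * (75e-7) ** 2 / 1.8e-5)
        t2 = crank_uptake_time(SphereUptakeSpec(150e-7, 1.8e-5, 9.8e-4, 9.8e-4))
        assert t2 == pytest.approx(4 * t1)

    def test_alpha_ordering_enforced(self):
        with pytest.raises(InvalidInputError):
            SphereUptakeSpec(75e-7, 1.8e-5, 9.8e-4, 5e-4)
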