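"""18O-exchange forward model, metrics and permeability fitting."""

import math
from dataclasses import replace

import numpy as np
import pytest

from co2perm.carbonate import WATER_MM, CarbonateSystem, carbonate_equilibrium
from co2perm.errors import MetricError
from co2perm.o18 import (
    CellSuspension,
    MassSpecTrace,
    O18ExchangeModel,
    convolve_instrument_response,
    count_grid_local_minima,
    initial_label_state,
    label_rate_matrix,
    label_rhs,
    monte_carlo_label_decay,
    net_hydration_halftime,
    second_phase_difference,
    sensitivity_table,
    simulate_label_states,
    simulate_trace,
    terminal_decay_rate,
    trace_metrics,
    uncatalysed_decay_rate,
)
from co2perm.o18 import _propagate


class TestCarbonateEquilibrium:
    def test_physiological_ratio(self, chamber_73):
        co2, hco3 = carbonate_equilibrium(chamber_73)
        assert hco3 / co2 == pytest.approx(17, rel=0.01)

    def test_ratio_one_at_pK(self):
        sys_ = CarbonateSystem(pH=6.07)
        assert sys_.ratio == pytest.approx(1.0, rel=1e-6)

    def test_partitioning_of_total(self):
        sys_ = CarbonateSystem(pH=6.07 + math.log10(17), total_carbonate=20.0)
        co2, hco3 = carbonate_equilibrium(sys_)
        assert co2 + hco3 == pytest.approx(20.0)
        assert hco3 == pytest.approx(20.0 * 17 / 18, rel=1e-6)  # algebra oracle


class TestLabelKinetics:
    def test_total_label_is_conserved(self, rbc_suspension, chamber_74):
        ys = simulate_label_states(rbc_suspension, chamber_74, 0.0,
                                   np.linspace(0, 600, 25))
        f = rbc_suspension.cytocrit
        total = (1 - f) * ys[:3].sum(axis=0) + f * ys[3:].sum(axis=0)
        assert np.max(np.abs(total - total[0])) / total[0] < 1e-9

    def test_rate_matrix_columns_conserve_label(self, rbc_suspension, chamber_74):
        M = label_rate_matrix(rbc_suspension, chamber_74)
        f = rbc_suspension.cytocrit
        w = np.array([1 - f] * 3 + [f] * 3)
        assert np.allclose(w @ M, 0.0, atol=1e-12)

    def test_labelled_water_feeds_back_into_bicarbonate(self, chamber_74):
        # all-labelled-water start: label must flow into HCO3-, not CO2 directly
        dy = label_rhs(0.0, np.array([0.0, 0.0, 1.0]), None, chamber_74)
        assert dy[1] > 0 and dy[0] == 0 and dy[2] < 0

    def test_slow_eigenvalue_matches_two_species_closed_form(self, chamber_73):
        # 2x2 eigenvalue oracle for the extracellular label subsystem
        M = label_rate_matrix(None, chamber_73)
        M = M.copy(); M[:, 2] = 0.0; M[2, 2] = 0.0
        lam = np.sort(np.linalg.eigvals(M).real)
        approx = chamber_73.k_h_uncat / (3 * (1 + chamber_73.ratio))
        assert -lam[1] == pytest.approx(approx, rel=0.03)
        assert -lam[1] == pytest.approx(uncatalysed_decay_rate(chamber_73), rel=1e-9)

    def test_isotopic_equilibrium_proportions_in_null_space(self, chamber_73):
        # chemical-equilibrium consistency: the stationary label distribution
        # puts equal labelled fraction on every oxygen site, i.e. the amounts
        # of labelled CO2 : HCO3- : H2O stand as 2[CO2] : 3[HCO3-] : W
        M = label_rate_matrix(None, chamber_73)
        w, V = np.linalg.eig(M)
        v = np.real(V[:, np.argmin(np.abs(w))])
        v = v / v.sum()
        sites = np.array([2 * chamber_73.co2, 3 * chamber_73.hco3, WATER_MM])
        assert np.allclose(v, sites / sites.sum(), rtol=1e-6)


class TestSimulateTrace:
    def test_solution_only_slow_decay_halftime(self, chamber_73):
        trace = simulate_trace(None, chamber_73, t_end=1500, n_points=1501)
        t_half = math.log(2) / terminal_decay_rate(trace)
        assert t_half == pytest.approx(250, rel=0.15)

    def test_decay_to_net_hydration_ratio(self, chamber_73):
        trace = simulate_trace(None, chamber_73, t_end=1500, n_points=1501)
        t_half = math.log(2) / terminal_decay_rate(trace)
        assert t_half / net_hydration_halftime(chamber_73) == pytest.approx(50, rel=0.15)

    def test_net_hydration_scaling_and_buffered_mode(self, chamber_73):
        fast = CarbonateSystem(pH=7.3, k_h_uncat=2 * chamber_73.k_h_uncat)
        assert net_hydration_halftime(fast) == pytest.approx(
            net_hydration_halftime(chamber_73) / 2)
        # a strong but finite buffer approaches the clamped-pH limit
        buffered = net_hydration_halftime(chamber_73, buffer_total=2000.0)
        assert buffered == pytest.approx(net_hydration_halftime(chamber_73), rel=0.1)

    def test_hematocrit_step_accelerates_overall_kinetics(
        self, rbc_suspension, chamber_74
    ):
        tr_lo = simulate_trace(rbc_suspension, chamber_74, t_end=600, n_points=601)
        tr_hi = simulate_trace(replace(rbc_suspension, cytocrit=0.002),
                               chamber_74, t_end=600, n_points=601)
        ratio = terminal_decay_rate(tr_hi) / terminal_decay_rate(tr_lo)
        assert ratio == pytest.approx(5.5, rel=0.2)

    def test_trace_monotone_toward_equilibrium(self, rbc_suspension, chamber_74):
        trace = simulate_trace(rbc_suspension, chamber_74, t_end=600, n_points=301)
        assert np.all(np.diff(trace.c18o16o) <= 1e-12)
        assert trace.c18o16o[-1] >= trace.equilibrium_value - 1e-12

    def test_eig_and_bdf_routes_agree(self, rbc_suspension, chamber_74):
        kw = dict(t_add=30.0, t_end=300, n_points=61)
        a = simulate_trace(rbc_suspension, chamber_74, **kw, method="eig")
        b = simulate_trace(rbc_suspension, chamber_74, **kw, method="ivp")
        assert np.max(np.abs(a.c18o16o - b.c18o16o)) / a.c18o16o[0] < 1e-6

    def test_reduced_five_state_mode_agrees(self, rbc_suspension, chamber_74):
        a = simulate_trace(rbc_suspension, chamber_74, t_end=600, n_points=301)
        b = simulate_trace(rbc_suspension, chamber_74, t_end=600, n_points=301,
                           track_extracellular_water=False)
        assert np.max(np.abs(a.c18o16o - b.c18o16o)) / a.c18o16o[0] < 1e-3

    def test_monte_carlo_oracle_matches_ode(self, chamber_73):
        t_grid = np.linspace(0, 600, 121)
        n = 100_000
        mc = monte_carlo_label_decay(chamber_73, t_grid, n_molecules=n,
                                     rng=np.random.default_rng(20240917))
        M = label_rate_matrix(None, chamber_73).copy()
        M[:, 2] = 0.0; M[2, 2] = 0.0  # absorbing water, as in the MC rule
        y0 = initial_label_state(chamber_73, 1.0)
        ode = _propagate(M, y0 / y0.sum(), t_grid)[0]
        envelope = 4 * math.sqrt(ode[0] * (1 - ode[0]) / n)
        assert np.max(np.abs(mc - ode)) < envelope


class TestTraceMetrics:
    def test_pure_exponential_halftime(self):
        t = np.linspace(0, 100, 501)
        m = trace_metrics(MassSpecTrace(t, np.exp(-0.05 * t), 0.0))
        assert m["half_time"] == pytest.approx(math.log(2) / 0.05, rel=0.01)
        assert m["fast_phase_amplitude"] == 0.0

    def test_non_monotone_trace_rejected(self):
        t = np.linspace(0, 10, 11)
        c = np.exp(-t); c[5] = 2.0
        with pytest.raises(MetricError):
            trace_metrics(MassSpecTrace(t, c, 0.0))

    def test_second_phase_separation_mdck(self, mdck_suspension, chamber_74):
        traces = {
            P: simulate_trace(replace(mdck_suspension, P_CO2=P), chamber_74,
                              t_end=600, n_points=601)
            for P in (0.01, 0.1, 1.0)
        }
        d_low = second_phase_difference(traces[0.01], traces[0.1])
        d_high = second_phase_difference(traces[0.1], traces[1.0])
        assert d_low == pytest.approx(0.20, abs=0.05)
        assert d_high == pytest.approx(0.03, abs=0.05)
        assert d_low > d_high  # resolution degrades with rising permeability


class TestInstrumentResponse:
    def test_zero_tau_is_identity(self, chamber_73):
        trace = simulate_trace(None, chamber_73, t_end=300, n_points=301)
        out = convolve_instrument_response(trace, tau=0.0)
        assert np.array_equal(out.c18o16o, trace.c18o16o)

    def test_step_input_relaxes_with_tau(self):
        t = np.linspace(0, 30, 3001)
        u = np.ones_like(t); u[0] = 0.0
        out = convolve_instrument_response(MassSpecTrace(t, u, 1.0), tau=3.0)
        expected = 1.0 - np.exp(-(t[1:]) / 3.0)
        assert np.max(np.abs(out.c18o16o[1:] - expected)) < 5e-3

    def test_slow_trace_nearly_unchanged(self, chamber_73):
        # the 3-s low-pass shifts the record by ~tau but leaves the slow
        # decay rate (hence the observed half-time) essentially untouched
        trace = simulate_trace(None, chamber_73, t_end=1500, n_points=1501)
        filt = convolve_instrument_response(trace, tau=3.0)
        r0 = terminal_decay_rate(trace)
        r1 = terminal_decay_rate(filt)
        assert abs(r1 - r0) / r0 < 0.01
        h0 = trace_metrics(trace)["half_time"]
        h1 = trace_metrics(filt)["half_time"]
        assert abs(h1 - h0) < 1.5 * 3.0  # crossing delayed by at most ~tau


class TestFitting:
    def test_noiseless_round_trip_recovery(self, rbc_suspension, chamber_74):
        trace = simulate_trace(rbc_suspension, chamber_74, t_end=600, n_points=301)
        start = replace(rbc_suspension, P_CO2=0.02, P_HCO3=2e-4)
        fit = O18ExchangeModel(trace, start, chamber_74).fit()
        assert fit.converged
        assert abs(fit.P_CO2_hat - 0.15) < 0.005
        assert fit.P_HCO3_hat == pytest.approx(1e-3, rel=0.05)

    def test_self_consistent_init_gives_zero_ssq(self, rbc_suspension, chamber_74):
        trace = simulate_trace(rbc_suspension, chamber_74, t_end=600, n_points=301)
        fit = O18ExchangeModel(trace, rbc_suspension, chamber_74).fit(
            init=(0.15, 1e-3))
        assert fit.ssq_min < 1e-12 * float(np.sum(trace.c18o16o**2))

    def test_identifiability_across_permeability_decades(
        self, rbc_suspension, chamber_74
    ):
        for true_p in (0.0015, 0.015, 0.15):
            susp = replace(rbc_suspension, P_CO2=true_p)
            trace = simulate_trace(susp, chamber_74, t_end=600, n_points=301)
            fit = O18ExchangeModel(trace, susp, chamber_74).fit()
            assert abs(fit.P_CO2_hat - true_p) / true_p < 0.05

    def test_ssq_surface_has_single_minimum(self, rbc_suspension, chamber_74):
        trace = simulate_trace(rbc_suspension, chamber_74, t_end=600, n_points=301)
        model = O18ExchangeModel(trace, rbc_suspension, chamber_74)
        _, _, Z = model.ssq_surface(n=40)
        assert count_grid_local_minima(Z) == 1

    def test_summary_mentions_estimates(self, rbc_suspension, chamber_74):
        trace = simulate_trace(rbc_suspension, chamber_74, t_end=600, n_points=151)
        fit = O18ExchangeModel(trace, rbc_suspension, chamber_74).fit(
            init=(0.15, 1e-3))
        assert "P_CO2" in fit.summary() and "sum of squares" in fit.summary()


class TestSensitivity:
    def test_zero_perturbation_changes_nothing(self, mdck_suspension, chamber_74):
        table = sensitivity_table(mdck_suspension, chamber_74,
                                  parameters=("A_i",), fractions=(0.0,))
        assert abs(table["delta_P_CO2_percent"].iloc[0]) < 0.5

    def test_raising_assumed_activity_lowers_fitted_permeability(
        self, mdck_suspension, chamber_74
    ):
        # A_i and P_CO2 play compensating roles in the fast phase; the
        # printed magnitudes (-11%/+26%) depend on the unstated cytocrit,
        # so only the sign structure and the order of magnitude are checked
        table = sensitivity_table(mdck_suspension, chamber_74,
                                  parameters=("A_i",), fractions=(-0.05, 0.05))
        down = table[table.fraction == 0.05]["delta_P_CO2_percent"].iloc[0]
        up = table[table.fraction == -0.05]["delta_P_CO2_percent"].iloc[0]
        assert down < -2 and up > 2
        assert 2 < abs(down) < 40 and 2 < abs(up) < 60
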