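import dataclasses
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cavclamp import curves, pipeline
from cavclamp.gating_model import CellModel, HookModel
from cavclamp.presets import PRESETS
from cavclamp.protocols import default_recovery_gaps_s

V_GRID = np.arange(-84.0, 62.0, 5.0)


class TestFitIv:
    @pytest.mark.parametrize(
        "v05,k,vrev",
        [(-0.12, 9.14, 62.82), (-28.5, 5.97, 41.64), (1.98, 10.08, 66.41)],
    )
    def test_exact_recovery_on_own_closed_form(self, v05, k, vrev):
        y = curves.iv_model(V_GRID, 0.4, vrev, v05, k)
        fit = curves.fit_iv(V_GRID, y)
        assert fit.v05_act_mV == pytest.approx(v05, abs=1e-6)
        assert fit.k_act_mV == pytest.approx(k, abs=1e-6)
        assert fit.vrev_mV == pytest.approx(vrev, abs=1e-6)

    def test_all_zero_densities_rejected(self):
        with pytest.raises(curves.DegenerateDataError):
            curves.fit_iv(V_GRID, np.zeros_like(V_GRID))

    def test_too_few_voltages_rejected(self):
        with pytest.raises(curves.FitError, match="at least 6"):
            curves.fit_iv(V_GRID[:4], np.ones(4))


class TestFitConductance:
    def test_exact_recovery_and_half_max_at_v05(self):
        g = curves.boltzmann_model(V_GRID, 8.0, -0.12, 9.14)
        fit = curves.fit_conductance(V_GRID, g)
        assert fit.v05_act_mV == pytest.approx(-0.12, abs=1e-8)
        assert curves.boltzmann_model(fit.v05_act_mV, fit.gmax, fit.v05_act_mV,
                                      fit.k_act_mV) == pytest.approx(fit.gmax / 2)

    def test_agrees_with_iv_fit_on_simulated_wt_family(self, quiet_cell):
        """Chord-conductance Boltzmann and the I-V fit give the same midpoint."""
        bundle = pipeline.simulate_iv_bundle(PRESETS["WT+b3"].gating, quiet_cell)
        V, dens = pipeline.iv_peak_densities(bundle)
        fit1 = curves.fit_iv(V, dens)
        Vg, g = curves.conductance_from_iv(V, dens, fit1.vrev_mV)
        fit2 = curves.fit_conductance(Vg, g)
        assert abs(fit1.v05_act_mV - fit2.v05_act_mV) <= 0.5


class TestFitSsi:
    def test_exact_recovery_of_mutant_parameters(self):
        V = np.arange(-109.0, 22.0, 10.0)
        y = curves.ssi_model(V, 0.3124, -42.88, 4.93)
        fit = curves.fit_ssi(V, y)
        assert fit.v05_inact_mV == pytest.approx(-42.88, abs=1e-6)
        assert fit.k_inact_mV == pytest.approx(4.93, abs=1e-6)
        assert fit.frac_noninact == pytest.approx(0.3124, abs=1e-8)

    def test_flat_curve_flagged_degenerate(self):
        V = np.arange(-109.0, 22.0, 10.0)
        with pytest.raises(curves.DegenerateDataError, match="indeterminate"):
            curves.fit_ssi(V, np.ones_like(V))

    def test_out_of_range_ratios_rejected(self):
        V = np.arange(-109.0, 22.0, 10.0)
        with pytest.raises(curves.FitError, match="outside"):
            curves.fit_ssi(V, np.linspace(1.5, 0.0, V.size))


class TestWindowCurrent:
    def test_full_availability_returns_iv_densities(self):
        fit = curves.InactivationFit(-26.0, 6.0, 1.0, 0.0, 10)
        pts = curves.window_current([-40.0, -20.0], [-5.0, -15.0], fit)
        assert [p.window_density_pA_per_pF for p in pts] == [-5.0, -15.0]

    def test_plateau_availability_scales_by_ini(self):
        fit = curves.InactivationFit(-200.0, 1.0, 0.3, 0.0, 10)  # fully plateaued
        pts = curves.window_current([0.0], [-10.0], fit)
        assert pts[0].window_density_pA_per_pF == pytest.approx(-3.0)

    def test_mutant_window_exceeds_wt_at_subthreshold_voltages(self, quiet_cell):
        """Gain-of-function: |window| of F747S > WT throughout -50..-20 mV."""
        profiles = {}
        for name in ("WT+b3", "F747S+b3"):
            ps = PRESETS[name]
            bundle = pipeline.simulate_iv_bundle(ps.gating, quiet_cell)
            V, dens = pipeline.iv_peak_densities(bundle)
            clean = dataclasses.replace(quiet_cell, leak_conductance_nS=0.0)
            ssi = pipeline.run_ssi(ps.gating, clean)
            profiles[name] = {
                p.V_mV: abs(p.window_density_pA_per_pF)
                for p in curves.window_current(V, dens, ssi)
            }
        for v in np.arange(-49.0, -19.0, 5.0):
            assert profiles["F747S+b3"][v] > profiles["WT+b3"][v]


class TestRemainingFractions:
    def _sweep(self, decay_tau=None, n_ms=5100.0):
        from cavclamp.preprocess import Sweep

        t = np.arange(0.0, n_ms, 0.5)
        i = np.full(t.size, -100.0)
        if decay_tau:
            i = -100.0 * np.exp(-t / decay_tau)
        return Sweep(
            time_ms=t,
            current_pA=i,
            v_command_mV=np.full(t.size, -9.0),
            sampling_rate_hz=2000.0,
            capacitance_pF=20.0,
            metadata={"pulse_window_ms": (0.0, n_ms)},
        )

    def test_non_decaying_trace_reads_100_everywhere(self):
        r = curves.remaining_fractions(self._sweep())
        assert all(v == pytest.approx(100.0) for v in r.values())

    def test_pure_mono_exponential_matches_e_folding(self):
        r = curves.remaining_fractions(self._sweep(decay_tau=1000.0))
        assert r[1000.0] == pytest.approx(100.0 * math.exp(-1.0), abs=0.05)

    def test_r_sequence_non_increasing(self, clean_cell):
        sw = pipeline.simulate_decay_sweep(PRESETS["WT+b3"].gating, clean_cell)
        # measured from the peak; keep points inside the 5-s pulse
        r = curves.remaining_fractions(sw, times_ms=(50, 100, 250, 500, 1000, 4900))
        vals = list(r.values())
        assert all(a >= b for a, b in zip(vals, vals[1:]))

    def test_time_beyond_pulse_rejected(self):
        with pytest.raises(curves.FitError, match="beyond"):
            curves.remaining_fractions(self._sweep(n_ms=3000.0))


class TestFitDecay:
    T = np.arange(0.0, 5000.0, 2.0)

    def test_biexponential_closed_form_recovered_exactly(self):
        y = curves._bi_model(self.T, 63.74, 227.20, 25.13, 1987.59, 7.12)
        fit = curves.fit_decay(self.T, y, model="bi")
        assert fit.a_fast_pct == pytest.approx(63.74, rel=1e-6)
        assert fit.tau_fast_ms == pytest.approx(227.20, rel=1e-6)
        assert fit.a_slow_pct == pytest.approx(25.13, rel=1e-6)
        assert fit.tau_slow_ms == pytest.approx(1987.59, rel=1e-6)
        assert fit.plateau_pct == pytest.approx(7.12, rel=1e-6)

    def test_monoexponential_closed_form_recovered_exactly(self):
        y = curves._mono_model(self.T, 67.48, 1424.08, 28.27)
        fit = curves.fit_decay(self.T, y, model="auto")
        assert fit.model == "mono"
        assert fit.a_slow_pct == pytest.approx(67.48, rel=1e-6)
        assert fit.tau_slow_ms == pytest.approx(1424.08, rel=1e-6)
        assert fit.plateau_pct == pytest.approx(28.27, rel=1e-6)

    def test_auto_prefers_bi_only_when_supported(self):
        y_bi = curves._bi_model(self.T, 63.74, 227.20, 25.13, 1987.59, 7.12)
        assert curves.fit_decay(self.T, y_bi, model="auto").model == "bi"
        y_mono = curves._mono_model(self.T, 67.48, 1424.08, 28.27)
        assert curves.fit_decay(self.T, y_mono, model="auto").model == "mono"

    def test_decay_fit_orders_time_constants(self):
        y = curves._bi_model(self.T, 25.0, 2000.0, 60.0, 200.0, 10.0)
        fit = curves.fit_decay(self.T, y, model="bi")
        assert fit.tau_fast_ms < fit.tau_slow_ms


class TestFitRecovery:
    GAPS = np.asarray(default_recovery_gaps_s())

    @pytest.mark.parametrize(
        "af,tf,aslow,ts",
        [(0.72, 67.6, 0.10, 5625.0), (0.36, 165.94, 0.44, 6778.23)],
    )
    def test_closed_form_parameters_recovered_exactly(self, af, tf, aslow, ts):
        off = 1.0 - af - aslow
        y = curves.recovery_model(self.GAPS * 1000.0, af, tf, aslow, ts, off)
        fit = curves.fit_recovery(self.GAPS, y)
        assert fit.a_fast == pytest.approx(af, abs=1e-6)
        assert fit.tau_fast_ms == pytest.approx(tf, rel=1e-6)
        assert fit.a_slow == pytest.approx(aslow, abs=1e-6)
        assert fit.tau_slow_ms == pytest.approx(ts, rel=1e-5)

    def test_single_exponential_data_drives_second_amplitude_to_zero(self):
        y = curves.recovery_model(self.GAPS * 1000.0, 0.8, 100.0, 0.0, 5000.0, 0.2)
        fit = curves.fit_recovery(self.GAPS, y)
        small = min(fit.a_fast, fit.a_slow)
        assert small == pytest.approx(0.0, abs=1e-4)

    def test_fractional_recovery_non_decreasing_in_gap(self, clean_cell):
        bundle = pipeline.simulate_recovery_bundle(PRESETS["WT+b3"].gating, clean_cell)
        gaps, frac = pipeline.recovery_fractions(bundle)
        order = np.argsort(gaps)
        assert np.all(np.diff(frac[order]) > -1e-9)

    def test_mutant_recovers_slower_than_wt_in_full_simulation(self, clean_cell):
        taus = {}
        for name in ("WT+b3", "F747S+b3"):
            fit = pipeline.run_recovery(PRESETS[name].gating, clean_cell)
            taus[name] = fit.tau_fast_ms
        assert taus["F747S+b3"] > taus["WT+b3"]


class TestAnalyzeTail:
    def _tail_sweep(self, tau=2.0):
        from cavclamp.preprocess import Sweep

        t = np.arange(0.0, 35.0, 0.02)
        i = np.zeros(t.size)
        repol = t >= 15.0
        i[repol] = -500.0 * np.exp(-(t[repol] - 15.0) / tau)
        return Sweep(
            time_ms=t,
            current_pA=i,
            v_command_mV=np.where(repol, -69.0, 62.8),
            sampling_rate_hz=50_000.0,
            capacitance_pF=20.0,
            metadata={"repol_window_ms": (15.0, 35.0), "repol_voltage_mV": -69.0},
        )

    def test_ideal_exponential_tail_integral_matches_closed_form(self):
        res = curves.analyze_tail(self._tail_sweep(tau=2.0))
        assert res.normalized_integral_ms == pytest.approx(
            2.0 * (1.0 - math.exp(-10.0)), abs=0.02
        )
        assert res.tau_deact_ms == pytest.approx(2.0, rel=0.02)

    def test_monotone_decay_reports_no_hook(self):
        assert not curves.analyze_tail(self._tail_sweep()).hook_present

    def test_hook_simulation_delays_tail_peak(self, clean_cell):
        p = dataclasses.replace(
            PRESETS["F747S+b3"].gating,
            hook=HookModel(enabled=True, tau_unblock_ms=1.5, blocked_frac=0.4),
        )
        bundle = pipeline.simulate_tail_bundle(p, clean_cell)
        sw = next(s for s in bundle if s.metadata["repol_voltage_mV"] == -69.0)
        res = curves.analyze_tail(sw)
        assert res.hook_present
        assert res.hook_delay_ms > 0.0

    def test_silent_trace_rejected(self):
        sw = self._tail_sweep()
        sw.current_pA[:] = 0.0
        with pytest.raises(curves.FitError, match="noise floor"):
            curves.analyze_tail(sw)


class TestFitDoseResponse:
    def test_points_on_curve_recover_ic50(self):
        c = np.array([10.0, 30.0, 100.0, 300.0, 3000.0])
        y = 100.0 * c / (c + 60.0)
        fit = curves.fit_dose_response(c, y)
        assert fit.ic50_nM == pytest.approx(60.0, rel=1e-8)
        assert fit.ci95_nM[0] <= fit.ic50_nM <= fit.ci95_nM[1]

    def test_inhibition_at_ic50_is_half(self):
        fit = curves.fit_dose_response(
            np.array([30.0, 300.0]), 100.0 * np.array([30.0, 300.0]) / (np.array([30.0, 300.0]) + 60.0)
        )
        assert curves.hill_inhibition_model(fit.log_ic50, fit.log_ic50) == pytest.approx(50.0)

    def test_unconstrained_inhibition_rejected(self):
        with pytest.raises(curves.DegenerateDataError):
            curves.fit_dose_response(np.array([1.0, 3.0]), np.array([0.0, 0.1]))

    @settings(max_examples=40, deadline=None)
    @given(log_ic50=st.floats(min_value=0.0, max_value=4.0))
    def test_identity_on_own_closed_form_across_ic50_range(self, log_ic50):
        """IC50 in [1, 10^4] nM is recovered from its own Hill curve."""
        ic50 = 10.0**log_ic50
        c = np.array([0.1, 1.0, 10.0, 100.0]) * ic50
        y = 100.0 * c / (c + ic50)
        fit = curves.fit_dose_response(c, y)
        assert fit.ic50_nM == pytest.approx(ic50, rel=1e-6)
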