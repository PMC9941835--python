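import dataclasses

import numpy as np
import pytest

from cavclamp import gating_model as gm
from cavclamp import preprocess as pp
from cavclamp import protocols as pr
from cavclamp.gating_model import CellModel
from cavclamp.presets import PRESETS

WT = PRESETS["WT+b3"].gating


def _iv_sweep_with_leaks(p, cell, v=-19.0):
    proto = pr.build_iv_family(v_start_mV=v, v_stop_mV=v).sweeps[0]
    test = gm.simulate_sweep(proto, p, cell)
    leaks = [
        gm.simulate_sweep(lp, p, cell) for lp in pr.p4_leak_pulses(proto).sweeps
    ]
    return test, leaks


class TestP4Subtract:
    def test_pure_ohmic_cell_cancels_exactly(self, quiet_cell):
        p = dataclasses.replace(WT, gmax_density_nS_per_pF=0.0)
        test, leaks = _iv_sweep_with_leaks(p, quiet_cell)
        out = pp.p4_subtract(test, leaks)
        assert np.max(np.abs(out.current_pA)) <= 1e-9

    def test_no_leak_leaves_channel_current_unchanged(self, clean_cell):
        """Without leak, P/4 only re-baselines: the channel current survives
        up to the sub-pA standing current of the hyperpolarizing sub-pulses."""
        test, leaks = _iv_sweep_with_leaks(WT, clean_cell)
        out = pp.p4_subtract(test, leaks)
        rebased = test.current_pA - test.current_pA[:100].mean()
        # the four quarter-pulses deactivate the sub-pA standing current at
        # the holding potential, leaving ~0.25 pA on a ~160 pA peak
        np.testing.assert_allclose(out.current_pA, rebased, atol=0.3)

    def test_mixed_sweep_recovers_channel_only_current(self, quiet_cell):
        """P/4 on channel + ohmic leak equals P/4 on the leak-free cell."""
        test, leaks = _iv_sweep_with_leaks(WT, quiet_cell)
        out = pp.p4_subtract(test, leaks)
        clean = dataclasses.replace(quiet_cell, leak_conductance_nS=0.0)
        ref, ref_leaks = _iv_sweep_with_leaks(WT, clean)
        ref_out = pp.p4_subtract(ref, ref_leaks)
        np.testing.assert_allclose(out.current_pA, ref_out.current_pA, atol=1e-6)

    def test_misaligned_sweeps_rejected(self, quiet_cell):
        test, leaks = _iv_sweep_with_leaks(WT, quiet_cell)
        with pytest.raises(pp.PreprocessError, match="misaligned"):
            pp.p4_subtract(test, leaks[:3] + [dataclasses.replace(
                leaks[3],
                time_ms=leaks[3].time_ms[:-1],
                current_pA=leaks[3].current_pA[:-1],
                v_command_mV=leaks[3].v_command_mV[:-1],
            )])


class TestOfflineLinearSubtract:
    def test_leak_only_sweep_flattens(self, quiet_cell):
        p = dataclasses.replace(WT, gmax_density_nS_per_pF=0.0)
        proto = pr.build_inact5s_protocol(-9.0, sampling_rate_hz=10_000.0)
        sw = gm.simulate_sweep(proto, p, quiet_cell)
        with pytest.warns(UserWarning, match="single command voltage"):
            out = pp.offline_linear_subtract(sw, (0.0, 5.0))
        # holding-segment samples are zeroed exactly; pulse leak remains ohmic
        hold = out.window_slice((0.0, 5.0))
        assert np.max(np.abs(out.current_pA[hold])) < 1e-9

    def test_zero_leak_sweep_unchanged(self, clean_cell):
        proto = pr.build_inact5s_protocol(-9.0, sampling_rate_hz=10_000.0)
        sw = gm.simulate_sweep(proto, WT, clean_cell)
        with pytest.warns(UserWarning):
            out = pp.offline_linear_subtract(sw, (0.0, 5.0))
        # only the sub-pA standing holding current is removed
        np.testing.assert_allclose(out.current_pA, sw.current_pA, atol=0.1)


class TestPeakCurrent:
    def test_flat_trace_returns_zero(self):
        n = 100
        sw = pp.Sweep(
            time_ms=np.arange(n) * 0.1,
            current_pA=np.zeros(n),
            v_command_mV=np.full(n, -89.0),
            sampling_rate_hz=10_000.0,
            capacitance_pF=20.0,
        )
        pk = pp.peak_current(sw, (0.0, 5.0))
        assert pk.amplitude_pA == 0.0

    def test_density_is_amplitude_over_capacitance(self):
        n = 100
        i = np.zeros(n)
        i[40] = -500.0
        sw = pp.Sweep(
            time_ms=np.arange(n) * 0.1,
            current_pA=i,
            v_command_mV=np.full(n, -19.0),
            sampling_rate_hz=10_000.0,
            capacitance_pF=20.0,
        )
        pk = pp.peak_current(sw, (0.0, 10.0))
        assert pk.amplitude_pA == -500.0
        assert pk.density_pA_per_pF == pytest.approx(-25.0)

    def test_density_is_capacitance_invariant(self, clean_cell):
        """Scaled cells give the same density at different absolute peaks."""
        proto = pr.build_iv_family(v_start_mV=-19, v_stop_mV=-19).sweeps[0]
        small = gm.simulate_sweep(proto, WT, clean_cell)
        big_cell = dataclasses.replace(clean_cell, capacitance_pF=40.0)
        big = gm.simulate_sweep(proto, WT, big_cell)
        w = tuple(small.metadata["pulse_window_ms"])
        d_small = pp.peak_current(small, w).density_pA_per_pF
        d_big = pp.peak_current(big, w).density_pA_per_pF
        assert d_small == pytest.approx(d_big, rel=1e-12)

    def test_empty_window_rejected(self):
        sw = pp.Sweep(
            time_ms=np.arange(10) * 0.1,
            current_pA=np.zeros(10),
            v_command_mV=np.zeros(10),
            sampling_rate_hz=10_000.0,
            capacitance_pF=20.0,
        )
        with pytest.raises(pp.PreprocessError, match="empty window"):
            pp.peak_current(sw, (0.5, 0.5))


class TestRundown:
    def test_constant_series_gives_zero_slope(self):
        t = np.arange(10) * 10.0
        fit = pp.fit_rundown(t, np.full(10, -800.0))
        assert fit.slope_pct_per_min == pytest.approx(0.0, abs=1e-12)

    def test_generated_slope_recovered_exactly(self):
        """A noise-free linear run-down series returns its slope verbatim."""
        slope = -1.5383  # %/min
        t = np.arange(30) * 10.0
        peaks = -800.0 * (1.0 + slope / 100.0 * t / 60.0)
        fit = pp.fit_rundown(t, peaks)
        assert fit.slope_pct_per_min == pytest.approx(slope, abs=1e-10)

    def test_noisy_slope_ci_covers_truth(self, rng):
        """~95% of noisy regressions bracket the generating slope."""
        slope = -1.5
        t = np.arange(40) * 10.0
        hits = 0
        n_rep = 200
        for _ in range(n_rep):
            peaks = -800.0 * (1.0 + slope / 100.0 * t / 60.0)
            peaks += rng.normal(0.0, 4.0, size=t.size)
            fit = pp.fit_rundown(t, peaks)
            half = 1.96 * fit.stderr_slope
            if fit.slope_pct_per_min - half <= slope <= fit.slope_pct_per_min + half:
                hits += 1
        assert 0.88 <= hits / n_rep <= 1.0

    def test_too_few_points_rejected(self):
        with pytest.raises(pp.PreprocessError, match="at least 3"):
            pp.fit_rundown([0.0, 10.0], [-800.0, -790.0])


class TestRundownCorrect:
    def _rundown(self, slope):
        t = np.arange(30) * 10.0
        peaks = -800.0 * (1.0 + slope / 100.0 * t / 60.0)
        return pp.fit_rundown(t, peaks)

    def test_drug_free_run_corrects_to_zero_inhibition(self):
        slope = -1.5383
        rd = self._rundown(slope)
        t = np.arange(30) * 10.0
        peaks = -800.0 * (1.0 + slope / 100.0 * t / 60.0)
        with pytest.warns(UserWarning, match="clipped"):
            # numerical noise straddles 0% inhibition, so clipping warns
            inh = pp.rundown_correct(t, peaks, rd)
        np.testing.assert_allclose(inh, 0.0, atol=1e-8)

    def test_full_block_reads_100_percent(self):
        rd = self._rundown(-1.0)
        t = np.arange(5) * 10.0
        inh = pp.rundown_correct(t, np.zeros(5), rd, reference_peak_pA=-800.0)
        np.testing.assert_allclose(inh, 100.0)

    def test_correction_invariant_to_rundown_slope(self):
        """Corrected steady-state inhibition does not depend on how fast the
        control current ran down (within a small fraction of a point)."""
        t = np.arange(40) * 10.0
        block = 1.0 / 3.0  # 30 nM on IC50 60 nM at equilibrium
        results = []
        for slope in (-1.5383, -0.1006):
            rd = self._rundown(slope)
            peaks = -800.0 * (1.0 + slope / 100.0 * t / 60.0) * (1.0 - block)
            inh = pp.rundown_correct(t, peaks, rd, reference_peak_pA=-800.0)
            results.append(inh[-5:].mean())
        assert abs(results[0] - results[1]) < 1.0
        assert results[0] == pytest.approx(100.0 * block, abs=0.5)


def test_steady_state_inhibition_averages_last_three():
    t = np.arange(8) * 10.0
    conc = [0, 0, 30, 30, 30, 30, 30, 30]
    inh = [0, 0, 10, 20, 30, 31, 32, 33]
    out = pp.steady_state_inhibition(t, inh, conc)
    assert out == {30.0: pytest.approx(32.0)}
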