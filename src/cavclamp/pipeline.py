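"""End-to-end workflows: simulate a protocol family on a channel preset,
preprocess the sweeps, and run the corresponding curve fit.

These functions tie the modules together the way the analysis scripts, the
CLI and the test-suite use them; each is a thin composition of the public
operations of :mod:`protocols`, :mod:`gating_model`, :mod:`preprocess` and
:mod:`curves`.
"""

from __future__ import annotations

import numpy as np

from . import curves, preprocess, protocols
from .gating_model import (
    CellModel,
    DrugModel,
    GatingParams,
    simulate_family,
    simulate_pharmacology_run,
    simulate_sweep,
    voltage_of_peak_current,
)
from .preprocess import SweepBundle


# ---------------------------------------------------------------------------
# I-V


def simulate_iv_bundle(
    p: GatingParams,
    cell: CellModel,
    *,
    v_start_mV: float = -84.0,
    v_stop_mV: float = 61.0,
    step_mV: float = 5.0,
    p4: bool = True,
) -> SweepBundle:
    """Simulate a 25-ms I-V family with online P/4 leak subtraction."""
    family = protocols.build_iv_family(
        v_start_mV=v_start_mV, v_stop_mV=v_stop_mV, step_mV=step_mV
    )
    rng = np.random.default_rng(cell.seed)
    sweeps = []
    for i, proto in enumerate(family.sweeps):
        sw = simulate_sweep(proto, p, cell, rng=rng)
        if p4:
            leak_protos = protocols.p4_leak_pulses(proto)
            leaks = [simulate_sweep(lp, p, cell, rng=rng) for lp in leak_protos.sweeps]
            sw = preprocess.p4_subtract(sw, leaks)
        sw.metadata["sweep_index"] = i
        sweeps.append(sw)
    return SweepBundle(sweeps=sweeps, family_kind="IV", metadata={"channel": p.label})


def iv_peak_densities(bundle: SweepBundle) -> tuple[np.ndarray, np.ndarray]:
    """(test voltage, peak current density) across an I-V bundle.

    The peak window is the entire test pulse of each sweep; the extremum is
    taken by magnitude so that test potentials beyond reversal contribute
    their (small) outward peaks.
    """
    V, dens = [], []
    for sw in bundle:
        pk = preprocess.peak_current(
            sw, tuple(sw.metadata["pulse_window_ms"]), polarity="absolute"
        )
        V.append(sw.metadata["test_voltage_mV"])
        dens.append(pk.density_pA_per_pF)
    return np.asarray(V), np.asarray(dens)


def analyze_iv(bundle: SweepBundle) -> curves.ActivationFit:
    V, dens = iv_peak_densities(bundle)
    return curves.fit_iv(V, dens)


def run_iv(p: GatingParams, cell: CellModel, **kwargs) -> curves.ActivationFit:
    return analyze_iv(simulate_iv_bundle(p, cell, **kwargs))


# ---------------------------------------------------------------------------
# steady-state inactivation


def simulate_ssi_bundle(
    p: GatingParams,
    cell: CellModel,
    *,
    cond_start_mV: float = -109.0,
    cond_stop_mV: float = 21.0,
    step_mV: float = 10.0,
    sampling_rate_hz: float = 10_000.0,
) -> SweepBundle:
    """Simulate the two-pulse SSI family (5-s conditioning, 10-mV steps).

    Availability is insensitive to the sampling rate, so the default here is
    10 kHz to keep the 5-s conditioning sweeps light.
    """
    vmax = voltage_of_peak_current(p)
    family = protocols.build_ssi_family(
        vmax_mV=vmax,
        cond_start_mV=cond_start_mV,
        cond_stop_mV=cond_stop_mV,
        step_mV=step_mV,
        sampling_rate_hz=sampling_rate_hz,
    )
    return simulate_family(family, p, cell)


def ssi_ratios(
    bundle: SweepBundle, *, settle_ms: float = 8.0
) -> tuple[np.ndarray, np.ndarray]:
    """(conditioning voltage, test/control peak ratio) per sweep.

    Both peak-search windows start ``settle_ms`` into their pulse, mirroring
    cursor placement after the activation settling phase: following a
    depolarized conditioning step the activation gate is still open at test
    onset, and an instantaneous-onset peak would overstate availability.
    """
    import warnings

    V, ratio = [], []
    for sw in bundle:
        if sw.metadata.get("leak_subtracted") is None:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")  # single-voltage baseline is expected
                sw = preprocess.offline_linear_subtract(
                    sw, (0.0, sw.metadata["control_window_ms"][0])
                )
        c0, c1 = sw.metadata["control_window_ms"]
        t0, t1 = sw.metadata["test_window_ms"]
        ctrl = preprocess.peak_current(sw, (c0 + settle_ms, c1))
        test = preprocess.peak_current(sw, (t0 + settle_ms, t1))
        V.append(sw.metadata["cond_voltage_mV"])
        ratio.append(test.amplitude_pA / ctrl.amplitude_pA)
    return np.asarray(V), np.asarray(ratio)


def analyze_ssi(bundle: SweepBundle) -> curves.InactivationFit:
    V, ratio = ssi_ratios(bundle)
    return curves.fit_ssi(V, np.clip(ratio, 0.0, 1.05))


def run_ssi(p: GatingParams, cell: CellModel, **kwargs) -> curves.InactivationFit:
    return analyze_ssi(simulate_ssi_bundle(p, cell, **kwargs))


# ---------------------------------------------------------------------------
# 5-s decay


def simulate_decay_sweep(
    p: GatingParams,
    cell: CellModel,
    *,
    sampling_rate_hz: float = 10_000.0,
    duration_ms: float = 5000.0,
):
    vmax = voltage_of_peak_current(p)
    proto = protocols.build_inact5s_protocol(
        vmax, duration_ms=duration_ms, sampling_rate_hz=sampling_rate_hz
    )
    sw = simulate_sweep(proto, p, cell)
    if cell.leak_conductance_nS > 0:
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # single-voltage baseline is expected
            sw = preprocess.offline_linear_subtract(
                sw, (0.0, sw.metadata["pulse_window_ms"][0])
            )
    return sw


def run_decay(
    p: GatingParams, cell: CellModel, model: str = "auto", **kwargs
) -> curves.DecayFit:
    return curves.fit_decay_sweep(simulate_decay_sweep(p, cell, **kwargs), model=model)


# ---------------------------------------------------------------------------
# recovery from inactivation


def simulate_recovery_bundle(
    p: GatingParams,
    cell: CellModel,
    *,
    gaps_s: list[float] | None = None,
) -> SweepBundle:
    vmax = voltage_of_peak_current(p)
    family = protocols.build_recovery_family(vmax_mV=vmax, gaps_s=gaps_s)
    return simulate_family(family, p, cell)


def recovery_fractions(
    bundle: SweepBundle, *, settle_ms: float = 8.0
) -> tuple[np.ndarray, np.ndarray]:
    """(gap s, test-pulse peak / prepulse peak) per sweep.

    Peak windows start ``settle_ms`` into each pulse so that, at the shortest
    gaps, channels still activated (not yet deactivated at the holding
    potential) do not inflate the test-pulse peak.
    """
    gaps, frac = [], []
    for sw in bundle:
        p0, p1 = sw.metadata["prepulse_window_ms"]
        t0, t1 = sw.metadata["test_window_ms"]
        pre = preprocess.peak_current(sw, (p0 + settle_ms, p1))
        test = preprocess.peak_current(sw, (t0 + settle_ms, t1))
        gaps.append(sw.metadata["gap_s"])
        frac.append(test.amplitude_pA / pre.amplitude_pA)
    return np.asarray(gaps), np.asarray(frac)


def run_recovery(p: GatingParams, cell: CellModel, **kwargs) -> curves.RecoveryFit:
    gaps, frac = recovery_fractions(simulate_recovery_bundle(p, cell, **kwargs))
    return curves.fit_recovery(gaps, frac)


# ---------------------------------------------------------------------------
# tails


def simulate_tail_bundle(p: GatingParams, cell: CellModel, **kwargs) -> SweepBundle:
    family = protocols.build_tail_family(vrev_mV=p.vrev_mV, **kwargs)
    rng = np.random.default_rng(cell.seed)
    sweeps = []
    for i, proto in enumerate(family.sweeps):
        sw = simulate_sweep(proto, p, cell, rng=rng)
        leak_protos = protocols.p4_leak_pulses(proto)
        leaks = [simulate_sweep(lp, p, cell, rng=rng) for lp in leak_protos.sweeps]
        sw = preprocess.p4_subtract(sw, leaks)
        sw.metadata["sweep_index"] = i
        sweeps.append(sw)
    return SweepBundle(sweeps=sweeps, family_kind="TAIL", metadata={"channel": p.label})


# ---------------------------------------------------------------------------
# pharmacology


def run_pharmacology(
    p: GatingParams,
    cell: CellModel,
    drug: DrugModel,
    *,
    test_concentrations_nM: tuple[float, ...] = (30.0, 300.0),
    full_block_nM: float = 3000.0,
    n_control: int = 6,
    n_per_conc: int = 12,
) -> curves.DoseResponseFit:
    """Full drug assay: control run-down run, drug run, correction, Hill fit.

    Mirrors the experimental design: a drug-free control run measured in the
    same conditions provides the linear run-down regression, which is then
    subtracted from the drug run's inhibition time course; steady-state
    inhibition per concentration (mean of the last 3 sweeps) plus the full
    block reference feed the fixed-slope Hill fit.
    """
    total = n_control + n_per_conc * (len(test_concentrations_nM) + 1)
    control_schedule = [0.0] * total
    ctrl_bundle = simulate_pharmacology_run(p, cell, None, control_schedule)
    t_c, peaks_c = preprocess.bundle_peaks(ctrl_bundle)
    rundown = preprocess.fit_rundown(t_c, peaks_c)

    schedule = [0.0] * n_control
    for c in (*test_concentrations_nM, full_block_nM):
        schedule += [c] * n_per_conc
    drug_bundle = simulate_pharmacology_run(p, cell, drug, schedule)
    t_d, peaks_d = preprocess.bundle_peaks(drug_bundle)
    inhibition = preprocess.rundown_correct(t_d, peaks_d, rundown)
    ss = preprocess.steady_state_inhibition(t_d, inhibition, schedule)
    conc = np.array(sorted(ss))
    inh = np.array([ss[c] for c in conc])
    return curves.fit_dose_response(conc, inh)
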