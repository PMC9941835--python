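"""Hodgkin-Huxley-style generator of whole-cell Cav1.3 current sweeps.

The channel is modelled with independent first-order gates: one activation
gate ``m`` and two inactivation gates ``h_fast``/``h_slow`` with fixed
fractional amplitudes plus a non-inactivating plateau,

    I(t) = Gmax * (V - Vrev) * m(t) * [f_ni + A_f*h_f(t) + A_s*h_s(t)],

with a linear ohmic driving force. This is the smallest gate structure whose
output the empirical analysis pipeline (Boltzmann I-V fit, modified-Boltzmann
availability fit, mono/bi-exponential decay, double-exponential recovery) can
invert back to its generating parameters.

Voltage dependences:

* ``m`` relaxes toward a Boltzmann steady state with a bell-shaped (Gaussian
  in V) activation time constant; at repolarized voltages the time constant
  crosses over smoothly to a deactivation branch anchored at -69 mV with a
  mild exponential voltage dependence.
* each ``h`` gate relaxes toward the availability steady state with time
  constants interpolated logistically (centered at -50 mV) between the
  depolarized decay values and the recovery values at the holding potential.

On top of the channel current the cell model adds ohmic leak (reversal
0 mV), additive Gaussian current noise, and a linear sweep-to-sweep
run-down in percent of the initial peak per minute. An optional "hook"
mechanism (a pool of channels blocked during depolarization that re-enter
the open state on repolarization with time constant tau_unblock) reproduces
a delayed tail-current peak.

All simulation is exact per constant-voltage segment: first-order gates are
propagated analytically sample-by-sample, so traces are deterministic given
the seed and free of ODE-solver error.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

from .protocols import ProtocolFamily, SweepProtocol

__all__ = [
    "TauActivation",
    "HookModel",
    "GatingParams",
    "CellModel",
    "DrugModel",
    "steady_state_activation",
    "steady_state_availability",
    "tau_activation",
    "tau_inactivation_fast",
    "tau_inactivation_slow",
    "simulate_sweep",
    "simulate_family",
    "simulate_pharmacology_run",
    "voltage_of_peak_current",
]


@dataclass(frozen=True)
class TauActivation:
    """Bell-shaped activation time constant: Gaussian in voltage with a floor.

    The voltage-clamp data constrain activation only to be fast relative to
    the 25-ms test pulse, so the default peaks at 2 ms near -20 mV.
    """

    tau_peak_ms: float = 2.0
    v_peak_mV: float = -20.0
    sigma_mV: float = 30.0
    floor_ms: float = 0.3


@dataclass(frozen=True)
class HookModel:
    """Optional blocked-open pool producing a delayed tail-current peak.

    A fraction of conducting channels is occluded during depolarization and
    re-opens with ``tau_unblock_ms`` after repolarization, so the tail current
    transiently grows before deactivation takes over ("hook").
    """

    enabled: bool = False
    tau_unblock_ms: float = 1.5
    blocked_frac: float = 0.4


@dataclass(frozen=True)
class GatingParams:
    """Full biophysical parameterization of one channel/beta-subunit combination."""

    label: str
    # activation
    v05_act_mV: float
    k_act_mV: float
    vrev_mV: float
    gmax_density_nS_per_pF: float
    tau_act: TauActivation = field(default_factory=TauActivation)
    # availability (steady-state inactivation)
    v05_inact_mV: float = -30.0
    k_inact_mV: float = 6.0
    frac_noninact: float = 0.2
    a_fast: float = 0.5
    a_slow: float = 0.3
    # kinetics
    tau_inact_fast_ms: float = 200.0
    tau_inact_slow_ms: float = 2000.0
    tau_rec_fast_ms: float = 70.0
    tau_rec_slow_ms: float = 5000.0
    # deactivation branch of tau_m, anchored at -69 mV
    tau_deact_ref_ms: float = 1.0
    tau_deact_efold_mV: float = 25.0
    hook: HookModel = field(default_factory=HookModel)

    def __post_init__(self) -> None:
        if self.k_act_mV <= 0 or self.k_inact_mV <= 0:
            raise ValueError("Boltzmann slope factors must be > 0")
        for name in (
            "tau_inact_fast_ms",
            "tau_inact_slow_ms",
            "tau_rec_fast_ms",
            "tau_rec_slow_ms",
            "tau_deact_ref_ms",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.gmax_density_nS_per_pF < 0:
            raise ValueError("Gmax density must be >= 0")
        for name in ("frac_noninact", "a_fast", "a_slow"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        total = self.a_fast + self.a_slow + self.frac_noninact
        if abs(total - 1.0) > 1e-9:
            raise ValueError(
                f"a_fast + a_slow + frac_noninact must equal 1, got {total!r}"
            )


@dataclass(frozen=True)
class CellModel:
    """Recording-cell model: size, passive leak, noise, and run-down."""

    capacitance_pF: float = 20.0
    leak_conductance_nS: float = 1.5
    noise_sd_pA: float = 0.0
    rundown_slope_pct_per_min: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.capacitance_pF <= 0:
            raise ValueError("capacitance must be > 0")
        if self.noise_sd_pA < 0:
            raise ValueError("noise SD must be >= 0")
        if self.leak_conductance_nS < 0:
            raise ValueError("leak conductance must be >= 0")


@dataclass(frozen=True)
class DrugModel:
    """Hill-type (slope 1) open-channel blocker with first-order wash-in."""

    ic50_nM: float
    hill_slope: float = 1.0
    equilibration_tau_s: float = 15.0

    def __post_init__(self) -> None:
        if self.ic50_nM <= 0:
            raise ValueError("IC50 must be > 0")
        if self.equilibration_tau_s <= 0:
            raise ValueError("equilibration tau must be > 0")

    def equilibrium_block(self, conc_nM: float) -> float:
        """Fractional block at equilibrium, Hill slope 1: c / (c + IC50)."""
        if conc_nM < 0:
            raise ValueError("concentration must be >= 0")
        return conc_nM / (conc_nM + self.ic50_nM)


# ---------------------------------------------------------------------------
# steady states and time constants


def steady_state_activation(V_mV, p: GatingParams):
    """Boltzmann activation curve m_inf(V) = 1/(1+exp(-(V-V0.5)/k))."""
    return expit((np.asarray(V_mV, dtype=float) - p.v05_act_mV) / p.k_act_mV)


def steady_state_availability(V_mV, p: GatingParams):
    """Modified Boltzmann availability with a non-inactivating plateau.

    h_inf(V) = f_ni + (1 - f_ni) / (1 + exp((V - V0.5,inact)/k_inact)).
    """
    s = expit(-(np.asarray(V_mV, dtype=float) - p.v05_inact_mV) / p.k_inact_mV)
    return p.frac_noninact + (1.0 - p.frac_noninact) * s


def _gate_availability(V_mV, p: GatingParams):
    """Per-gate steady state (no plateau): each h gate relaxes toward this."""
    return expit(-(np.asarray(V_mV, dtype=float) - p.v05_inact_mV) / p.k_inact_mV)


def tau_activation(V_mV, p: GatingParams):
    """Activation/deactivation time constant of the m gate, in ms."""
    V = np.asarray(V_mV, dtype=float)
    ta = p.tau_act
    bell = ta.floor_ms + (ta.tau_peak_ms - ta.floor_ms) * np.exp(
        -(((V - ta.v_peak_mV) / ta.sigma_mV) ** 2)
    )
    deact = p.tau_deact_ref_ms * np.exp((V + 69.0) / p.tau_deact_efold_mV)
    # crossover from the deactivation to the activation branch sits below the
    # activation range of both channel variants, so test-pulse kinetics stay
    # fast (quasi-steady within 25 ms) while repolarization tails deactivate
    # with the reference time constant
    w = expit((V + 60.0) / 5.0)
    return w * bell + (1.0 - w) * deact


def _tau_h(V_mV, tau_dep_ms: float, tau_rec_ms: float):
    """Logistic interpolation (centered -50 mV) between decay and recovery tau."""
    w = expit((np.asarray(V_mV, dtype=float) + 50.0) / 5.0)
    return w * tau_dep_ms + (1.0 - w) * tau_rec_ms


def tau_inactivation_fast(V_mV, p: GatingParams):
    return _tau_h(V_mV, p.tau_inact_fast_ms, p.tau_rec_fast_ms)


def tau_inactivation_slow(V_mV, p: GatingParams):
    return _tau_h(V_mV, p.tau_inact_slow_ms, p.tau_rec_slow_ms)


def voltage_of_peak_current(p: GatingParams, v_lo: float = -80.0, v_hi: float = 40.0):
    """Vmax: test potential of maximal inward current, from the steady-state
    I-V shape (V - Vrev) * m_inf(V) on a fine grid."""
    grid = np.arange(v_lo, v_hi + 0.01, 0.1)
    drive = (grid - p.vrev_mV) * steady_state_activation(grid, p)
    return float(grid[np.argmin(drive)])


# ---------------------------------------------------------------------------
# sweep simulation


def _hook_target_tau(V_mV: float, p: GatingParams) -> tuple[float, float]:
    """Blocked-pool occupancy target and time constant at voltage V."""
    occ = p.hook.blocked_frac * float(expit((V_mV + 30.0) / 5.0))
    w = float(expit((V_mV + 60.0) / 5.0))
    tau = w * 1.0 + (1.0 - w) * p.hook.tau_unblock_ms
    return occ, tau


def simulate_sweep(
    protocol: SweepProtocol,
    p: GatingParams,
    cell: CellModel,
    *,
    gmax_scale: float = 1.0,
    include_leak: bool = True,
    rng: np.random.Generator | None = None,
):
    """Simulate one whole-cell current sweep for a square-segment protocol.

    Gates start at equilibrium for the first segment's voltage (the holding
    potential). Returns a :class:`cavclamp.preprocess.Sweep` with current in
    pA; deterministic for a fixed cell seed.
    """
    from .preprocess import Sweep  # local import to avoid a cycle

    counts = protocol.segment_samples()
    dt = protocol.dt_ms
    n_total = sum(counts)
    current = np.empty(n_total)
    vcmd = np.empty(n_total)

    v0 = protocol.segments[0].voltage_mV
    m = float(steady_state_activation(v0, p))
    hf = float(_gate_availability(v0, p))
    hs = hf
    b = _hook_target_tau(v0, p)[0] if p.hook.enabled else 0.0

    gmax_pA_per_mV = p.gmax_density_nS_per_pF * cell.capacitance_pF * gmax_scale

    pos = 0
    for seg, n in zip(protocol.segments, counts):
        V = seg.voltage_mV
        if not math.isfinite(V):
            raise ValueError("non-finite segment voltage")
        t_local = np.arange(1, n + 1) * dt

        m_inf = float(steady_state_activation(V, p))
        tm = float(tau_activation(V, p))
        m_t = m_inf + (m - m_inf) * np.exp(-t_local / tm)

        h_inf = float(_gate_availability(V, p))
        tf = float(_tau_h(V, p.tau_inact_fast_ms, p.tau_rec_fast_ms))
        ts = float(_tau_h(V, p.tau_inact_slow_ms, p.tau_rec_slow_ms))
        hf_t = h_inf + (hf - h_inf) * np.exp(-t_local / tf)
        hs_t = h_inf + (hs - h_inf) * np.exp(-t_local / ts)

        if p.hook.enabled:
            b_inf, tb = _hook_target_tau(V, p)
            b_t = b_inf + (b - b_inf) * np.exp(-t_local / tb)
            b = float(b_t[-1])
        else:
            b_t = 0.0

        h_total = p.frac_noninact + p.a_fast * hf_t + p.a_slow * hs_t
        current[pos : pos + n] = gmax_pA_per_mV * (V - p.vrev_mV) * m_t * h_total * (
            1.0 - b_t
        )
        vcmd[pos : pos + n] = V

        m, hf, hs = float(m_t[-1]), float(hf_t[-1]), float(hs_t[-1])
        pos += n

    if include_leak and cell.leak_conductance_nS > 0:
        current += cell.leak_conductance_nS * vcmd  # ohmic, reversal 0 mV

    if cell.noise_sd_pA > 0:
        if rng is None:
            rng = np.random.default_rng(cell.seed)
        current += rng.normal(0.0, cell.noise_sd_pA, size=n_total)

    t = np.arange(n_total) * dt
    meta = {"label": protocol.label, **protocol.meta}
    # annotate analysis windows for every '<name>_segment' index in the meta
    for key, idx in list(protocol.meta.items()):
        if key.endswith("_segment") and isinstance(idx, int):
            meta[key.replace("_segment", "_window_ms")] = protocol.segment_window_ms(idx)
    return Sweep(
        time_ms=t,
        current_pA=current,
        v_command_mV=vcmd,
        sampling_rate_hz=protocol.sampling_rate_hz,
        capacitance_pF=cell.capacitance_pF,
        metadata=meta,
    )


def simulate_family(
    family: ProtocolFamily,
    p: GatingParams,
    cell: CellModel,
    *,
    include_leak: bool = True,
):
    """Simulate every sweep of a protocol family into a SweepBundle.

    A single generator seeded from the cell model drives the noise of all
    sweeps, so the bundle is reproducible as a whole.
    """
    from .preprocess import SweepBundle

    rng = np.random.default_rng(cell.seed)
    sweeps = []
    for i, proto in enumerate(family.sweeps):
        sw = simulate_sweep(proto, p, cell, include_leak=include_leak, rng=rng)
        sw.metadata["sweep_index"] = i
        sw.metadata["t_start_s"] = i * proto.inter_sweep_interval_s
        sweeps.append(sw)
    return SweepBundle(
        sweeps=sweeps,
        family_kind=family.family_kind,
        metadata={"channel": p.label, "varied": family.varied},
    )


def simulate_pharmacology_run(
    p: GatingParams,
    cell: CellModel,
    drug: DrugModel | None,
    schedule_nM: list[float],
    *,
    vmax_mV: float | None = None,
    include_leak: bool = False,
):
    """Repeated 100-ms pulses at 0.1 Hz under a per-sweep concentration schedule.

    Fractional block relaxes first-order toward the Hill equilibrium
    c/(c+IC50) with the drug's equilibration time constant; peaks are
    additionally scaled by the cell's linear run-down (percent of the initial
    amplitude per minute). ``schedule_nM[i]`` is the bath concentration during
    sweep i; use 0 throughout for a drug-free control run.
    """
    from .preprocess import SweepBundle
    from .protocols import build_pharm_protocol

    if any(c < 0 for c in schedule_nM):
        raise ValueError("concentrations must be >= 0")
    if vmax_mV is None:
        vmax_mV = voltage_of_peak_current(p)
    proto = build_pharm_protocol(vmax_mV)
    interval_s = proto.inter_sweep_interval_s

    rng = np.random.default_rng(cell.seed)
    block = 0.0
    sweeps = []
    for i, conc in enumerate(schedule_nM):
        t_s = i * interval_s
        if drug is not None:
            target = drug.equilibrium_block(conc)
            # first-order relaxation over one inter-sweep interval
            step = math.exp(-interval_s / drug.equilibration_tau_s)
            if i > 0:
                block = target + (block - target) * step
            else:
                block = target * (1.0 - step)
        rundown = 1.0 + cell.rundown_slope_pct_per_min / 100.0 * (t_s / 60.0)
        rundown = max(rundown, 0.0)
        scale = rundown * (1.0 - block)
        sw = simulate_sweep(
            proto, p, cell, gmax_scale=scale, include_leak=include_leak, rng=rng
        )
        sw.metadata.update(
            {
                "sweep_index": i,
                "t_start_s": t_s,
                "concentration_nM": conc,
                "true_block_frac": block,
            }
        )
        sweeps.append(sw)
    return SweepBundle(
        sweeps=sweeps,
        family_kind="PHARM",
        metadata={"channel": p.label, "vmax_mV": vmax_mV},
    )
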