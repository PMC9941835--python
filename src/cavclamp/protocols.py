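"""Voltage-command protocols for whole-cell Ca2+ current recordings.

Square-segment command waveforms for the six protocol families used to
characterize L-type channel gating: current-voltage (I-V) relationships,
two-pulse steady-state inactivation (SSI), 5-s inactivation time course,
recovery from inactivation, tail currents, and repeated-pulse pharmacology.

All voltages handled here are liquid-junction-potential (LJP) corrected
membrane voltages; builders default to the corrected holding potential of
-89 mV. Protocols assembled from raw command voltages can be corrected once
with :func:`correct_protocol_junction`, which sets a bookkeeping flag so the
-9.3 mV shift can never be applied twice.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

#: Liquid junction potential of the Cs-chloride pipette / choline-chloride
#: bath solution pair, in mV. Corrected voltage = command voltage - 9.3 mV.
JUNCTION_POTENTIAL_MV = -9.3

#: Holding potential (mV, LJP-corrected).
HOLDING_POTENTIAL_MV = -89.0

DEFAULT_SAMPLING_RATE_HZ = 50_000.0


class ProtocolError(ValueError):
    """Invalid protocol construction or use."""


@dataclass(frozen=True)
class Segment:
    """One constant-voltage command segment."""

    duration_ms: float
    voltage_mV: float

    def __post_init__(self) -> None:
        if not (self.duration_ms > 0):
            raise ProtocolError(f"segment duration must be > 0 ms, got {self.duration_ms}")
        if not math.isfinite(self.voltage_mV):
            raise ProtocolError(f"segment voltage must be finite, got {self.voltage_mV}")


@dataclass(frozen=True)
class SweepProtocol:
    """An ordered list of square command segments plus acquisition metadata.

    ``meta`` carries builder-specific annotations (test voltage, conditioning
    voltage, recovery gap, indices of the segments to analyze) used by the
    downstream analysis operations.
    """

    segments: tuple[Segment, ...]
    sampling_rate_hz: float = DEFAULT_SAMPLING_RATE_HZ
    inter_sweep_interval_s: float = 5.0
    label: str = ""
    jp_corrected: bool = True
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.segments:
            raise ProtocolError("protocol needs at least one segment")
        if not (self.sampling_rate_hz > 0):
            raise ProtocolError("sampling rate must be > 0")
        dt_ms = 1000.0 / self.sampling_rate_hz
        for i, seg in enumerate(self.segments):
            n = seg.duration_ms / dt_ms
            # Segment boundaries must land on the sample grid within half a
            # sample, and every segment must contain at least one sample.
            if round(n) < 1:
                raise ProtocolError(
                    f"segment {i} duration {seg.duration_ms} ms is shorter than "
                    f"one sample at {self.sampling_rate_hz} Hz"
                )
            if abs(n - round(n)) > 0.5:
                raise ProtocolError(
                    f"segment {i} duration {seg.duration_ms} ms does not align "
                    f"to the {dt_ms} ms sample grid"
                )

    @property
    def dt_ms(self) -> float:
        return 1000.0 / self.sampling_rate_hz

    @property
    def total_duration_ms(self) -> float:
        return sum(s.duration_ms for s in self.segments)

    @property
    def n_samples(self) -> int:
        return sum(int(round(s.duration_ms / self.dt_ms)) for s in self.segments)

    def segment_samples(self) -> list[int]:
        """Sample count of each segment (durations align to the grid)."""
        return [int(round(s.duration_ms / self.dt_ms)) for s in self.segments]

    def segment_window_ms(self, index: int) -> tuple[float, float]:
        """(start, end) time in ms of segment ``index`` on the sweep clock."""
        start = sum(s.duration_ms for s in self.segments[:index])
        return start, start + self.segments[index].duration_ms

    def command_waveform(self) -> tuple[np.ndarray, np.ndarray]:
        """Return (t_ms, V_mV) sampled arrays of the command voltage."""
        counts = self.segment_samples()
        v = np.concatenate(
            [np.full(n, s.voltage_mV) for n, s in zip(counts, self.segments)]
        )
        t = np.arange(v.size) * self.dt_ms
        return t, v


@dataclass(frozen=True)
class ProtocolFamily:
    """A family of sweeps sharing structure, varying one quantity."""

    sweeps: tuple[SweepProtocol, ...]
    family_kind: str  # IV | SSI | INACT5S | RECOVERY | TAIL | PHARM
    varied: str = ""

    def __post_init__(self) -> None:
        if not self.sweeps:
            raise ProtocolError("protocol family must be non-empty")
        rates = {s.sampling_rate_hz for s in self.sweeps}
        if len(rates) != 1:
            raise ProtocolError("family sweeps must share one sampling rate")
        vals = self.varied_values()
        if vals is not None and len(vals) > 1:
            diffs = np.diff(vals)
            if not (np.all(diffs > 0) or np.all(diffs < 0)):
                raise ProtocolError(f"family varied quantity '{self.varied}' not monotone")

    def varied_values(self):
        if not self.varied:
            return None
        return [s.meta.get(self.varied) for s in self.sweeps]

    def __len__(self) -> int:
        return len(self.sweeps)


def junction_correct(v_command_mV: float) -> float:
    """Convert a raw command voltage to the LJP-corrected membrane voltage."""
    if not math.isfinite(v_command_mV):
        raise ProtocolError("voltage must be finite")
    return v_command_mV + JUNCTION_POTENTIAL_MV


def correct_protocol_junction(protocol: SweepProtocol) -> SweepProtocol:
    """Apply the LJP correction once to every segment of a raw protocol.

    Raises if the protocol is already flagged as corrected, guarding against
    accidental double correction.
    """
    if protocol.jp_corrected:
        raise ProtocolError(
            f"protocol '{protocol.label}' is already junction-corrected"
        )
    segs = tuple(
        replace(s, voltage_mV=junction_correct(s.voltage_mV)) for s in protocol.segments
    )
    return replace(protocol, segments=segs, jp_corrected=True)


def _voltage_ladder(v_start: float, v_stop: float, step: float) -> list[float]:
    if step <= 0:
        raise ProtocolError("step must be > 0")
    if v_stop < v_start:
        raise ProtocolError("v_stop must be >= v_start")
    n = int(math.floor((v_stop - v_start) / step + 1e-9)) + 1
    volts = [v_start + i * step for i in range(n)]
    if volts[-1] < v_stop - 1e-9:
        warnings.warn(
            f"step {step} mV does not divide the range; last pulse clipped to {v_stop} mV",
            stacklevel=3,
        )
        volts.append(v_stop)
    return volts


def build_iv_family(
    hp_mV: float = HOLDING_POTENTIAL_MV,
    v_start_mV: float = -84.0,
    v_stop_mV: float = 61.0,
    step_mV: float = 5.0,
    pulse_ms: float = 25.0,
    pre_ms: float = 5.0,
    post_ms: float = 10.0,
    sampling_rate_hz: float = DEFAULT_SAMPLING_RATE_HZ,
) -> ProtocolFamily:
    """25-ms square depolarizations from the holding potential in 5-mV steps.

    The default -84..+61 mV grid spans the activation range of both wild-type
    and gain-of-function channels on the 5-mV post-correction grid.
    """
    sweeps = []
    for v in _voltage_ladder(v_start_mV, v_stop_mV, step_mV):
        sweeps.append(
            SweepProtocol(
                segments=(
                    Segment(pre_ms, hp_mV),
                    Segment(pulse_ms, v),
                    Segment(post_ms, hp_mV),
                ),
                sampling_rate_hz=sampling_rate_hz,
                inter_sweep_interval_s=5.0,
                label=f"IV_{v:+.0f}mV",
                meta={"kind": "IV", "test_voltage_mV": v, "pulse_segment": 1},
            )
        )
    return ProtocolFamily(tuple(sweeps), "IV", varied="test_voltage_mV")


def build_ssi_family(
    vmax_mV: float,
    hp_mV: float = HOLDING_POTENTIAL_MV,
    control_pulse_ms: float = 25.0,
    cond_duration_ms: float = 5000.0,
    cond_start_mV: float = -109.0,
    cond_stop_mV: float = 21.0,
    step_mV: float = 10.0,
    gap_ms: float = 100.0,
    sampling_rate_hz: float = DEFAULT_SAMPLING_RATE_HZ,
) -> ProtocolFamily:
    """Two-pulse steady-state inactivation: control pulse, 5-s conditioning
    step (10-mV increments), test pulse; 30 s between sweep starts.

    Availability is the test/control peak ratio per conditioning voltage.
    """
    if not (20.0 <= control_pulse_ms <= 75.0):
        raise ProtocolError(
            f"control pulse must lie within 20-75 ms, got {control_pulse_ms}"
        )
    sweeps = []
    for vc in _voltage_ladder(cond_start_mV, cond_stop_mV, step_mV):
        sweeps.append(
            SweepProtocol(
                segments=(
                    Segment(5.0, hp_mV),
                    Segment(control_pulse_ms, vmax_mV),
                    Segment(gap_ms, hp_mV),
                    Segment(cond_duration_ms, vc),
                    Segment(control_pulse_ms, vmax_mV),
                    Segment(10.0, hp_mV),
                ),
                sampling_rate_hz=sampling_rate_hz,
                inter_sweep_interval_s=30.0,
                label=f"SSI_{vc:+.0f}mV",
                meta={
                    "kind": "SSI",
                    "cond_voltage_mV": vc,
                    "control_segment": 1,
                    "test_segment": 4,
                },
            )
        )
    return ProtocolFamily(tuple(sweeps), "SSI", varied="cond_voltage_mV")


def default_recovery_gaps_s(n: int = 15) -> list[float]:
    """Logarithmic recovery-gap ladder over 0.001-20 s."""
    return list(np.logspace(math.log10(0.001), math.log10(20.0), n))


def build_recovery_family(
    vmax_mV: float,
    hp_mV: float = HOLDING_POTENTIAL_MV,
    prepulse_ms: float = 2000.0,
    gaps_s: list[float] | None = None,
    test_ms: float = 25.0,
    sampling_rate_hz: float = 10_000.0,
) -> ProtocolFamily:
    """Two-pulse recovery from inactivation: 2-s conditioning pulse, variable
    gap at the holding potential (0.001-20 s), 25-ms test pulse; 10 kHz.
    """
    if gaps_s is None:
        gaps_s = default_recovery_gaps_s()
    dt_ms = 1000.0 / sampling_rate_hz
    sweeps = []
    for gap in sorted(gaps_s):
        if not (0.001 - 1e-12 <= gap <= 20.0 + 1e-12):
            raise ProtocolError(f"recovery gap {gap} s outside 0.001-20 s")
        gap_ms = max(dt_ms, round(gap * 1000.0 / dt_ms) * dt_ms)
        sweeps.append(
            SweepProtocol(
                segments=(
                    Segment(5.0, hp_mV),
                    Segment(prepulse_ms, vmax_mV),
                    Segment(gap_ms, hp_mV),
                    Segment(test_ms, vmax_mV),
                    Segment(10.0, hp_mV),
                ),
                sampling_rate_hz=sampling_rate_hz,
                inter_sweep_interval_s=30.0,
                label=f"REC_{gap:.4g}s",
                meta={
                    "kind": "RECOVERY",
                    "gap_s": gap_ms / 1000.0,
                    "prepulse_segment": 1,
                    "test_segment": 3,
                },
            )
        )
    return ProtocolFamily(tuple(sweeps), "RECOVERY", varied="gap_s")


def build_tail_family(
    vrev_mV: float,
    hp_mV: float = HOLDING_POTENTIAL_MV,
    pre_ms: float = 10.0,
    repol_ms: float = 20.0,
    repol_voltages_mV: list[float] | None = None,
    sampling_rate_hz: float = DEFAULT_SAMPLING_RATE_HZ,
) -> ProtocolFamily:
    """Tail currents: 10-ms step to the reversal potential, then 20-ms
    repolarizations to various voltages (default ladder includes -69 and
    -49 mV, the voltages used to quantify deactivation).
    """
    if repol_ms <= 0:
        raise ProtocolError("repolarization must be > 0 ms")
    if repol_voltages_mV is None:
        repol_voltages_mV = [-89.0, -79.0, -69.0, -59.0, -49.0, -39.0]
    if not repol_voltages_mV:
        raise ProtocolError("empty repolarization voltage list")
    sweeps = []
    for v in sorted(repol_voltages_mV):
        sweeps.append(
            SweepProtocol(
                segments=(
                    Segment(5.0, hp_mV),
                    Segment(pre_ms, vrev_mV),
                    Segment(repol_ms, v),
                    Segment(5.0, hp_mV),
                ),
                sampling_rate_hz=sampling_rate_hz,
                inter_sweep_interval_s=5.0,
                label=f"TAIL_{v:+.0f}mV",
                meta={
                    "kind": "TAIL",
                    "repol_voltage_mV": v,
                    "pre_segment": 1,
                    "repol_segment": 2,
                },
            )
        )
    return ProtocolFamily(tuple(sweeps), "TAIL", varied="repol_voltage_mV")


def build_pharm_protocol(
    vmax_mV: float,
    hp_mV: float = HOLDING_POTENTIAL_MV,
    pulse_ms: float = 100.0,
    freq_hz: float = 0.1,
    sampling_rate_hz: float = DEFAULT_SAMPLING_RATE_HZ,
) -> SweepProtocol:
    """100-ms square pulse to Vmax repeated at 0.1 Hz (drug-block assays)."""
    if freq_hz <= 0:
        raise ProtocolError("pulse frequency must be > 0")
    return SweepProtocol(
        segments=(Segment(5.0, hp_mV), Segment(pulse_ms, vmax_mV), Segment(20.0, hp_mV)),
        sampling_rate_hz=sampling_rate_hz,
        inter_sweep_interval_s=1.0 / freq_hz,
        label="PHARM",
        meta={"kind": "PHARM", "pulse_segment": 1, "test_voltage_mV": vmax_mV},
    )


def build_inact5s_protocol(
    v_mV: float,
    hp_mV: float = HOLDING_POTENTIAL_MV,
    duration_ms: float = 5000.0,
    sampling_rate_hz: float = DEFAULT_SAMPLING_RATE_HZ,
) -> SweepProtocol:
    """5-s depolarization to Vmax for the inactivation time course."""
    return SweepProtocol(
        segments=(Segment(5.0, hp_mV), Segment(duration_ms, v_mV), Segment(10.0, hp_mV)),
        sampling_rate_hz=sampling_rate_hz,
        inter_sweep_interval_s=30.0,
        label="INACT5S",
        meta={"kind": "INACT5S", "pulse_segment": 1, "test_voltage_mV": v_mV},
    )


def p4_leak_pulses(test: SweepProtocol) -> ProtocolFamily:
    """Build the four P/4 leak sub-sweeps for a single-pulse test protocol.

    Each sub-sweep repeats the test sweep's timing with every voltage
    excursion from the holding level scaled by -1/4, so that the summed
    linear (ohmic) responses of the four sub-sweeps cancel the leak of the
    test pulse exactly.
    """
    hp = test.segments[0].voltage_mV
    excursion_idx = [
        i for i, s in enumerate(test.segments) if abs(s.voltage_mV - hp) > 1e-12
    ]
    if excursion_idx and excursion_idx != list(
        range(excursion_idx[0], excursion_idx[-1] + 1)
    ):
        raise ProtocolError(
            "P/4 requires a single contiguous test-pulse block, not multiple pulses"
        )
    sweeps = []
    for k in range(4):
        segs = tuple(
            replace(s, voltage_mV=hp - (s.voltage_mV - hp) / 4.0) for s in test.segments
        )
        sweeps.append(
            replace(
                test,
                segments=segs,
                label=f"{test.label}_P4_{k}",
                meta={**test.meta, "kind": "P4", "p4_index": k},
            )
        )
    return ProtocolFamily(tuple(sweeps), "P4")
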