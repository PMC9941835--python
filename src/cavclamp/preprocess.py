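"""Sweep containers, leak subtraction, peak extraction and run-down handling.

Sign conventions: inward Ca2+ currents are negative; every "% of peak"
quantity is computed on current magnitudes, matching current-density plots
with downward peaks. Run-down is expressed in percent of the initial peak
per minute, with the time base starting at the first control sweep.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sstats


class PreprocessError(ValueError):
    pass


@dataclass
class Sweep:
    """One recorded or simulated sweep: time, current, and command voltage."""

    time_ms: np.ndarray
    current_pA: np.ndarray
    v_command_mV: np.ndarray
    sampling_rate_hz: float
    capacitance_pF: float
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time_ms = np.asarray(self.time_ms, dtype=float)
        self.current_pA = np.asarray(self.current_pA, dtype=float)
        self.v_command_mV = np.asarray(self.v_command_mV, dtype=float)
        n = self.time_ms.size
        if self.current_pA.size != n or self.v_command_mV.size != n:
            raise PreprocessError("time, current and voltage arrays must be equal length")
        if n > 1 and not np.all(np.diff(self.time_ms) > 0):
            raise PreprocessError("time must be strictly increasing")

    def window_slice(self, window_ms: tuple[float, float]) -> slice:
        t0, t1 = window_ms
        i0 = int(np.searchsorted(self.time_ms, t0 - 1e-9))
        i1 = int(np.searchsorted(self.time_ms, t1 - 1e-9))
        if i1 <= i0:
            raise PreprocessError(f"empty window {window_ms}")
        return slice(i0, i1)


@dataclass
class SweepBundle:
    """An ordered family of sweeps sharing a protocol and sampling rate."""

    sweeps: list[Sweep]
    family_kind: str
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        rates = {s.sampling_rate_hz for s in self.sweeps}
        if len(rates) > 1:
            raise PreprocessError("bundle sweeps must share one sampling rate")

    def __len__(self) -> int:
        return len(self.sweeps)

    def __iter__(self):
        return iter(self.sweeps)


@dataclass(frozen=True)
class PeakResult:
    amplitude_pA: float
    density_pA_per_pF: float
    t_peak_ms: float


@dataclass(frozen=True)
class RundownFit:
    """Linear regression of normalized peak amplitude (%) vs time (min)."""

    slope_pct_per_min: float
    intercept_pct: float
    stderr_slope: float
    n: int

    def predicted_pct(self, t_min):
        return self.intercept_pct + self.slope_pct_per_min * np.asarray(t_min, float)


def p4_subtract(test: Sweep, leak_sweeps: list[Sweep]) -> Sweep:
    """Online P/4 leak subtraction.

    Each of the four sub-sweeps carries the test waveform scaled by -1/4 from
    the holding level; after removing each sub-sweep's own holding baseline,
    their summed responses equal minus the linear leak of the test excursion.
    The corrected sweep is the test sweep plus that sum, re-baselined on its
    pre-pulse holding segment, so any ohmic component cancels exactly.
    """
    if len(leak_sweeps) != 4:
        raise PreprocessError("P/4 subtraction needs exactly 4 leak sub-sweeps")
    n = test.current_pA.size
    for ls in leak_sweeps:
        if ls.current_pA.size != n or ls.sampling_rate_hz != test.sampling_rate_hz:
            raise PreprocessError("leak sweeps misaligned with the test sweep")

    hp = test.v_command_mV[0]
    base_mask = np.abs(test.v_command_mV - hp) < 1e-9
    # holding samples before the first excursion
    first_exc = np.argmax(~base_mask) if not base_mask.all() else n
    if first_exc == 0:
        raise PreprocessError("test sweep must start at the holding potential")
    pre = slice(0, first_exc)

    corrected = test.current_pA.astype(float).copy()
    for ls in leak_sweeps:
        corrected += ls.current_pA - ls.current_pA[pre].mean()
    corrected -= corrected[pre].mean()
    return Sweep(
        time_ms=test.time_ms.copy(),
        current_pA=corrected,
        v_command_mV=test.v_command_mV.copy(),
        sampling_rate_hz=test.sampling_rate_hz,
        capacitance_pF=test.capacitance_pF,
        metadata={**test.metadata, "leak_subtracted": "P/4"},
    )


def offline_linear_subtract(sweep: Sweep, baseline_window_ms: tuple[float, float]) -> Sweep:
    """Offline leak subtraction from a holding-segment baseline window.

    Fits I = a + g*V over the baseline samples and subtracts the predicted
    linear leak from the whole sweep. When the window contains a single
    command voltage (the usual case for a holding segment) the fit is
    degenerate and the baseline mean is subtracted instead, with a warning.
    """
    sl = sweep.window_slice(baseline_window_ms)
    V = sweep.v_command_mV[sl]
    I = sweep.current_pA[sl]
    if np.ptp(V) < 1e-9:
        warnings.warn(
            "baseline window has a single command voltage; subtracting its mean only",
            stacklevel=2,
        )
        pred = np.full_like(sweep.current_pA, I.mean())
    else:
        g, a = np.polyfit(V, I, 1)
        pred = a + g * sweep.v_command_mV
    return Sweep(
        time_ms=sweep.time_ms.copy(),
        current_pA=sweep.current_pA - pred,
        v_command_mV=sweep.v_command_mV.copy(),
        sampling_rate_hz=sweep.sampling_rate_hz,
        capacitance_pF=sweep.capacitance_pF,
        metadata={**sweep.metadata, "leak_subtracted": "offline"},
    )


def peak_current(
    sweep: Sweep, window_ms: tuple[float, float], polarity: str = "inward"
) -> PeakResult:
    """Signed extremum of the current in a time window, plus its density.

    Inward peaks are negative; ``density`` normalizes to cell capacitance
    (pA/pF) and is therefore cell-size invariant. Polarity ``"absolute"``
    returns the signed extremum of largest magnitude, which I-V families
    need for test potentials beyond the reversal potential where the current
    turns outward.
    """
    sl = sweep.window_slice(window_ms)
    seg = sweep.current_pA[sl]
    if polarity == "inward":
        idx = int(np.argmin(seg))
    elif polarity == "outward":
        idx = int(np.argmax(seg))
    elif polarity == "absolute":
        idx = int(np.argmax(np.abs(seg)))
    else:
        raise PreprocessError(f"unknown polarity {polarity!r}")
    amp = float(seg[idx])
    return PeakResult(
        amplitude_pA=amp,
        density_pA_per_pF=amp / sweep.capacitance_pF,
        t_peak_ms=float(sweep.time_ms[sl][idx]),
    )


def fit_rundown(t_s, peaks_pA) -> RundownFit:
    """Ordinary least squares of normalized peak amplitude (%) vs time.

    Peaks are normalized to the first control sweep (100 %) on magnitudes;
    time is converted to minutes from the first sweep.
    """
    t = np.asarray(t_s, dtype=float)
    peaks = np.abs(np.asarray(peaks_pA, dtype=float))
    if t.size < 3:
        raise PreprocessError("run-down regression needs at least 3 control sweeps")
    if peaks[0] == 0:
        raise PreprocessError("first control peak is zero; cannot normalize")
    t_min = (t - t[0]) / 60.0
    pct = 100.0 * peaks / peaks[0]
    res = sstats.linregress(t_min, pct)
    return RundownFit(
        slope_pct_per_min=float(res.slope),
        intercept_pct=float(res.intercept),
        stderr_slope=float(res.stderr),
        n=t.size,
    )


def rundown_correct(
    t_s,
    peaks_pA,
    rundown: RundownFit,
    *,
    reference_peak_pA: float | None = None,
) -> np.ndarray:
    """Run-down-corrected fractional inhibition in percent.

    The drug-free peak expected at each time is extrapolated from the control
    run-down regression (anchored at the drug run's first drug-free peak, or
    at ``reference_peak_pA``); inhibition(t) = 100*(1 - peak(t)/predicted).
    Values are clipped to [0, 100] with a warning when more than two points
    clip.
    """
    t = np.asarray(t_s, dtype=float)
    peaks = np.abs(np.asarray(peaks_pA, dtype=float))
    ref = abs(reference_peak_pA) if reference_peak_pA is not None else peaks[0]
    t_min = (t - t[0]) / 60.0
    predicted = ref * rundown.predicted_pct(t_min) / rundown.intercept_pct
    if np.any(predicted <= 0):
        raise PreprocessError("predicted drug-free peak is <= 0 within the run")
    inhibition = 100.0 * (1.0 - peaks / predicted)
    clipped = np.sum((inhibition < 0) | (inhibition > 100))
    if clipped > 2:
        warnings.warn(f"{clipped} inhibition points clipped to [0, 100]", stacklevel=2)
    return np.clip(inhibition, 0.0, 100.0)


def bundle_peaks(
    bundle: SweepBundle, segment_key: str = "pulse_segment"
) -> tuple[np.ndarray, np.ndarray]:
    """(t_start_s, peak_pA) per sweep, peak taken over the pulse segment."""
    times, peaks = [], []
    for sw in bundle:
        window = sw.metadata.get("pulse_window_ms")
        if window is None:
            raise PreprocessError("sweep metadata lacks 'pulse_window_ms'")
        pk = peak_current(sw, tuple(window))
        times.append(sw.metadata.get("t_start_s", 0.0))
        peaks.append(pk.amplitude_pA)
    return np.asarray(times), np.asarray(peaks)


def steady_state_inhibition(
    t_s, inhibition_pct, concentrations_nM, *, n_last: int = 3
) -> dict[float, float]:
    """Steady-state inhibition per concentration: mean of the last ``n_last``
    sweeps at each non-zero concentration (the averaging rule is configurable
    because no canonical rule exists for "steady-state" in this assay)."""
    conc = np.asarray(concentrations_nM, dtype=float)
    inh = np.asarray(inhibition_pct, dtype=float)
    out: dict[float, float] = {}
    for c in sorted(set(conc[conc > 0])):
        idx = np.flatnonzero(conc == c)
        out[float(c)] = float(inh[idx[-n_last:]].mean())
    return out
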