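"""Curve fits and derived statistics for whole-cell Ca2+ current analysis.

Implements the complete empirical description of voltage-gated channel
gating used in whole-cell studies:

* Boltzmann-scaled linear I-V fit, I = Gmax*(V-Vrev)/(1+exp(-(V-V0.5)/k))
* Boltzmann conductance fit, G = Gmax/(1+exp(-(V-V0.5)/k))
* modified-Boltzmann steady-state inactivation with a non-inactivating
  plateau, I/Ictrl = Ini + (1-Ini)/(1+exp((V-V0.5,inact)/k))
* window-current profile (availability x peak current density per voltage)
* remaining-current fractions at prespecified times and mono/bi-exponential
  decay fits with extra-sum-of-squares model selection
* double-exponential recovery from inactivation
* tail-current deactivation (time constant, normalized 20-ms integral, and
  hook detection)
* Hill (slope 1) concentration-inhibition fit on log IC50.

All fits are derivative-based nonlinear least squares (scipy) with the
initialization and bounds documented per function; parameter standard errors
come from the Jacobian at the solution.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize
from scipy import stats as sstats

from .preprocess import Sweep, peak_current
from .stats import FTestResult, ess_f_test

TAU_BOUNDS_MS = (1.0, 60_000.0)
K_BOUNDS_MV = (0.5, 30.0)


class FitError(RuntimeError):
    pass


class DegenerateDataError(FitError):
    pass


# ---------------------------------------------------------------------------
# result containers


@dataclass
class ActivationFit:
    v05_act_mV: float
    k_act_mV: float
    vrev_mV: float
    gmax: float  # nS if fit on pA, nS/pF if fit on pA/pF
    ss_res: float
    n: int
    stderr: dict = field(default_factory=dict)
    flags: list = field(default_factory=list)

    @property
    def n_params(self) -> int:
        return 4


@dataclass
class InactivationFit:
    v05_inact_mV: float
    k_inact_mV: float
    frac_noninact: float
    ss_res: float
    n: int
    stderr: dict = field(default_factory=dict)
    flags: list = field(default_factory=list)

    def availability(self, V_mV):
        V = np.asarray(V_mV, dtype=float)
        return self.frac_noninact + (1.0 - self.frac_noninact) / (
            1.0 + np.exp((V - self.v05_inact_mV) / self.k_inact_mV)
        )


@dataclass
class DecayFit:
    model: str  # "mono" | "bi"
    a_fast_pct: float | None
    tau_fast_ms: float | None
    a_slow_pct: float
    tau_slow_ms: float
    plateau_pct: float
    ss_res: float
    n: int
    stderr: dict = field(default_factory=dict)
    flags: list = field(default_factory=list)
    f_test: FTestResult | None = None


@dataclass
class RecoveryFit:
    a_fast: float
    tau_fast_ms: float
    a_slow: float
    tau_slow_ms: float
    offset: float
    ss_res: float
    n: int
    stderr: dict = field(default_factory=dict)
    flags: list = field(default_factory=list)


@dataclass
class DoseResponseFit:
    ic50_nM: float
    log_ic50: float
    ci95_nM: tuple[float, float]
    ss_res: float
    n: int
    stderr_log_ic50: float = float("nan")
    flags: list = field(default_factory=list)


@dataclass(frozen=True)
class WindowPoint:
    V_mV: float
    density_pA_per_pF: float
    window_density_pA_per_pF: float


@dataclass
class TailResult:
    repol_voltage_mV: float
    tau_deact_ms: float
    normalized_integral_ms: float
    hook_present: bool
    hook_delay_ms: float


# ---------------------------------------------------------------------------
# helpers


def _curve_fit(model, x, y, p0, bounds, name: str):
    try:
        popt, pcov = optimize.curve_fit(
            model, x, y, p0=p0, bounds=bounds, maxfev=20000, xtol=1e-14, ftol=1e-14
        )
    except (RuntimeError, ValueError) as exc:
        raise FitError(f"{name} fit did not converge: {exc}") from exc
    resid = y - model(x, *popt)
    ss = float(resid @ resid)
    with np.errstate(invalid="ignore"):
        se = np.sqrt(np.diag(pcov))
    return popt, se, ss


def _half_crossing(x: np.ndarray, y: np.ndarray, level: float) -> float:
    """First linear-interpolated crossing of ``level`` in y(x)."""
    for i in range(len(y) - 1):
        y0, y1 = y[i], y[i + 1]
        if (y0 - level) * (y1 - level) <= 0 and y0 != y1:
            return float(x[i] + (level - y0) * (x[i + 1] - x[i]) / (y1 - y0))
    return float(x[np.argmin(np.abs(y - level))])


def _pin_flags(popt, bounds_lo, bounds_hi, names, rel=1e-6):
    flags = []
    for v, lo, hi, nm in zip(popt, bounds_lo, bounds_hi, names):
        span = hi - lo if np.isfinite(hi - lo) else max(abs(v), 1.0)
        if np.isfinite(lo) and abs(v - lo) < rel * span:
            flags.append(f"{nm}_at_lower_bound")
        if np.isfinite(hi) and abs(v - hi) < rel * span:
            flags.append(f"{nm}_at_upper_bound")
    return flags


# ---------------------------------------------------------------------------
# I-V and conductance


def iv_model(V, gmax, vrev, v05, k):
    return gmax * (V - vrev) / (1.0 + np.exp(-(V - v05) / k))


def fit_iv(V_mV, peak_density) -> ActivationFit:
    """Fit the Boltzmann-scaled linear I-V relationship to peak densities.

    Initialization: Vrev from the interpolated zero crossing beyond the
    current peak, V0.5 from the half-maximum crossing of the implied
    conductance, k = 6 mV, Gmax from the conductance plateau. Slope factor
    bounded to (0.5, 30) mV.
    """
    V = np.asarray(V_mV, dtype=float)
    y = np.asarray(peak_density, dtype=float)
    if V.size < 6:
        raise FitError("I-V fit needs at least 6 test potentials")
    if np.allclose(y, 0.0):
        raise DegenerateDataError("all densities are zero")

    ipk = int(np.argmin(y))
    post = slice(ipk, None)
    vrev0 = _half_crossing(V[post], y[post], 0.0)
    if not np.isfinite(vrev0) or vrev0 <= V[ipk]:
        vrev0 = V[-1] + 15.0
    with np.errstate(divide="ignore", invalid="ignore"):
        g = np.where(np.abs(V - vrev0) > 5.0, y / (V - vrev0), np.nan)
    gmax0 = np.nanmax(g)
    if not np.isfinite(gmax0) or gmax0 <= 0:
        gmax0 = abs(y[ipk]) / max(abs(V[ipk] - vrev0), 1.0)
    gnorm = g / gmax0
    valid = np.isfinite(gnorm)
    v050 = _half_crossing(V[valid], gnorm[valid], 0.5)

    lo = [0.0, V.min(), V.min() - 50.0, K_BOUNDS_MV[0]]
    hi = [np.inf, V.max() + 200.0, V.max() + 50.0, K_BOUNDS_MV[1]]
    popt, se, ss = _curve_fit(
        iv_model, V, y, p0=[gmax0, vrev0, v050, 6.0], bounds=(lo, hi), name="I-V"
    )
    flags = _pin_flags(popt, lo, hi, ["gmax", "vrev", "v05", "k"])
    return ActivationFit(
        v05_act_mV=float(popt[2]),
        k_act_mV=float(popt[3]),
        vrev_mV=float(popt[1]),
        gmax=float(popt[0]),
        ss_res=ss,
        n=V.size,
        stderr={"gmax": se[0], "vrev": se[1], "v05": se[2], "k": se[3]},
        flags=flags,
    )


def conductance_from_iv(V_mV, peak_density, vrev_mV, min_driving_mV: float = 10.0):
    """Chord conductance G = I/(V-Vrev), excluding voltages near reversal."""
    V = np.asarray(V_mV, dtype=float)
    y = np.asarray(peak_density, dtype=float)
    mask = np.abs(V - vrev_mV) >= min_driving_mV
    return V[mask], y[mask] / (V[mask] - vrev_mV)


def boltzmann_model(V, gmax, v05, k):
    return gmax / (1.0 + np.exp(-(V - v05) / k))


def fit_conductance(V_mV, G) -> ActivationFit:
    """Boltzmann fit of the normalized (or raw) conductance-voltage curve."""
    V = np.asarray(V_mV, dtype=float)
    g = np.asarray(G, dtype=float)
    if np.allclose(g, 0.0):
        raise DegenerateDataError("all conductances are zero")
    gmax0 = g.max()
    v050 = _half_crossing(V, g / gmax0, 0.5)
    lo = [0.0, V.min() - 50.0, K_BOUNDS_MV[0]]
    hi = [np.inf, V.max() + 50.0, K_BOUNDS_MV[1]]
    popt, se, ss = _curve_fit(
        boltzmann_model, V, g, p0=[gmax0, v050, 6.0], bounds=(lo, hi), name="conductance"
    )
    return ActivationFit(
        v05_act_mV=float(popt[1]),
        k_act_mV=float(popt[2]),
        vrev_mV=float("nan"),
        gmax=float(popt[0]),
        ss_res=ss,
        n=V.size,
        stderr={"gmax": se[0], "v05": se[1], "k": se[2]},
        flags=_pin_flags(popt, lo, hi, ["gmax", "v05", "k"]),
    )


# ---------------------------------------------------------------------------
# steady-state inactivation and window current


def ssi_model(V, ini, v05, k):
    return ini + (1.0 - ini) / (1.0 + np.exp((V - v05) / k))


def fit_ssi(cond_V_mV, ratio) -> InactivationFit:
    """Modified-Boltzmann fit of the availability curve (test/control ratio)."""
    V = np.asarray(cond_V_mV, dtype=float)
    y = np.asarray(ratio, dtype=float)
    if V.size < 6:
        raise FitError("SSI fit needs at least 6 conditioning voltages")
    if np.any((y < -0.01) | (y > 1.05)):
        raise FitError("availability ratios outside [0, 1.05]")
    if np.ptp(y) < 0.05:
        raise DegenerateDataError(
            "availability curve is flat; non-inactivating fraction indeterminate"
        )
    ini0 = max(float(y.min()), 0.0)
    v050 = _half_crossing(V, y, ini0 + (1.0 - ini0) / 2.0)
    lo = [0.0, V.min() - 50.0, K_BOUNDS_MV[0]]
    hi = [1.0, V.max() + 50.0, K_BOUNDS_MV[1]]
    popt, se, ss = _curve_fit(
        ssi_model, V, y, p0=[ini0, v050, 6.0], bounds=(lo, hi), name="SSI"
    )
    flags = _pin_flags(popt, lo, hi, ["frac_noninact", "v05_inact", "k_inact"])
    return InactivationFit(
        v05_inact_mV=float(popt[1]),
        k_inact_mV=float(popt[2]),
        frac_noninact=float(popt[0]),
        ss_res=ss,
        n=V.size,
        stderr={"frac_noninact": se[0], "v05_inact": se[1], "k_inact": se[2]},
        flags=flags,
    )


def window_current(V_mV, peak_density, ssi: InactivationFit) -> list[WindowPoint]:
    """Voltage-resolved steady Ca2+-influx estimate.

    window(V) = availability(V) * peak current density(V), with the fitted
    availability curve evaluated on the I-V voltage grid.
    """
    V = np.asarray(V_mV, dtype=float)
    dens = np.asarray(peak_density, dtype=float)
    avail = ssi.availability(V)
    return [
        WindowPoint(float(v), float(d), float(d * a))
        for v, d, a in zip(V, dens, avail)
    ]


# ---------------------------------------------------------------------------
# decay kinetics


def extract_decay(sweep: Sweep, pulse_window_ms: tuple[float, float] | None = None):
    """(t_ms from peak, % of peak magnitude) of the decaying phase of a pulse."""
    if pulse_window_ms is None:
        pulse_window_ms = tuple(sweep.metadata["pulse_window_ms"])
    pk = peak_current(sweep, pulse_window_ms)
    sl = sweep.window_slice((pk.t_peak_ms, pulse_window_ms[1]))
    t = sweep.time_ms[sl] - pk.t_peak_ms
    y = 100.0 * sweep.current_pA[sl] / pk.amplitude_pA  # magnitudes: both negative
    return t, y


def remaining_fractions(
    sweep: Sweep,
    times_ms=(50.0, 100.0, 250.0, 500.0, 1000.0, 5000.0),
    pulse_window_ms: tuple[float, float] | None = None,
) -> dict[float, float]:
    """Remaining current at prespecified times after the peak, in % of peak."""
    if pulse_window_ms is None:
        pulse_window_ms = tuple(sweep.metadata["pulse_window_ms"])
    pk = peak_current(sweep, pulse_window_ms)
    out = {}
    for t in times_ms:
        t_abs = pk.t_peak_ms + t
        if t_abs > pulse_window_ms[1] + 1e-9:
            raise FitError(f"time point {t} ms lies beyond the pulse")
        idx = min(
            int(np.searchsorted(sweep.time_ms, t_abs - 1e-9)), sweep.time_ms.size - 1
        )
        out[float(t)] = float(100.0 * sweep.current_pA[idx] / pk.amplitude_pA)
    return out


def _mono_model(t, a, tau, plateau):
    return plateau + a * np.exp(-t / tau)


def _bi_model(t, af, tauf, aslow, taus, plateau):
    return plateau + af * np.exp(-t / tauf) + aslow * np.exp(-t / taus)


def _tau0_loglinear(t, y, plateau0) -> float:
    """Log-linear regression of (y - plateau) over the decaying stretch."""
    z = y - plateau0
    mask = z > max(1e-3, 0.01 * z.max())
    if mask.sum() < 2:
        return max(t[-1] / 3.0, TAU_BOUNDS_MS[0] * 1.01)
    slope, _ = np.polyfit(t[mask], np.log(z[mask]), 1)
    if slope >= 0:
        return max(t[-1] / 3.0, TAU_BOUNDS_MS[0] * 1.01)
    return float(np.clip(-1.0 / slope, TAU_BOUNDS_MS[0] * 1.01, TAU_BOUNDS_MS[1] * 0.99))


def fit_decay(t_ms, pct_of_peak, model: str = "auto") -> DecayFit:
    """Mono- or bi-exponential fit of a current decay (in % of peak).

    ``model='auto'`` selects the bi-exponential only when the extra
    sum-of-squares F-test prefers it at alpha = 0.05 (the study-wide
    significance level); when the mono fit is already at numerical noise the
    simpler model is kept, and a bi fit whose time constants collapse
    (tau_fast/tau_slow > 0.8) is refit as mono and flagged.
    """
    t = np.asarray(t_ms, dtype=float)
    y = np.asarray(pct_of_peak, dtype=float)
    if t.size < 10:
        raise FitError("decay fit needs a longer trace")

    plateau0 = float(max(y.min(), 0.0))
    tau0 = _tau0_loglinear(t, y, plateau0)
    a0 = max(float(y[0] - plateau0), 1.0)

    lo_m = [0.0, TAU_BOUNDS_MS[0], 0.0]
    hi_m = [200.0, TAU_BOUNDS_MS[1], 100.0]
    popt_m, se_m, ss_m = _curve_fit(
        _mono_model, t, y, p0=[a0, tau0, plateau0], bounds=(lo_m, hi_m), name="mono decay"
    )

    def _mono_result(flags=(), f_test=None):
        return DecayFit(
            model="mono",
            a_fast_pct=None,
            tau_fast_ms=None,
            a_slow_pct=float(popt_m[0]),
            tau_slow_ms=float(popt_m[1]),
            plateau_pct=float(popt_m[2]),
            ss_res=ss_m,
            n=t.size,
            stderr={"a": se_m[0], "tau": se_m[1], "plateau": se_m[2]},
            flags=list(flags),
            f_test=f_test,
        )

    if model == "mono":
        return _mono_result()

    lo_b = [0.0, TAU_BOUNDS_MS[0], 0.0, TAU_BOUNDS_MS[0], 0.0]
    hi_b = [200.0, TAU_BOUNDS_MS[1], 200.0, TAU_BOUNDS_MS[1], 100.0]
    p0_b = [a0 * 0.6, tau0 / 4.0, a0 * 0.4, min(tau0 * 3.0, TAU_BOUNDS_MS[1] * 0.9), plateau0]
    try:
        popt_b, se_b, ss_b = _curve_fit(
            _bi_model, t, y, p0=p0_b, bounds=(lo_b, hi_b), name="bi decay"
        )
    except FitError:
        if model == "bi":
            raise
        return _mono_result(flags=["bi_fit_failed"])

    if popt_b[1] > popt_b[3]:  # order tau_fast < tau_slow
        popt_b = [popt_b[2], popt_b[3], popt_b[0], popt_b[1], popt_b[4]]
        se_b = [se_b[2], se_b[3], se_b[0], se_b[1], se_b[4]]

    collapse = popt_b[1] / popt_b[3] > 0.8

    def _bi_result(f_test=None):
        return DecayFit(
            model="bi",
            a_fast_pct=float(popt_b[0]),
            tau_fast_ms=float(popt_b[1]),
            a_slow_pct=float(popt_b[2]),
            tau_slow_ms=float(popt_b[3]),
            plateau_pct=float(popt_b[4]),
            ss_res=ss_b,
            n=t.size,
            stderr={
                "a_fast": se_b[0],
                "tau_fast": se_b[1],
                "a_slow": se_b[2],
                "tau_slow": se_b[3],
                "plateau": se_b[4],
            },
            flags=[],
            f_test=f_test,
        )

    if model == "bi":
        res = _bi_result()
        if collapse:
            res.flags.append("tau_collapse")
        return res

    # auto selection
    if collapse:
        return _mono_result(flags=["tau_collapse_refit_mono"])
    scale = float(np.sum((y - y.mean()) ** 2))
    if scale > 0 and ss_m / scale < 1e-10:
        # mono already fits to numerical precision; F ratio would be noise
        return _mono_result(flags=["mono_adequate"])
    if ss_b >= ss_m:
        return _mono_result(flags=["bi_no_improvement"])
    ft = ess_f_test(ss_m, t.size - 3, max(ss_b, 1e-300), t.size - 5)
    if ft.p < 0.05 and ss_b < ss_m:
        return _bi_result(f_test=ft)
    return _mono_result(f_test=ft)


def fit_decay_sweep(sweep: Sweep, model: str = "auto") -> DecayFit:
    t, y = extract_decay(sweep)
    return fit_decay(t, y, model=model)


# ---------------------------------------------------------------------------
# recovery from inactivation


def recovery_model(t_ms, af, tauf, aslow, taus, offset):
    return (
        offset
        + af * (1.0 - np.exp(-t_ms / tauf))
        + aslow * (1.0 - np.exp(-t_ms / taus))
    )


def fit_recovery(gaps_s, fractional_recovery) -> RecoveryFit:
    """Double-exponential fit of fractional recovery vs gap duration.

    The instantaneous (zero-gap) fraction is a free offset bounded to
    [0, 0.95]: the fitted amplitudes of the two recovering components need
    not sum to 1, and a conditioning prepulse short relative to slow
    inactivation can leave a large un-inactivated fraction. Requires gaps
    spanning at least two decades.
    """
    g = np.asarray(gaps_s, dtype=float)
    y = np.asarray(fractional_recovery, dtype=float)
    if g.size < 6:
        raise FitError("recovery fit needs at least 6 gap durations")
    if g.max() / g.min() < 100.0:
        raise FitError("recovery gaps must span at least two decades")
    order = np.argsort(g)
    g, y = g[order], y[order]
    t = g * 1000.0  # ms

    off0 = float(np.clip(y.min(), 0.0, 0.9))
    amp = max(float(y.max() - off0), 0.05)
    tauf0 = _half_crossing(t, y, off0 + 0.5 * amp)
    tauf0 = float(np.clip(tauf0, TAU_BOUNDS_MS[0] * 1.1, TAU_BOUNDS_MS[1] * 0.5))
    lo = [0.0, TAU_BOUNDS_MS[0], 0.0, TAU_BOUNDS_MS[0], 0.0]
    hi = [1.0, TAU_BOUNDS_MS[1], 1.0, TAU_BOUNDS_MS[1], 0.95]

    best = None
    last_err = None
    for ratio in (30.0, 8.0, 100.0):
        taus0 = min(tauf0 * ratio, TAU_BOUNDS_MS[1] * 0.9)
        p0 = [amp * 0.8, tauf0, amp * 0.2, taus0, off0]
        try:
            popt, se, ss = _curve_fit(
                recovery_model, t, y, p0=p0, bounds=(lo, hi), name="recovery"
            )
        except FitError as exc:
            last_err = exc
            continue
        if best is None or ss < best[2]:
            best = (popt, se, ss)
    if best is None:
        raise last_err
    popt, se, ss = best
    if popt[1] > popt[3]:
        popt = [popt[2], popt[3], popt[0], popt[1], popt[4]]
        se = [se[2], se[3], se[0], se[1], se[4]]
    flags = _pin_flags(popt, lo, hi, ["a_fast", "tau_fast", "a_slow", "tau_slow", "offset"])
    return RecoveryFit(
        a_fast=float(popt[0]),
        tau_fast_ms=float(popt[1]),
        a_slow=float(popt[2]),
        tau_slow_ms=float(popt[3]),
        offset=float(popt[4]),
        ss_res=ss,
        n=g.size,
        stderr={
            "a_fast": se[0],
            "tau_fast": se[1],
            "a_slow": se[2],
            "tau_slow": se[3],
            "offset": se[4],
        },
        flags=flags,
    )


# ---------------------------------------------------------------------------
# tail currents


def analyze_tail(
    sweep: Sweep,
    repol_window_ms: tuple[float, float] | None = None,
    *,
    integral_ms: float = 20.0,
    noise_floor_pA: float = 1.0,
    hook_min_delay_samples: int = 2,
) -> TailResult:
    """Deactivation analysis of one repolarization tail.

    Fits a mono-exponential to the decaying phase after the tail peak,
    integrates the peak-normalized tail over 20 ms, and reports a "hook"
    when the tail peak lags repolarization onset by more than 2 samples.
    """
    if repol_window_ms is None:
        repol_window_ms = tuple(sweep.metadata["repol_window_ms"])
    t0, _ = repol_window_ms
    t_end = t0 + integral_ms
    sl = sweep.window_slice((t0, t_end))
    t = sweep.time_ms[sl]
    i = sweep.current_pA[sl]
    ipk = int(np.argmin(i))
    peak = float(i[ipk])
    if abs(peak) < noise_floor_pA:
        raise FitError("no measurable tail current above the noise floor")

    hook_delay = float(t[ipk] - t0)
    hook = (t[ipk] - t0) > hook_min_delay_samples * (1000.0 / sweep.sampling_rate_hz)

    td = t[ipk:] - t[ipk]
    yd = i[ipk:] / peak  # normalized, starts at 1, decays toward 0
    tau0 = _tau0_loglinear(td, yd * 100.0, 0.0)
    popt, _, _ = _curve_fit(
        lambda tt, a, tau, c: c + a * np.exp(-tt / tau),
        td,
        yd,
        p0=[1.0, min(tau0, integral_ms), 0.0],
        bounds=([0.0, 0.01, -0.5], [2.0, 1000.0, 0.5]),
        name="tail",
    )
    integral = float(np.trapezoid(i / peak, t))
    return TailResult(
        repol_voltage_mV=float(sweep.metadata.get("repol_voltage_mV", np.nan)),
        tau_deact_ms=float(popt[1]),
        normalized_integral_ms=integral,
        hook_present=bool(hook),
        hook_delay_ms=hook_delay,
    )


# ---------------------------------------------------------------------------
# dose-response


def hill_inhibition_model(log_c, log_ic50):
    """Percent inhibition, Hill slope 1, bottom 0 / top 100 fixed."""
    return 100.0 / (1.0 + 10.0 ** (log_ic50 - log_c))


def fit_dose_response(conc_nM, inhibition_pct) -> DoseResponseFit:
    """One-parameter Hill fit (log IC50) of run-down-corrected inhibition.

    Bottom and top are fixed at 0 and 100 % and the Hill slope at 1; the 95%
    confidence interval is asymptotic on the log scale and exponentiated.
    """
    c = np.asarray(conc_nM, dtype=float)
    y = np.asarray(inhibition_pct, dtype=float)
    if np.any(c <= 0):
        raise FitError("concentrations must be > 0 for the log-scale fit")
    if c.size < 2:
        raise FitError("dose-response fit needs at least 2 concentrations")
    if np.all(y < 1.0) or np.all(y > 99.0):
        raise DegenerateDataError("inhibition all ~0% or all ~100%; IC50 unconstrained")
    order = np.argsort(c)
    if np.any(np.diff(y[order]) < -5.0):
        warnings.warn("inhibition is non-monotone in concentration", stacklevel=2)

    log_c = np.log10(c)
    lic0 = _half_crossing(log_c[order], y[order], 50.0)
    popt, se, ss = _curve_fit(
        hill_inhibition_model, log_c, y, p0=[lic0], bounds=([-3.0], [8.0]),
        name="dose-response",
    )
    lic = float(popt[0])
    dof = max(c.size - 1, 1)
    tcrit = sstats.t.ppf(0.975, dof)
    half = tcrit * se[0] if np.isfinite(se[0]) else 0.0
    return DoseResponseFit(
        ic50_nM=float(10.0**lic),
        log_ic50=lic,
        ci95_nM=(float(10.0 ** (lic - half)), float(10.0 ** (lic + half))),
        ss_res=ss,
        n=c.size,
        stderr_log_ic50=float(se[0]),
    )
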