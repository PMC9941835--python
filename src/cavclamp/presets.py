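"""Shipped parameter sets for the four channel / beta-subunit combinations.

Each preset bundles:

* ``gating`` — the simulator parameterization (Boltzmann activation and
  availability, gate amplitudes, decay/recovery time constants);
* ``decay`` — the mono- or bi-exponential 5-s inactivation parameters in the
  amplitude-percent convention of the curve-fit tables, used verbatim for
  closed-form fixtures;
* ``recovery`` — double-exponential recovery-from-inactivation parameters
  (fractional amplitudes, time constants at the holding potential);
* ``rundown_slope_pct_per_min`` — the linear run-down slope of drug-free
  control runs for this subunit combination.

The simulator's two inactivation-gate amplitudes must sum with the
non-inactivating fraction to exactly 1, while the empirically fitted decay
amplitudes do not (they sum to ~95-96%); presets therefore renormalize the
fitted fast:slow amplitude ratio into 1 - frac_noninact. The mutant channel
inactivates mono-exponentially but recovers bi-exponentially, which the
gate model reproduces by giving both gates the same depolarized decay time
constant while keeping distinct recovery time constants. Recovery parameters
were measured with the beta3 subunit; beta2a presets reuse the values of the
matching channel variant.
"""

from __future__ import annotations

from dataclasses import dataclass

from .gating_model import GatingParams, HookModel, TauActivation

__all__ = ["DecayTruth", "RecoveryTruth", "ChannelPreset", "PRESETS", "get_preset"]


@dataclass(frozen=True)
class DecayTruth:
    """Exponential inactivation parameters (amplitudes in % of peak)."""

    model: str  # "mono" | "bi"
    a_slow_pct: float
    tau_slow_ms: float
    plateau_pct: float
    a_fast_pct: float | None = None
    tau_fast_ms: float | None = None


@dataclass(frozen=True)
class RecoveryTruth:
    """Double-exponential recovery parameters (fractional amplitudes)."""

    a_fast: float
    tau_fast_ms: float
    a_slow: float
    tau_slow_ms: float

    @property
    def offset(self) -> float:
        """Instantaneous/unrecovered fraction implied by amplitudes < 1."""
        return max(0.0, 1.0 - self.a_fast - self.a_slow)

    def curve(self, gap_s):
        """Fractional recovery as a function of the gap duration (s)."""
        import numpy as np

        t_ms = np.asarray(gap_s, dtype=float) * 1000.0
        return (
            self.offset
            + self.a_fast * (1.0 - np.exp(-t_ms / self.tau_fast_ms))
            + self.a_slow * (1.0 - np.exp(-t_ms / self.tau_slow_ms))
        )


@dataclass(frozen=True)
class ChannelPreset:
    label: str
    gating: GatingParams
    decay: DecayTruth
    recovery: RecoveryTruth
    rundown_slope_pct_per_min: float


def _split_amplitudes(frac_noninact: float, fast: float, slow: float):
    """Renormalize a fast:slow amplitude ratio into 1 - frac_noninact."""
    avail = 1.0 - frac_noninact
    a_fast = avail * fast / (fast + slow)
    return a_fast, avail - a_fast


def _build_presets() -> dict[str, ChannelPreset]:
    presets: dict[str, ChannelPreset] = {}

    # ---- WT + beta3 -------------------------------------------------------
    frac = 0.2048
    a_fast, a_slow = _split_amplitudes(frac, fast=63.74, slow=25.13)
    presets["WT+b3"] = ChannelPreset(
        label="WT+b3",
        gating=GatingParams(
            label="WT+b3",
            v05_act_mV=-0.12,
            k_act_mV=9.14,
            vrev_mV=62.82,
            gmax_density_nS_per_pF=0.40,
            tau_act=TauActivation(),
            v05_inact_mV=-26.02,
            k_inact_mV=6.07,
            frac_noninact=frac,
            a_fast=a_fast,
            a_slow=a_slow,
            tau_inact_fast_ms=227.20,
            tau_inact_slow_ms=1987.59,
            tau_rec_fast_ms=67.6,
            tau_rec_slow_ms=5625.0,
            tau_deact_ref_ms=0.9,
        ),
        decay=DecayTruth(
            model="bi",
            a_slow_pct=25.13,
            tau_slow_ms=1987.59,
            a_fast_pct=63.74,
            tau_fast_ms=227.20,
            plateau_pct=7.12,
        ),
        recovery=RecoveryTruth(a_fast=0.72, tau_fast_ms=67.6, a_slow=0.10, tau_slow_ms=5625.0),
        rundown_slope_pct_per_min=-1.5383,
    )

    # ---- F747S + beta3 ----------------------------------------------------
    frac = 0.3124
    a_fast, a_slow = _split_amplitudes(frac, fast=0.36, slow=0.44)
    presets["F747S+b3"] = ChannelPreset(
        label="F747S+b3",
        gating=GatingParams(
            label="F747S+b3",
            v05_act_mV=-28.5,
            k_act_mV=5.97,
            vrev_mV=41.64,
            gmax_density_nS_per_pF=0.40,
            tau_act=TauActivation(),
            v05_inact_mV=-42.88,
            k_inact_mV=4.93,
            frac_noninact=frac,
            a_fast=a_fast,
            a_slow=a_slow,
            # mono-exponential decay: both gates share the depolarized tau
            tau_inact_fast_ms=1424.08,
            tau_inact_slow_ms=1424.08,
            tau_rec_fast_ms=165.94,
            tau_rec_slow_ms=6778.23,
            tau_deact_ref_ms=4.0,
            hook=HookModel(enabled=False),
        ),
        decay=DecayTruth(
            model="mono",
            a_slow_pct=67.48,
            tau_slow_ms=1424.08,
            plateau_pct=28.27,
        ),
        recovery=RecoveryTruth(
            a_fast=0.36, tau_fast_ms=165.94, a_slow=0.44, tau_slow_ms=6778.23
        ),
        rundown_slope_pct_per_min=-0.4941,
    )

    # ---- WT + beta2a ------------------------------------------------------
    frac = 0.3030
    a_fast, a_slow = _split_amplitudes(frac, fast=28.97, slow=41.27)
    presets["WT+b2a"] = ChannelPreset(
        label="WT+b2a",
        gating=GatingParams(
            label="WT+b2a",
            v05_act_mV=1.98,
            k_act_mV=10.08,
            vrev_mV=66.41,
            gmax_density_nS_per_pF=0.40,
            tau_act=TauActivation(),
            v05_inact_mV=-16.22,
            k_inact_mV=10.12,
            frac_noninact=frac,
            a_fast=a_fast,
            a_slow=a_slow,
            tau_inact_fast_ms=283.48,
            tau_inact_slow_ms=2070.87,
            tau_rec_fast_ms=67.6,
            tau_rec_slow_ms=5625.0,
            tau_deact_ref_ms=0.9,
        ),
        decay=DecayTruth(
            model="bi",
            a_slow_pct=41.27,
            tau_slow_ms=2070.87,
            a_fast_pct=28.97,
            tau_fast_ms=283.48,
            plateau_pct=24.74,
        ),
        recovery=RecoveryTruth(a_fast=0.72, tau_fast_ms=67.6, a_slow=0.10, tau_slow_ms=5625.0),
        rundown_slope_pct_per_min=-0.4046,
    )

    # ---- F747S + beta2a ---------------------------------------------------
    frac = 0.4248
    a_fast, a_slow = _split_amplitudes(frac, fast=0.36, slow=0.44)
    presets["F747S+b2a"] = ChannelPreset(
        label="F747S+b2a",
        gating=GatingParams(
            label="F747S+b2a",
            v05_act_mV=-24.68,
            k_act_mV=5.94,
            vrev_mV=44.79,
            gmax_density_nS_per_pF=0.40,
            tau_act=TauActivation(),
            v05_inact_mV=-38.94,
            k_inact_mV=4.04,
            frac_noninact=frac,
            a_fast=a_fast,
            a_slow=a_slow,
            tau_inact_fast_ms=2176.09,
            tau_inact_slow_ms=2176.09,
            tau_rec_fast_ms=165.94,
            tau_rec_slow_ms=6778.23,
            tau_deact_ref_ms=4.0,
            hook=HookModel(enabled=False),
        ),
        decay=DecayTruth(
            model="mono",
            a_slow_pct=65.75,
            tau_slow_ms=2176.09,
            plateau_pct=31.61,
        ),
        recovery=RecoveryTruth(
            a_fast=0.36, tau_fast_ms=165.94, a_slow=0.44, tau_slow_ms=6778.23
        ),
        rundown_slope_pct_per_min=-0.1006,
    )
    return presets


PRESETS: dict[str, ChannelPreset] = _build_presets()

#: Table-row ordering used by reports.
PRESET_ORDER = ["WT+b3", "F747S+b3", "WT+b2a", "F747S+b2a"]


def get_preset(name: str) -> ChannelPreset:
    try:
        return PRESETS[name]
    except KeyError:
        raise KeyError(
            f"unknown preset {name!r}; available: {', '.join(PRESET_ORDER)}"
        ) from None
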