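#!/usr/bin/env python
"""Deactivation tail currents after a 10-ms step to the reversal potential.

Simulates P/4-subtracted tail families (20-ms repolarizations, 10-mV steps)
for WT and mutant with beta3, extracts the deactivation time constant and
the 20-ms peak-normalized tail integral per repolarization voltage, and
demonstrates hook detection (delayed tail peak) with the optional
blocked-open-pool mechanism enabled.

Writes results/tail_currents.csv.
"""

import dataclasses
from pathlib import Path

import pandas as pd

from cavclamp import curves, pipeline
from cavclamp.gating_model import CellModel, HookModel
from cavclamp.presets import PRESETS

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)

cell = CellModel(capacitance_pF=20.0, leak_conductance_nS=1.0, noise_sd_pA=0.0, seed=2022)

rows = []
variants = {
    "WT+b3": PRESETS["WT+b3"].gating,
    "F747S+b3": PRESETS["F747S+b3"].gating,
    "F747S+b3 (hook)": dataclasses.replace(
        PRESETS["F747S+b3"].gating, hook=HookModel(enabled=True)
    ),
}
for label, g in variants.items():
    for sw in pipeline.simulate_tail_bundle(g, cell):
        v = sw.metadata["repol_voltage_mV"]
        if v not in (-69.0, -49.0):
            continue
        r = curves.analyze_tail(sw)
        rows.append(
            {
                "channel": label,
                "repol_mV": v,
                "tau_deact_ms": r.tau_deact_ms,
                "tail_integral_ms": r.normalized_integral_ms,
                "hook": r.hook_present,
                "hook_delay_ms": r.hook_delay_ms,
            }
        )

df = pd.DataFrame(rows)
df.to_csv(OUT / "tail_currents.csv", index=False)
print(df.to_string(index=False, float_format=lambda x: f"{x:7.3f}"))
ratio = (
    df.query("channel == 'F747S+b3' and repol_mV == -69")["tail_integral_ms"].iloc[0]
    / df.query("channel == 'WT+b3' and repol_mV == -69")["tail_integral_ms"].iloc[0]
)
print(f"\nNormalized tail integral ratio (F747S/WT) at -69 mV: {ratio:.1f}x —")
print("the mutant deactivates several-fold more slowly; with the")
print("blocked-open-pool mechanism the tail peak is delayed (hook).")
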