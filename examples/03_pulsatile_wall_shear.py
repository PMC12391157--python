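"""Analytic pulsatile wall shear over a synthetic PA bifurcation.

Builds the default three-branch geometry, drives it with the
regurgitant waveform, synthesizes the Womersley wall-shear field at 20
timepoints per cycle, and prints the per-segment metric table: steady
WSS, time-averaged WSS, systolic/diastolic WSS (dynes/cm^2) and OSI.
An OSI of 0 means shear never reverses; 0.5 means full reversal.
"""

import numpy as np

from pahemo import (
    FluidProperties,
    OutletResistanceSpec,
    fourier_decompose,
    reconstruct_waveform,
    resistance_network,
    steady_inflow,
    summarize_case,
)
from pahemo.engine import synthesize_steady_wss_field, synthesize_wss_field
from pahemo.synthetic import (
    WaveformSpec,
    default_pa_spec,
    make_flow_waveform,
    make_pa_bifurcation,
)

spec = default_pa_spec()  # MPA r=1.5, LPA r=0.8 (curvier), RPA r=1.0 cm
mesh, centerlines, labeling = make_pa_bifurcation(spec)
fluid = FluidProperties()  # rho = 1.06 g/cm^3, mu = 0.04 g/(cm s)

wf = make_flow_waveform(WaveformSpec())
ff = fourier_decompose(wf, 10)
_, fractions = resistance_network(OutletResistanceSpec({"LPA": 2.0, "RPA": 2.0}))

pulsatile = synthesize_wss_field(mesh, labeling, centerlines, ff, fluid, fractions)
steady = synthesize_steady_wss_field(
    mesh, labeling, centerlines, steady_inflow(wf.net_volume(), wf.heart_rate),
    fluid, fractions,
)

inflow = reconstruct_waveform(ff, pulsatile.times)
summary = summarize_case(steady, pulsatile, inflow_at_timepoints=inflow)

print(summary.to_tidy().pivot(index="metric", columns="region", values="value").round(2))
print("\nThe narrow, curvy LPA carries half the flow through the smallest")
print("lumen, so its segment-average WSS exceeds the RPA's, which exceeds")
print("the wide MPA trunk's — the expected post-repair pattern.")
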