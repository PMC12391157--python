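"""Inlet and outlet boundary conditions for a regurgitant PA case.

Generates the cohort-typical pulsatile waveform (heart rate 75 bpm,
100 mL forward volume, regurgitant fraction 0.40), decomposes it into 10
Fourier modes, and prints the derived boundary-condition quantities:
steady inflow, outlet resistance network, and waveform features.
"""

import numpy as np

from pahemo import (
    OutletResistanceSpec,
    find_systole_diastole,
    fourier_decompose,
    iwu_to_cgs,
    parabolic_profile,
    reconstruct_waveform,
    regurgitant_fraction,
    resistance_network,
    steady_inflow,
)
from pahemo.synthetic import WaveformSpec, make_flow_waveform

wf = make_flow_waveform(WaveformSpec(heart_rate=75, forward_volume=100, regurgitant_fraction=0.40))
print(f"cycle period        {wf.period:.3f} s")
print(f"forward volume      {wf.forward_volume():.1f} mL")
print(f"net volume          {wf.net_volume():.1f} mL  (forward minus regurgitant)")
print(f"regurgitant fraction {regurgitant_fraction(wf):.3f}")

# steady inflow uses the NET stroke volume (what RVSVi measures)
q = steady_inflow(wf.net_volume(), wf.heart_rate)
print(f"steady inflow       {q:.1f} cm^3/s")
print(f"peak inlet velocity {parabolic_profile(q, 1.5, 0.0):.1f} cm/s (parabolic profile, R=1.5 cm)")

# 10-mode Fourier fit of the periodic waveform, sampled at the 20 output timepoints
ff = fourier_decompose(wf, n_modes=10)
t20 = np.arange(20) * ff.period / 20
inflow = reconstruct_waveform(ff, t20)
i_sys, i_dia = find_systole_diastole(inflow)
print(f"systole at t={t20[i_sys]:.3f} s (Q={inflow[i_sys]:.0f}), "
      f"diastole at t={t20[i_dia]:.3f} s (Q={inflow[i_dia]:.0f} — negative: regurgitation)")

# two 2-iWU branch outlets give the lungs' total of 1 iWU
total, frac = resistance_network(OutletResistanceSpec({"LPA": 2.0, "RPA": 2.0}, bsa=1.0))
print(f"total lung resistance {total:.1f} iWU; flow split {frac}")
print(f"2 iWU at BSA 1 m^2 = {iwu_to_cgs(2.0, 1.0):.1f} dyn s/cm^5")
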