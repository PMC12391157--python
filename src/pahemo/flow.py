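"""Inlet and outlet boundary conditions for pulmonary-artery flow.

Covers the steady inflow rule (stroke volume x heart rate), truncated
Fourier representation of the periodic inlet waveform (10 harmonics by
default), the parabolic inlet velocity profile, parallel resistance
outlets in indexed Wood units, and waveform feature extraction
(systole/diastole timepoints, regurgitant fraction).

Units are CGS internally: cm, s, g, dynes. Volumes arrive in mL (= cm^3)
and heart rate in beats/min; they are converted at the interface.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

#: frequency-domain truncation used for the periodic inlet flow
DEFAULT_N_MODES = 10

#: 1 Wood unit = 1 mmHg.min/L expressed in dyn.s/cm^5
MMHG_TO_DYN_CM2 = 1333.22
LMIN_TO_CM3_S = 1000.0 / 60.0
WOOD_UNIT_CGS = MMHG_TO_DYN_CM2 / LMIN_TO_CM3_S  # 79.993 dyn.s/cm^5


@dataclass
class FluidProperties:
    """Newtonian blood: density g/cm^3, dynamic viscosity g/(cm.s)."""

    density: float = 1.06
    viscosity: float = 0.04

    def __post_init__(self) -> None:
        if self.density <= 0 or self.viscosity <= 0:
            raise ValueError("fluid properties must be positive")


@dataclass
class FlowWaveform:
    """One cardiac cycle of volumetric flow.

    ``times`` are uniform in [0, period) seconds; ``flows`` are signed
    cm^3/s with forward flow positive.
    """

    times: np.ndarray
    flows: np.ndarray
    heart_rate: float

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.flows = np.asarray(self.flows, dtype=float)
        if self.heart_rate <= 0:
            raise ValueError("heart rate must be positive")
        if len(self.times) != len(self.flows):
            raise ValueError("times and flows must have equal length")
        if not (np.isfinite(self.times).all() and np.isfinite(self.flows).all()):
            raise ValueError("waveform samples must be finite")
        if np.any(self.times < 0) or np.any(self.times >= self.period):
            raise ValueError("times must lie in [0, period)")

    @property
    def period(self) -> float:
        return 60.0 / self.heart_rate

    def _closed(self) -> tuple[np.ndarray, np.ndarray]:
        """Samples with the periodic closure point appended."""
        t = np.append(self.times, self.times[0] + self.period)
        q = np.append(self.flows, self.flows[0])
        return t, q

    def net_volume(self) -> float:
        """Net ejected volume per cycle (mL), trapezoidal."""
        t, q = self._closed()
        return float(np.trapezoid(q, t))

    def forward_volume(self) -> float:
        t, q = self._closed()
        return float(np.trapezoid(np.clip(q, 0, None), t))

    def reverse_volume(self) -> float:
        t, q = self._closed()
        return float(np.trapezoid(np.clip(-q, 0, None), t))


@dataclass
class FourierFlow:
    """Truncated complex Fourier series of a periodic flow.

    ``modes[n]`` is the coefficient of exp(i n w0 t); the reconstructed
    signal is Re(sum_n modes[n] exp(i n w0 t)), so mode 0 is the mean flow
    (real) and |modes[n]| for n >= 1 is the amplitude of harmonic n.
    """

    modes: np.ndarray
    fundamental_angular_frequency: float

    def __post_init__(self) -> None:
        self.modes = np.asarray(self.modes, dtype=complex)
        if abs(self.modes[0].imag) > 1e-9 * max(1.0, abs(self.modes[0])):
            raise ValueError("mode 0 must be real (mean flow)")
        self.modes[0] = self.modes[0].real
        if self.fundamental_angular_frequency <= 0:
            raise ValueError("fundamental frequency must be positive")

    @property
    def n_modes(self) -> int:
        return len(self.modes)

    @property
    def period(self) -> float:
        return 2 * np.pi / self.fundamental_angular_frequency


@dataclass
class OutletResistanceSpec:
    """Per-outlet resistances in indexed Wood units, with body surface area."""

    resistances: dict[str, float]
    bsa: float = 1.0

    def __post_init__(self) -> None:
        if not self.resistances:
            raise ValueError("at least one outlet is required")
        if any(r <= 0 for r in self.resistances.values()):
            raise ValueError("resistances must be positive")
        if self.bsa <= 0:
            raise ValueError("body surface area must be positive")


def steady_inflow(stroke_volume: float, heart_rate: float) -> float:
    """Steady inflow as stroke volume x heart rate, in cm^3/s.

    ``stroke_volume`` is the net ejected volume per beat in mL and
    ``heart_rate`` is in beats/min; the product (mL/min) is returned in
    cm^3/s.
    """
    if stroke_volume <= 0 or heart_rate <= 0:
        raise ValueError("stroke volume and heart rate must be positive")
    return stroke_volume * heart_rate / 60.0


def fourier_decompose(
    waveform: FlowWaveform, n_modes: int = DEFAULT_N_MODES
) -> FourierFlow:
    """Project a uniformly sampled waveform onto its first harmonics.

    Returns the least-squares truncated Fourier series: mode 0 is the mean
    and modes 1..n_modes-1 carry factor 2/N so that reconstruction takes
    the real part directly.
    """
    dt = np.diff(waveform.times)
    if len(dt) and not np.allclose(dt, dt[0], rtol=1e-8, atol=1e-12):
        raise ValueError("waveform must be uniformly sampled")
    n = len(waveform.flows)
    if n_modes > n // 2:
        raise ValueError("n_modes must not exceed n_samples / 2")
    spec = np.fft.rfft(waveform.flows) / n
    modes = np.zeros(n_modes, dtype=complex)
    modes[0] = spec[0].real
    modes[1:n_modes] = 2.0 * spec[1:n_modes]
    w0 = 2 * np.pi / waveform.period
    # sample times may start anywhere in the cycle; re-reference the phase
    modes[1:] *= np.exp(-1j * np.arange(1, n_modes) * w0 * waveform.times[0])
    return FourierFlow(modes=modes, fundamental_angular_frequency=w0)


def reconstruct_waveform(ff: FourierFlow, times: np.ndarray) -> np.ndarray:
    """Evaluate the truncated Fourier series at arbitrary times (cm^3/s)."""
    times = np.asarray(times, dtype=float)
    if not np.isfinite(times).all():
        raise ValueError("times must be finite")
    n = np.arange(ff.n_modes)
    phases = np.exp(1j * np.outer(times, n) * ff.fundamental_angular_frequency)
    return np.real(phases @ ff.modes)


def parabolic_profile(Q: float, radius: float, radial_position) -> np.ndarray | float:
    """Axial velocity of the parabolic (Poiseuille) inlet profile, cm/s.

    u(r) = 2Q/(pi R^2) (1 - r^2/R^2); zero at the wall (no slip), twice the
    mean velocity on the axis.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    r = np.asarray(radial_position, dtype=float)
    if np.any(r < 0) or np.any(r > radius):
        raise ValueError("radial position must lie in [0, radius]")
    u = 2.0 * Q / (np.pi * radius**2) * (1.0 - (r / radius) ** 2)
    return float(u) if np.isscalar(radial_position) else u


def resistance_network(
    spec: OutletResistanceSpec,
) -> tuple[float, dict[str, float]]:
    """Parallel combination of outlet resistances and the flow split.

    Two 2-iWU outlets combine to 1 iWU total for the lungs; flow to outlet
    i is proportional to its conductance 1/R_i (all outlets see the same
    distal pressure).
    """
    cond = {k: 1.0 / r for k, r in spec.resistances.items()}
    total_cond = sum(cond.values())
    fractions = {k: c / total_cond for k, c in cond.items()}
    return 1.0 / total_cond, fractions


def iwu_to_cgs(R_iwu: float, bsa: float) -> float:
    """Convert an indexed-Wood-unit resistance to dyn.s/cm^5.

    Indexing convention: iWU = WU x BSA, so the absolute resistance is
    R_iwu / BSA Wood units, each worth 1333.22 / 16.667 dyn.s/cm^5.
    """
    if R_iwu <= 0 or bsa <= 0:
        raise ValueError("resistance and BSA must be positive")
    return R_iwu / bsa * WOOD_UNIT_CGS


def find_systole_diastole(flows: np.ndarray) -> tuple[int, int]:
    """Indices of the maximum (systolic) and minimum (diastolic) inflow.

    Operates on the discrete output timepoints (20 per cycle by default);
    ties resolve to the earliest index.
    """
    flows = np.asarray(flows, dtype=float)
    if len(flows) < 2:
        raise ValueError("need at least 2 timepoints")
    if np.ptp(flows) == 0:
        warnings.warn("constant flow: systole and diastole both at index 0")
        return 0, 0
    return int(np.argmax(flows)), int(np.argmin(flows))


def regurgitant_fraction(waveform: FlowWaveform) -> float:
    """Reverse volume over forward volume, RF = V_rev / V_fwd."""
    fwd = waveform.forward_volume()
    if fwd <= 0:
        raise ValueError("waveform has no forward flow; RF undefined")
    return waveform.reverse_volume() / fwd
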