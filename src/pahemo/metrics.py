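"""Focal hemodynamic metrics from wall-shear fields.

For each wall point x over one cardiac cycle of length T:

    taWSS(x) = (1/T) int_0^T |WSS(x, t)| dt
    OSI(x)   = 1/2 (1 - |int_0^T WSS(x, t) dt| / int_0^T |WSS(x, t)| dt)

with vector-valued WSS, periodic trapezoidal quadrature on the uniform
output timepoints, and the convention taWSS averages the magnitude. OSI is
0 when the shear never changes direction and 0.5 (its maximum) when the
shear fully reverses with zero mean. Per-segment summaries report the
area-weighted average and the pointwise peak over the MPA, LPA, RPA and
whole vessel, after extensions have been trimmed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .centerline import BRANCH_ORDER, SegmentLabeling
from .engine import SteadyWSSField, WSSTimeSeriesField
from .flow import FlowWaveform, find_systole_diastole

REGIONS = ("whole",) + BRANCH_ORDER


@dataclass
class OSIField:
    """Oscillatory shear index per wall point, in [0, 0.5]."""

    osi: np.ndarray

    def __post_init__(self) -> None:
        self.osi = np.asarray(self.osi, dtype=float)
        if np.any(self.osi < -1e-12) or np.any(self.osi > 0.5 + 1e-12):
            raise ValueError("OSI must lie in [0, 0.5]")
        self.osi = np.clip(self.osi, 0.0, 0.5)


@dataclass
class HemodynamicSummary:
    """Per-region metric table for one case.

    ``values[region][metric]`` with regions whole/MPA/LPA/RPA and metrics
    like ``WSS_steady_avg`` (dynes/cm^2) or ``OSI_avg`` (dimensionless).
    ``metadata`` records the systolic/diastolic timepoint indices used.
    """

    values: dict[str, dict[str, float]]
    metadata: dict = field(default_factory=dict)

    def to_tidy(self):
        """Long-format (region, metric, value) pandas DataFrame."""
        import pandas as pd

        rows = [
            {"region": region, "metric": metric, "value": value}
            for region, metrics in self.values.items()
            for metric, value in metrics.items()
        ]
        return pd.DataFrame(rows)


def _periodic_time_integral(values: np.ndarray, times: np.ndarray) -> np.ndarray:
    """Trapezoidal integral over one period with the closure sample.

    ``values`` has the time axis at position 1, shape (P, T) or (P, T, 3).
    On uniform samples of a periodic signal this reduces to mean * T,
    which is spectrally accurate for band-limited integrands.
    """
    dt = times[1] - times[0]
    T = times[-1] - times[0] + dt
    closed = np.concatenate([values, values[:, :1]], axis=1)
    t_closed = np.append(times, times[0] + T)
    return np.trapezoid(closed, t_closed, axis=1)


def osi_field(field: WSSTimeSeriesField) -> OSIField:
    """Oscillatory shear index at every wall point."""
    if field.n_times < 2:
        raise ValueError("OSI needs at least 2 timepoints spanning the cycle")
    num = np.linalg.norm(
        _periodic_time_integral(field.vectors, field.times), axis=-1
    )
    mags = np.linalg.norm(field.vectors, axis=-1)
    den = _periodic_time_integral(mags, field.times)
    osi = np.zeros(field.n_points)
    zero = den <= 0
    if zero.any():
        warnings.warn("identically zero shear at some points; OSI set to 0 there")
    nz = ~zero
    osi[nz] = 0.5 * (1.0 - num[nz] / den[nz])
    return OSIField(osi=osi)


def tawss_field(field: WSSTimeSeriesField) -> np.ndarray:
    """Time-averaged wall-shear magnitude per point (dynes/cm^2)."""
    if field.n_times < 2:
        raise ValueError("taWSS needs at least 2 timepoints spanning the cycle")
    mags = np.linalg.norm(field.vectors, axis=-1)
    T = field.times[-1] - field.times[0] + (field.times[1] - field.times[0])
    return _periodic_time_integral(mags, field.times) / T


def wss_at_timepoint(field: WSSTimeSeriesField, index: int) -> np.ndarray:
    """Shear magnitude per point at one output timepoint."""
    if not 0 <= index < field.n_times:
        raise IndexError(f"timepoint index {index} out of range [0, {field.n_times})")
    return np.linalg.norm(field.vectors[:, index, :], axis=-1)


def segment_summary(
    scalars: np.ndarray,
    labeling: SegmentLabeling,
    peak_percentile: float | None = None,
) -> dict[str, tuple[float, float]]:
    """Area-weighted average and pointwise peak per region.

    Returns ``{region: (avg, peak)}`` for the whole vessel and each branch
    present; extension points must already be trimmed away (the whole
    vessel is the MPA+LPA+RPA union). ``peak_percentile`` replaces the max
    by a percentile to probe outlier sensitivity.
    """
    scalars = np.asarray(scalars, dtype=float)
    if len(scalars) != len(labeling.labels):
        raise ValueError("scalars length does not match labeling")
    if (labeling.labels == "extension").any():
        raise ValueError("trim extensions before summarizing")

    def _peak(v: np.ndarray) -> float:
        if peak_percentile is not None:
            return float(np.percentile(v, peak_percentile))
        return float(v.max())

    out: dict[str, tuple[float, float]] = {}
    masks = {"whole": np.ones(len(scalars), dtype=bool)}
    masks.update({b: labeling.mask(b) for b in BRANCH_ORDER})
    for region, mask in masks.items():
        if not mask.any():
            continue  # empty region reported as missing, never as zero
        w = labeling.areas[mask]
        v = scalars[mask]
        out[region] = (float(np.average(v, weights=w)), _peak(v))
    return out


def summarize_case(
    steady: SteadyWSSField | None,
    pulsatile: WSSTimeSeriesField | None,
    waveform: FlowWaveform | None = None,
    inflow_at_timepoints: np.ndarray | None = None,
) -> HemodynamicSummary:
    """Assemble the per-region metric table for one case.

    Populates WSS_steady, taWSS, WSS_systole, WSS_diastole (avg and peak
    each) and OSI_avg for whole/MPA/LPA/RPA. Systole and diastole are
    located on the inflow sampled at the pulsatile output timepoints
    (``inflow_at_timepoints``, or the waveform resampled there). A missing
    pulsatile input yields a steady-only summary.
    """
    values: dict[str, dict[str, float]] = {r: {} for r in REGIONS}
    metadata: dict = {}

    def _store(name: str, scalars: np.ndarray, labeling: SegmentLabeling) -> None:
        for region, (avg, peak) in segment_summary(scalars, labeling).items():
            values[region][f"{name}_avg"] = avg
            values[region][f"{name}_peak"] = peak

    if steady is not None:
        if steady.labeling is None:
            raise ValueError("steady field lacks a segment labeling")
        _store("WSS_steady", steady.scalars, steady.labeling)

    if pulsatile is not None:
        lab = pulsatile.labeling
        if lab is None:
            raise ValueError("pulsatile field lacks a segment labeling")
        _store("taWSS", tawss_field(pulsatile), lab)

        if inflow_at_timepoints is None and waveform is not None:
            inflow_at_timepoints = np.interp(
                pulsatile.times,
                np.append(waveform.times, waveform.times[0] + waveform.period),
                np.append(waveform.flows, waveform.flows[0]),
            )
        if inflow_at_timepoints is not None:
            i_sys, i_dia = find_systole_diastole(inflow_at_timepoints)
            metadata["systole_index"] = i_sys
            metadata["diastole_index"] = i_dia
            _store("WSS_systole", wss_at_timepoint(pulsatile, i_sys), lab)
            _store("WSS_diastole", wss_at_timepoint(pulsatile, i_dia), lab)

        osi = osi_field(pulsatile).osi
        for region, (avg, _) in segment_summary(osi, lab).items():
            values[region]["OSI_avg"] = avg

    values = {r: m for r, m in values.items() if m}
    return HemodynamicSummary(values=values, metadata=metadata)
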