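"""Analytic pulsatile wall-shear engine.

A locally-cylindrical surrogate for a full 3D hemodynamics solve: every
wall point sees the shear of fully developed pipe flow in a tube whose
radius is the point's distance to the nearest centerline sample, driven by
the flow its branch receives from the resistance split. The steady
component is Poiseuille,

    tau_w = 4 mu Q / (pi R^3),

and each flow harmonic Q_n e^{i n w t} contributes the Womersley
flow-forced oscillatory solution, whose wall shear is

    tau_n = -mu (Q_n / (pi R^2)) (L / R) J1(L) / J0(L)
            / (1 - 2 J1(L) / (L J0(L))),   L = i^{3/2} alpha_n,

with Womersley number alpha_n = R sqrt(n w rho / mu). The superposition is
emitted at its periodic steady state on 20 uniform timepoints per cycle.
Externally computed shear fields (e.g. from a finite-element solver) can
be imported instead through :func:`load_external_wss_series`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.special import jv

from .centerline import CenterlinePolyline, SegmentLabeling
from .flow import FluidProperties, FourierFlow
from .mesh import SurfaceMesh

#: number of evenly spaced output timepoints per cardiac cycle
DEFAULT_N_TIMEPOINTS = 20

#: above this Womersley number the Bessel ratio is replaced by its
#: large-argument asymptote (J1/J0 -> i) to avoid overflow
WOMERSLEY_ASYMPTOTIC_ALPHA = 100.0


@dataclass
class SteadyWSSField:
    """Scalar wall-shear magnitudes (dynes/cm^2) from a steady solve."""

    wall_points: np.ndarray
    areas: np.ndarray
    scalars: np.ndarray
    labeling: SegmentLabeling | None = None

    def __post_init__(self) -> None:
        self.scalars = np.asarray(self.scalars, dtype=float)
        if np.any(self.scalars < 0):
            raise ValueError("steady WSS magnitudes must be non-negative")


@dataclass
class WSSTimeSeriesField:
    """Wall-shear vectors per point per timepoint (dynes/cm^2).

    ``vectors`` has shape (n_points, n_times, 3); ``times`` spans one
    cardiac cycle.
    """

    wall_points: np.ndarray
    areas: np.ndarray
    times: np.ndarray
    vectors: np.ndarray
    labeling: SegmentLabeling | None = None

    def __post_init__(self) -> None:
        self.wall_points = np.asarray(self.wall_points, dtype=float)
        self.areas = np.asarray(self.areas, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        self.vectors = np.asarray(self.vectors, dtype=float)
        if self.vectors.shape != (len(self.wall_points), len(self.times), 3):
            raise ValueError("vectors must have shape (n_points, n_times, 3)")
        if len(self.times) < 1:
            raise ValueError("need at least one timepoint")
        if not np.isfinite(self.vectors).all():
            raise ValueError("shear vectors must be finite")
        if np.any(self.areas <= 0):
            raise ValueError("areas must be positive")

    @property
    def n_points(self) -> int:
        return len(self.wall_points)

    @property
    def n_times(self) -> int:
        return len(self.times)


def poiseuille_wall_shear(Q: float, radius: float, fluid: FluidProperties) -> float:
    """Steady wall shear 4 mu Q / (pi R^3); sign follows the flow."""
    if radius <= 0:
        raise ValueError("radius must be positive")
    return 4.0 * fluid.viscosity * Q / (np.pi * radius**3)


def womersley_number(
    radius: float, angular_frequency: float, fluid: FluidProperties
) -> float:
    """alpha = R sqrt(w rho / mu)."""
    return radius * np.sqrt(angular_frequency * fluid.density / fluid.viscosity)


def _womersley_shear_coefficient(radius, n: int, w0: float, fluid: FluidProperties):
    """Complex wall-shear per unit complex flow for harmonic n >= 1.

    tau_n = coeff * Q_n with the wall-shear sign convention of
    :func:`poiseuille_wall_shear` (positive shear for positive flow).
    Accepts scalar or array radii.
    """
    scalar = np.isscalar(radius) or np.ndim(radius) == 0
    radius = np.atleast_1d(np.asarray(radius, dtype=float))
    alpha = womersley_number(radius, n * w0, fluid)
    lam = 1j**1.5 * alpha
    ratio = np.empty_like(lam)
    big = alpha > WOMERSLEY_ASYMPTOTIC_ALPHA
    ratio[big] = 1j  # J1(z)/J0(z) -> i for large |z| with Im z > 0
    ratio[~big] = jv(1, lam[~big]) / jv(0, lam[~big])
    denom = 1.0 - 2.0 * ratio / lam
    coeff = -fluid.viscosity / (np.pi * radius**2) * (lam / radius) * ratio / denom
    return complex(coeff[0]) if scalar else coeff


def womersley_wall_shear(
    ff: FourierFlow,
    radius: float,
    fluid: FluidProperties,
    times: np.ndarray,
) -> np.ndarray:
    """Signed axial wall shear of pulsatile pipe flow at the given times.

    Mode 0 contributes the Poiseuille shear of the mean flow; each
    harmonic adds its flow-forced Womersley wall shear. In the low
    Womersley-number limit this reduces to the quasi-static Poiseuille
    shear of the instantaneous flow.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    times = np.asarray(times, dtype=float)
    w0 = ff.fundamental_angular_frequency
    tau = np.full(times.shape, poiseuille_wall_shear(ff.modes[0].real, radius, fluid))
    for n in range(1, ff.n_modes):
        coeff = _womersley_shear_coefficient(radius, n, w0, fluid)
        tau = tau + np.real(coeff * ff.modes[n] * np.exp(1j * n * w0 * times))
    return tau


def _nearest_centerline(
    points: np.ndarray, line: CenterlinePolyline
) -> tuple[np.ndarray, np.ndarray]:
    """(distance, unit tangent) at the nearest centerline sample."""
    d = np.linalg.norm(points[:, None, :] - line.points[None, :, :], axis=2)
    idx = d.argmin(axis=1)
    tangents = line.tangents()
    return d[np.arange(len(points)), idx], tangents[idx]


def synthesize_wss_field(
    mesh: SurfaceMesh,
    labeling: SegmentLabeling,
    centerlines: dict[str, CenterlinePolyline],
    ff: FourierFlow,
    fluid: FluidProperties,
    flow_fractions: dict[str, float] | None = None,
    n_timepoints: int = DEFAULT_N_TIMEPOINTS,
) -> WSSTimeSeriesField:
    """Womersley shear time series over a labeled vessel wall.

    Each point's local radius is its distance to the nearest sample of its
    branch centerline, the shear vector is directed along the local
    centerline tangent with the sign of the instantaneous flow, and the
    branch flow is the inlet flow scaled by the resistance-split fraction
    (the MPA trunk carries the full inlet flow).
    """
    if flow_fractions is None:
        flow_fractions = {"LPA": 0.5, "RPA": 0.5}
    times = np.arange(n_timepoints) * ff.period / n_timepoints
    vectors = np.zeros((mesh.n_points, n_timepoints, 3))
    w0 = ff.fundamental_angular_frequency

    for branch, line in centerlines.items():
        mask = labeling.mask(branch)
        if not mask.any():
            continue
        radii, tangents = _nearest_centerline(mesh.points[mask], line)
        bad = radii <= 0
        if bad.any():
            warnings.warn("wall points coincide with the centerline; using branch median radius")
            radii[bad] = np.median(radii[~bad]) if (~bad).any() else 1.0
        frac = 1.0 if branch == "MPA" else flow_fractions.get(branch, 1.0)
        # shared time phases for all harmonics
        tau = np.empty((mask.sum(), n_timepoints))
        tau[:] = 4.0 * fluid.viscosity * frac * ff.modes[0].real / (
            np.pi * radii[:, None] ** 3
        )
        for n in range(1, ff.n_modes):
            coeff = _womersley_shear_coefficient(radii, n, w0, fluid)
            tau += np.real(
                np.outer(coeff * frac * ff.modes[n], np.exp(1j * n * w0 * times))
            )
        vectors[mask] = tau[:, :, None] * tangents[:, None, :]

    return WSSTimeSeriesField(
        wall_points=mesh.points,
        areas=labeling.areas,
        times=times,
        vectors=vectors,
        labeling=labeling,
    )


def steady_field_from_series(field: WSSTimeSeriesField, index: int = 0) -> SteadyWSSField:
    """Steady scalar field from one timepoint of a series (|vector|)."""
    if not 0 <= index < field.n_times:
        raise IndexError("timepoint index out of range")
    return SteadyWSSField(
        wall_points=field.wall_points,
        areas=field.areas,
        scalars=np.linalg.norm(field.vectors[:, index, :], axis=1),
        labeling=field.labeling,
    )


def synthesize_steady_wss_field(
    mesh: SurfaceMesh,
    labeling: SegmentLabeling,
    centerlines: dict[str, CenterlinePolyline],
    Q: float,
    fluid: FluidProperties,
    flow_fractions: dict[str, float] | None = None,
) -> SteadyWSSField:
    """Poiseuille wall-shear magnitudes for a steady inflow Q (cm^3/s)."""
    ff = FourierFlow(
        modes=np.array([Q], dtype=complex), fundamental_angular_frequency=2 * np.pi
    )
    series = synthesize_wss_field(
        mesh, labeling, centerlines, ff, fluid, flow_fractions, n_timepoints=1
    )
    return steady_field_from_series(series, 0)


def load_external_wss_series(files: list) -> WSSTimeSeriesField:
    """Assemble a shear time series from per-timepoint surface files.

    Files (VTP-style XML written by :func:`pahemo.io.write_vtp_surface`,
    with a per-point ``WSS`` vector array and a ``TimeValue`` annotation)
    are sorted by their embedded time; all must share point count and
    ordering.
    """
    from .io import read_vtp_surface  # local import to avoid a cycle

    if not files:
        raise ValueError("no files given")
    frames = []
    for f in files:
        mesh, arrays, time = read_vtp_surface(f)
        if "WSS" not in arrays:
            raise ValueError(f"{f}: missing per-point 'WSS' vector array")
        if time is None:
            raise ValueError(f"{f}: missing TimeValue annotation")
        frames.append((time, mesh, arrays["WSS"], arrays))
    frames.sort(key=lambda fr: fr[0])
    n0 = frames[0][1].n_points
    for f, (_, mesh, _, _) in zip(files, frames):
        if mesh.n_points != n0:
            raise ValueError(f"{f}: point count differs from the first file")
    mesh = frames[0][1]
    arrays0 = frames[0][3]
    if "Area" in arrays0:
        areas = arrays0["Area"]
    else:
        areas = mesh.vertex_areas()
    labeling = None
    if "Label" in arrays0:
        labeling = SegmentLabeling(labels=arrays0["Label"], areas=areas)
    times = np.array([fr[0] for fr in frames])
    vectors = np.stack([fr[2] for fr in frames], axis=1)
    return WSSTimeSeriesField(
        wall_points=mesh.points,
        areas=areas,
        times=times,
        vectors=vectors,
        labeling=labeling,
    )
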