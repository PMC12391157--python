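"""Synthetic stand-ins for patient pulmonary-artery data.

Three generators with known ground truth:

* tubular surface meshes around parametric centerlines, and a
  three-branch PA bifurcation (MPA trunk, curvier/narrower LPA, wider
  RPA) with exact centerlines and wall labels;
* pulsatile flow waveforms with controllable heart rate, forward stroke
  volume and regurgitant fraction (biphasic raised-cosine lobes: a
  systolic forward lobe and a diastolic reverse lobe), defaulting to the
  severe-regurgitation regime of repaired tetralogy of Fallot
  (RF = 0.40);
* patient cohorts with configurable linear outcome effects and
  log-hazards driving time to pulmonic valve replacement, for exercising
  the association-statistics stages against known truth.

All randomness flows from a single integer seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd

from .centerline import (
    CenterlinePolyline,
    SegmentLabeling,
    curvature_profile,
    resample_centerline,
)
from .flow import FlowWaveform
from .mesh import SurfaceMesh, merge_meshes

# -- geometry ----------------------------------------------------------------


@dataclass
class TubeSpec:
    """Parametric tube: centerline curve on [0, 1] plus a radius profile.

    ``centerline_fn`` maps parameter t in [0, 1] to a 3D point (cm);
    ``radius_profile`` maps arclength (cm) to radius (cm), or is a
    constant.
    """

    centerline_fn: Callable[[np.ndarray], np.ndarray]
    radius_profile: Callable[[np.ndarray], np.ndarray] | float = 1.0
    axial_samples: int = 60
    circumferential_samples: int = 24

    def __post_init__(self) -> None:
        if self.axial_samples < 4:
            raise ValueError("axial_samples must be >= 4")
        if self.circumferential_samples < 8:
            raise ValueError("circumferential_samples must be >= 8")

    def radii(self, arclength: np.ndarray) -> np.ndarray:
        if callable(self.radius_profile):
            r = np.asarray(self.radius_profile(arclength), dtype=float)
        else:
            r = np.full_like(np.asarray(arclength, dtype=float), self.radius_profile)
        if np.any(r <= 0):
            raise ValueError("radius must be positive everywhere")
        return r


@dataclass
class PABifurcationSpec:
    """Three-branch pulmonary-artery geometry: MPA trunk, LPA and RPA.

    Branch centerlines must originate at ``junction_point`` where the MPA
    centerline ends.
    """

    mpa: TubeSpec
    lpa: TubeSpec
    rpa: TubeSpec
    junction_point: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.junction_point = np.asarray(self.junction_point, dtype=float)
        for name, tube in (("mpa", self.mpa), ("lpa", self.lpa), ("rpa", self.rpa)):
            endpoint = tube.centerline_fn(np.array([1.0 if name == "mpa" else 0.0]))[0]
            if np.linalg.norm(endpoint - self.junction_point) > 1e-6:
                raise ValueError(f"{name} centerline does not meet the junction point")


def _parallel_transport_frames(points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Twist-minimizing normal/binormal frames along a polyline."""
    tangents = np.gradient(points, axis=0)
    tangents /= np.linalg.norm(tangents, axis=1, keepdims=True)
    normals = np.empty_like(tangents)
    ref = np.array([0.0, 0.0, 1.0])
    if abs(tangents[0] @ ref) > 0.9:
        ref = np.array([1.0, 0.0, 0.0])
    n = ref - (ref @ tangents[0]) * tangents[0]
    normals[0] = n / np.linalg.norm(n)
    for i in range(1, len(points)):
        # rotate the previous normal by the rotation taking t_{i-1} to t_i
        v = np.cross(tangents[i - 1], tangents[i])
        c = float(tangents[i - 1] @ tangents[i])
        if np.linalg.norm(v) < 1e-14:
            normals[i] = normals[i - 1]
        else:
            vx = np.array(
                [[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]]
            )
            R = np.eye(3) + vx + vx @ vx / (1.0 + c)
            normals[i] = R @ normals[i - 1]
        n = normals[i] - (normals[i] @ tangents[i]) * tangents[i]
        normals[i] = n / np.linalg.norm(n)
    binormals = np.cross(tangents, normals)
    return normals, binormals


def make_tube_geometry(spec: TubeSpec) -> tuple[SurfaceMesh, CenterlinePolyline]:
    """Triangulated tube around the spec's centerline.

    Every surface vertex lies exactly at the local radius from its
    centerline station, and the returned centerline is the exact sampled
    spec curve. Raises if the tube would self-intersect (radius exceeding
    the local curvature radius).
    """
    t = np.linspace(0.0, 1.0, spec.axial_samples)
    pts = np.asarray(spec.centerline_fn(t), dtype=float)
    line = CenterlinePolyline(pts)
    radii = spec.radii(line.arclength)

    kappa = curvature_profile(resample_centerline(line)).kappa
    if kappa.size and (kappa.max() * radii.max()) >= 1.0:
        raise ValueError(
            "tube self-intersects: radius exceeds the local curvature radius"
        )

    normals, binormals = _parallel_transport_frames(pts)
    theta = np.linspace(0.0, 2 * np.pi, spec.circumferential_samples, endpoint=False)
    ring = (
        np.cos(theta)[None, :, None] * normals[:, None, :]
        + np.sin(theta)[None, :, None] * binormals[:, None, :]
    )
    vertices = (pts[:, None, :] + radii[:, None, None] * ring).reshape(-1, 3)

    na, nc = spec.axial_samples, spec.circumferential_samples
    faces = []
    for i in range(na - 1):
        base = i * nc
        nxt = base + nc
        j = np.arange(nc)
        j1 = (j + 1) % nc
        faces.append(np.stack([base + j, base + j1, nxt + j1], axis=1))
        faces.append(np.stack([base + j, nxt + j1, nxt + j], axis=1))
    return SurfaceMesh(vertices, np.vstack(faces)), line


def _arc_centerline(
    start: np.ndarray,
    direction: np.ndarray,
    turn_axis: np.ndarray,
    curvature: float,
    length: float,
) -> Callable[[np.ndarray], np.ndarray]:
    """Circular-arc curve of given curvature; straight if curvature = 0."""
    start = np.asarray(start, dtype=float)
    d = np.asarray(direction, dtype=float)
    d = d / np.linalg.norm(d)
    n = np.cross(np.asarray(turn_axis, dtype=float), d)
    n = n / np.linalg.norm(n)

    def fn(t: np.ndarray) -> np.ndarray:
        s = np.asarray(t, dtype=float) * length
        if curvature == 0:
            return start[None, :] + s[:, None] * d[None, :]
        return (
            start[None, :]
            + (np.sin(curvature * s) / curvature)[:, None] * d[None, :]
            + ((1 - np.cos(curvature * s)) / curvature)[:, None] * n[None, :]
        )

    return fn


def default_pa_spec(
    mpa_radius: float = 1.5,
    lpa_radius: float = 0.8,
    rpa_radius: float = 1.0,
    lpa_curvature: float = 0.9,
    rpa_curvature: float = 0.6,
    mpa_length: float = 4.0,
    branch_length: float = 3.0,
) -> PABifurcationSpec:
    """A plausible repaired-ToF pulmonary bifurcation.

    Defaults encode the cohort-typical ordering: the LPA is the narrowest
    and most curved branch, the RPA intermediate, the MPA the widest
    trunk; branch curvatures bracket the cohort medians (LPA ~0.97,
    RPA ~0.82 cm^-1 territory).
    """
    junction = np.array([0.0, 0.0, mpa_length])
    mpa_fn = _arc_centerline(
        np.zeros(3), np.array([0.0, 0.0, 1.0]), np.array([0.0, 1.0, 0.0]),
        0.0, mpa_length,
    )
    lpa_fn = _arc_centerline(
        junction, np.array([-0.45, 0.1, 0.89]), np.array([0.0, -1.0, 0.0]),
        lpa_curvature, branch_length,
    )
    rpa_fn = _arc_centerline(
        junction, np.array([0.45, -0.1, 0.89]), np.array([0.0, 1.0, 0.0]),
        rpa_curvature, branch_length,
    )
    return PABifurcationSpec(
        mpa=TubeSpec(mpa_fn, mpa_radius),
        lpa=TubeSpec(lpa_fn, lpa_radius),
        rpa=TubeSpec(rpa_fn, rpa_radius),
        junction_point=junction,
    )


def make_pa_bifurcation(
    spec: PABifurcationSpec,
) -> tuple[SurfaceMesh, dict[str, CenterlinePolyline], SegmentLabeling]:
    """Three-branch PA wall mesh with ground-truth centerlines and labels.

    The trunk and branch tubes are concatenated into one mesh; the MPA
    inlet and the two branch outlets remain open, and the junction rings
    meet at the shared junction point. Ground-truth labels record which
    tube generated each wall point.
    """
    mpa_mesh, mpa_line = make_tube_geometry(spec.mpa)
    lpa_mesh, lpa_line = make_tube_geometry(spec.lpa)
    rpa_mesh, rpa_line = make_tube_geometry(spec.rpa)

    for name, tube, line in (
        ("lpa", spec.lpa, lpa_line),
        ("rpa", spec.rpa, rpa_line),
    ):
        if tube.radii(line.arclength)[0] >= spec.mpa.radii(mpa_line.arclength)[-1] * 1.5:
            raise ValueError(f"{name} radius infeasible at the junction")

    mesh, source = merge_meshes([mpa_mesh, lpa_mesh, rpa_mesh])
    labels = np.array(["MPA", "LPA", "RPA"], dtype="<U16")[source]
    labeling = SegmentLabeling(labels=labels, areas=mesh.vertex_areas())
    centerlines = {"MPA": mpa_line, "LPA": lpa_line, "RPA": rpa_line}
    return mesh, centerlines, labeling


# -- waveform ----------------------------------------------------------------


@dataclass
class WaveformSpec:
    """Pulsatile MPA flow: biphasic raised-cosine lobes.

    A systolic forward lobe carrying ``forward_volume`` mL and a diastolic
    reverse lobe carrying ``regurgitant_fraction x forward_volume`` mL,
    over one cycle of 60/heart_rate seconds.
    """

    heart_rate: float = 75.0  # beats/min
    forward_volume: float = 100.0  # mL per beat
    regurgitant_fraction: float = 0.40  # cohort-median severe PR
    n_samples: int = 200
    systolic_fraction: float = 0.35
    reverse_fraction: float = 0.45

    def __post_init__(self) -> None:
        if self.heart_rate <= 0 or self.forward_volume <= 0:
            raise ValueError("heart rate and forward volume must be positive")
        if not 0 <= self.regurgitant_fraction < 1:
            raise ValueError("regurgitant fraction must lie in [0, 1)")
        if self.n_samples < 16:
            raise ValueError("n_samples must be >= 16")
        if self.systolic_fraction + self.reverse_fraction >= 1:
            raise ValueError("lobe fractions must leave a diastasis gap")


def make_flow_waveform(spec: WaveformSpec) -> FlowWaveform:
    """One uniformly sampled cycle with the prescribed volumes.

    The forward lobe is A_f (1 - cos(2 pi t / T_s)) / 2 on [0, T_s] and
    the reverse lobe mirrors it on [T_s, T_s + T_r]; amplitudes are set so
    the lobes integrate exactly to the forward and regurgitant volumes.
    """
    T = 60.0 / spec.heart_rate
    times = np.arange(spec.n_samples) * T / spec.n_samples
    Ts = spec.systolic_fraction * T
    Tr = spec.reverse_fraction * T
    Af = 2.0 * spec.forward_volume / Ts
    Ar = 2.0 * spec.regurgitant_fraction * spec.forward_volume / Tr

    flows = np.zeros_like(times)
    in_sys = times < Ts
    flows[in_sys] = Af * 0.5 * (1.0 - np.cos(2 * np.pi * times[in_sys] / Ts))
    in_rev = (times >= Ts) & (times < Ts + Tr)
    flows[in_rev] = -Ar * 0.5 * (1.0 - np.cos(2 * np.pi * (times[in_rev] - Ts) / Tr))
    return FlowWaveform(times=times, flows=flows, heart_rate=spec.heart_rate)


# -- cohort ------------------------------------------------------------------

RV_METRIC_BASELINES = {  # median-scale anchors for a repaired-ToF cohort
    "RVEDVi": (145.0, 30.0),  # mL/m^2
    "RVESVi": (64.6, 20.0),
    "RVSVi": (70.8, 18.0),
    "RVEF": (56.6, 7.0),  # %
}

DEFAULT_PREDICTORS = {  # name: (mean, sd), dynes/cm^2 scale of the whole vessel
    "wss_steady_avg": (6.16, 2.0),
    "osi_avg": (0.214, 0.03),
}


@dataclass
class CohortSpec:
    """Synthetic patient cohort with known effect structure.

    ``linear_effects`` maps predictor name to its true coefficient on the
    linear outcome (outcome units per predictor unit); ``log_hazards``
    maps predictor name to the true log-hazard per unit on time to
    pulmonic valve replacement. Predictors are drawn as independent
    normals with the given (mean, sd).
    """

    n_patients: int = 100
    linear_effects: dict[str, float] = field(default_factory=dict)
    log_hazards: dict[str, float] = field(default_factory=dict)
    covariate_effects: dict[str, float] = field(
        default_factory=lambda: {"sex": 0.0, "age_at_cmr1": 0.0, "age_at_cmr2": 0.0}
    )
    predictors: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_PREDICTORS)
    )
    outcome: str = "RVEDVi"
    noise_sd: float = 10.0
    censoring_rate: float = 0.3
    baseline_median_days: float = 1500.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 2:
            raise ValueError("need at least 2 patients")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if not 0 <= self.censoring_rate <= 1:
            raise ValueError("censoring_rate must lie in [0, 1]")


def make_synthetic_cohort(spec: CohortSpec) -> tuple[pd.DataFrame, pd.DataFrame]:
    """(cohort table, survival records) with the spec's effect structure.

    The linear outcome is its population anchor plus centered predictor
    effects, covariate effects and Gaussian noise. Event times are
    exponential with hazard exp(sum log_hazard x centered predictor)
    around a baseline tuned to ``baseline_median_days``; censoring is an
    independent exponential calibrated to the requested censored
    fraction.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_patients

    sex = (rng.random(n) < 0.59).astype(int)  # 1 = female, cohort majority
    age1 = np.clip(rng.normal(12.0, 5.0, n), 1.0, 40.0)
    gap = np.clip(rng.normal(3.5, 1.0, n), 0.5, None)
    age2 = age1 + gap

    cohort = pd.DataFrame({"sex": sex, "age_at_cmr1": age1, "age_at_cmr2": age2})

    centered = {}
    for name, (mean, sd) in spec.predictors.items():
        x = rng.normal(mean, sd, n)
        cohort[name] = x
        centered[name] = x - mean
    for name in set(spec.linear_effects) | set(spec.log_hazards):
        if name not in cohort:
            raise ValueError(f"effect requested for unknown predictor {name!r}")
        if np.std(cohort[name].to_numpy()) == 0:
            warnings.warn(f"predictor {name!r} is constant; its effect is unidentifiable")

    pulm_rf = np.clip(rng.normal(0.40, 0.11, n), 0.0, 0.95)
    cohort["pulmonary_rf"] = pulm_rf

    for metric, (anchor, sd) in RV_METRIC_BASELINES.items():
        if metric == spec.outcome:
            continue
        cohort[metric] = rng.normal(anchor, sd, n)

    anchor, _ = RV_METRIC_BASELINES.get(spec.outcome, (0.0, 1.0))
    lin = np.full(n, anchor)
    lin += spec.covariate_effects.get("sex", 0.0) * sex
    lin += spec.covariate_effects.get("age_at_cmr1", 0.0) * (age1 - 12.0)
    lin += spec.covariate_effects.get("age_at_cmr2", 0.0) * (age2 - 15.5)
    for name, coef in spec.linear_effects.items():
        lin += coef * centered[name]
    cohort[spec.outcome] = lin + rng.normal(0.0, spec.noise_sd, n)

    # survival: exponential event times under individual log-hazards
    log_hr = np.zeros(n)
    for name, lh in spec.log_hazards.items():
        log_hr += lh * centered[name]
    lam0 = np.log(2.0) / spec.baseline_median_days
    lam = lam0 * np.exp(log_hr)
    event_time = rng.exponential(1.0 / lam)
    if spec.censoring_rate > 0 and spec.censoring_rate < 1:
        lam_c = lam.mean() * spec.censoring_rate / (1.0 - spec.censoring_rate)
        censor_time = rng.exponential(1.0 / lam_c, n)
    elif spec.censoring_rate == 0:
        censor_time = np.full(n, np.inf)
    else:
        censor_time = rng.uniform(1.0, spec.baseline_median_days, n)
        censor_time = np.minimum(censor_time, event_time * 0.99)
    observed = np.minimum(event_time, censor_time)
    event = event_time <= censor_time

    survival = pd.DataFrame(
        {
            "time_to_event": np.maximum(observed, 1.0),
            "event": event.astype(int),
            "sex": sex,
            "age_at_cmr": age1,
        }
    )
    for name in spec.predictors:
        survival[name] = cohort[name]
    return cohort, survival
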