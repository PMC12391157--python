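import numpy as np
import pytest

from pahemo import FluidProperties
from pahemo.centerline import CenterlinePolyline
from pahemo.synthetic import (
    WaveformSpec,
    default_pa_spec,
    make_flow_waveform,
    make_pa_bifurcation,
)


@pytest.fixture(scope="session")
def fluid():
    return FluidProperties()


@pytest.fixture(scope="session")
def pa_case():
    """Default synthetic bifurcation: (spec, mesh, centerlines, truth labels)."""
    spec = default_pa_spec()
    mesh, centerlines, truth = make_pa_bifurcation(spec)
    return spec, mesh, centerlines, truth


@pytest.fixture(scope="session")
def rtof_waveform():
    """Cohort-typical regurgitant waveform (HR 75, 100 mL forward, RF 0.40)."""
    return make_flow_waveform(WaveformSpec())


def circle_polyline(radius: float, n: int = 200, arc: float = np.pi) -> CenterlinePolyline:
    """Planar arc of the given radius spanning `arc` radians."""
    t = np.linspace(0.0, arc, n)
    pts = np.column_stack(
        [radius * np.cos(t), radius * np.sin(t), np.zeros_like(t)]
    )
    return CenterlinePolyline(pts)


def helix_polyline(r: float, c: float, n: int = 400, turns: float = 2.0) -> CenterlinePolyline:
    """Helix x=r cos t, y=r sin t, z=c t, with curvature r/(r^2+c^2)."""
    t = np.linspace(0.0, 2 * np.pi * turns, n)
    pts = np.column_stack([r * np.cos(t), r * np.sin(t), c * t])
    return CenterlinePolyline(pts)


def straight_polyline(length: float = 5.0, n: int = 51) -> CenterlinePolyline:
    pts = np.column_stack(
        [np.linspace(0, length, n), np.zeros(n), np.zeros(n)]
    )
    return CenterlinePolyline(pts)
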