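"""Centerline geometry: curvature and tortuosity of known shapes.

Builds analytic test curves (circle, helix) plus the default synthetic
pulmonary-artery bifurcation, resamples each centerline at 0.1 cm, and
prints mean curvature (cm^-1, inverse osculating-circle radius) and
tortuosity (arclength over chord, minus one).
"""

import numpy as np

from pahemo import CenterlinePolyline, curvature_profile, resample_centerline, tortuosity
from pahemo.synthetic import default_pa_spec, make_pa_bifurcation

# a semicircle of radius 2 cm: curvature 1/2, tortuosity pi/2 - 1
t = np.linspace(0, np.pi, 2000)
semicircle = CenterlinePolyline(
    np.column_stack([2 * np.cos(t), 2 * np.sin(t), np.zeros_like(t)])
)
line = resample_centerline(semicircle, 0.1)
print("semicircle r=2 cm:")
print(f"  mean curvature {curvature_profile(line).mean_kappa:.4f} cm^-1 (closed form 0.5)")
print(f"  tortuosity     {tortuosity(line).tortuosity:.4f} (closed form {np.pi/2-1:.4f})")

# the synthetic PA: the LPA path should be curvier than the RPA path,
# the typical anatomy after tetralogy of Fallot repair
_, centerlines, _ = make_pa_bifurcation(default_pa_spec())
for branch in ("LPA", "RPA"):
    path = CenterlinePolyline(
        np.vstack([centerlines["MPA"].points, centerlines[branch].points[1:]])
    )
    rs = resample_centerline(path, 0.1)
    kappa = curvature_profile(rs).mean_kappa
    chi = tortuosity(rs).tortuosity
    print(f"MPA->{branch} path: mean curvature {kappa:.3f} cm^-1, tortuosity {chi:.3f}")
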