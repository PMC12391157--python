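"""Lightweight triangle-mesh container for vessel walls.

The pipeline only needs vertex coordinates, triangle connectivity and
per-vertex areas (one third of the incident triangle areas, the standard
lumped-mass weighting), so a small dataclass is used rather than a full
mesh library; :mod:`pahemo.io` handles STL/VTP serialization.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class SurfaceMesh:
    """Triangulated vessel-wall surface.

    Parameters
    ----------
    points : (N, 3) float array
        Vertex coordinates in cm.
    faces : (M, 3) int array
        Triangle vertex indices.
    """

    points: np.ndarray
    faces: np.ndarray

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        self.faces = np.asarray(self.faces, dtype=np.int64)
        if self.points.ndim != 2 or self.points.shape[1] != 3:
            raise ValueError("points must be an (N, 3) array")
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise ValueError("faces must be an (M, 3) array")
        if not np.isfinite(self.points).all():
            raise ValueError("points must be finite")
        if self.faces.size and self.faces.max() >= len(self.points):
            raise ValueError("face index out of range")

    @property
    def n_points(self) -> int:
        return len(self.points)

    def triangle_areas(self) -> np.ndarray:
        """Area of each triangle (cm^2)."""
        p = self.points
        a, b, c = (p[self.faces[:, i]] for i in range(3))
        return 0.5 * np.linalg.norm(np.cross(b - a, c - a), axis=1)

    def vertex_areas(self) -> np.ndarray:
        """Per-vertex area: one third of each incident triangle's area.

        Sums to the total wall area exactly (each triangle contributes its
        whole area, split between its three corners).
        """
        tri_area = self.triangle_areas()
        areas = np.zeros(self.n_points)
        np.add.at(areas, self.faces.ravel(), np.repeat(tri_area / 3.0, 3))
        return areas

    def total_area(self) -> float:
        return float(self.triangle_areas().sum())


def merge_meshes(meshes: list[SurfaceMesh]) -> tuple[SurfaceMesh, np.ndarray]:
    """Concatenate meshes into one; returns (mesh, source index per point)."""
    pts, faces, src = [], [], []
    offset = 0
    for i, m in enumerate(meshes):
        pts.append(m.points)
        faces.append(m.faces + offset)
        src.append(np.full(m.n_points, i))
        offset += m.n_points
    return (
        SurfaceMesh(np.vstack(pts), np.vstack(faces)),
        np.concatenate(src),
    )
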