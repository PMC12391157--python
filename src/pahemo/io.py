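"""Readers and writers for the pipeline's on-disk artifacts.

Surface meshes go to STL (via trimesh) and to VTP-style XML PolyData
(ASCII, written and parsed with the standard-library ElementTree, since
the environment carries no VTK bindings); wall-shear time series are VTP
series with a per-point ``WSS`` vector array and a ``TimeValue`` field, or
a long-format CSV. Centerlines, waveforms and cohort tables are plain
CSV; every generated artifact can carry a JSON sidecar recording the spec
parameters and seed.
"""

from __future__ import annotations

import json
import xml.etree.ElementTree as ET
from pathlib import Path

import numpy as np
import pandas as pd

from .centerline import CenterlinePolyline
from .flow import FlowWaveform
from .mesh import SurfaceMesh


# -- STL ---------------------------------------------------------------------


def write_stl(path, mesh: SurfaceMesh) -> None:
    import trimesh

    tm = trimesh.Trimesh(vertices=mesh.points, faces=mesh.faces, process=False)
    tm.export(str(path))


def read_stl(path) -> SurfaceMesh:
    import trimesh

    tm = trimesh.load_mesh(str(path), process=False)
    return SurfaceMesh(np.asarray(tm.vertices), np.asarray(tm.faces))


# -- VTP-style XML PolyData --------------------------------------------------


def _ascii(a: np.ndarray) -> str:
    return " ".join(repr(x) if isinstance(x, float) else str(x) for x in np.asarray(a).ravel().tolist())


def write_vtp_surface(
    path,
    mesh: SurfaceMesh,
    point_data: dict[str, np.ndarray] | None = None,
    time_value: float | None = None,
) -> None:
    """XML PolyData with optional per-point arrays and a time annotation."""
    root = ET.Element(
        "VTKFile", type="PolyData", version="1.0", byte_order="LittleEndian"
    )
    poly = ET.SubElement(root, "PolyData")
    if time_value is not None:
        fd = ET.SubElement(poly, "FieldData")
        arr = ET.SubElement(
            fd, "DataArray", type="Float64", Name="TimeValue",
            NumberOfTuples="1", format="ascii",
        )
        arr.text = repr(float(time_value))
    piece = ET.SubElement(
        poly, "Piece",
        NumberOfPoints=str(mesh.n_points), NumberOfPolys=str(len(mesh.faces)),
    )
    pts = ET.SubElement(piece, "Points")
    arr = ET.SubElement(
        pts, "DataArray", type="Float64", NumberOfComponents="3", format="ascii"
    )
    arr.text = _ascii(mesh.points)
    if point_data:
        pd_el = ET.SubElement(piece, "PointData")
        for name, values in point_data.items():
            values = np.asarray(values)
            ncomp = 1 if values.ndim == 1 else values.shape[1]
            if values.dtype.kind in "OU":
                a = ET.SubElement(
                    pd_el, "DataArray", type="String", Name=name, format="ascii"
                )
                a.text = " ".join(map(str, values))
            else:
                a = ET.SubElement(
                    pd_el, "DataArray", type="Float64", Name=name,
                    NumberOfComponents=str(ncomp), format="ascii",
                )
                a.text = _ascii(values.astype(float))
    polys = ET.SubElement(piece, "Polys")
    conn = ET.SubElement(polys, "DataArray", type="Int64", Name="connectivity", format="ascii")
    conn.text = _ascii(mesh.faces)
    offs = ET.SubElement(polys, "DataArray", type="Int64", Name="offsets", format="ascii")
    offs.text = _ascii(3 * (np.arange(len(mesh.faces)) + 1))
    ET.ElementTree(root).write(str(path), xml_declaration=True)


def read_vtp_surface(path) -> tuple[SurfaceMesh, dict[str, np.ndarray], float | None]:
    """Parse a PolyData file; returns (mesh, point arrays, time or None)."""
    root = ET.parse(str(path)).getroot()
    poly = root.find("PolyData")
    time_value = None
    fd = poly.find("FieldData")
    if fd is not None:
        for arr in fd.findall("DataArray"):
            if arr.get("Name") == "TimeValue":
                time_value = float(arr.text.strip())
    piece = poly.find("Piece")
    n_points = int(piece.get("NumberOfPoints"))
    pts = np.fromstring(
        piece.find("Points").find("DataArray").text, sep=" "
    ).reshape(n_points, 3)
    conn = np.empty((0, 3), dtype=np.int64)
    for arr in piece.find("Polys").findall("DataArray"):
        if arr.get("Name") == "connectivity" and arr.text:
            conn = np.fromstring(arr.text, dtype=np.int64, sep=" ").reshape(-1, 3)
    mesh = SurfaceMesh(pts, conn)
    arrays: dict[str, np.ndarray] = {}
    pd_el = piece.find("PointData")
    if pd_el is not None:
        for arr in pd_el.findall("DataArray"):
            name = arr.get("Name")
            if arr.get("type") == "String":
                arrays[name] = np.array(arr.text.split())
            else:
                ncomp = int(arr.get("NumberOfComponents", "1"))
                vals = np.fromstring(arr.text, sep=" ")
                arrays[name] = vals.reshape(n_points, ncomp) if ncomp > 1 else vals
    return mesh, arrays, time_value


def write_wss_series(directory, field, prefix: str = "wss") -> list[Path]:
    """One VTP file per timepoint with shear vectors and a time stamp.

    Per-point areas (and segment labels, when present) ride along as
    point arrays so an imported series reproduces area-weighted summaries
    without the wall triangulation.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    mesh = SurfaceMesh(field.wall_points, np.empty((0, 3), dtype=np.int64))
    extra: dict[str, np.ndarray] = {"Area": field.areas}
    if field.labeling is not None:
        extra["Label"] = field.labeling.labels
    paths = []
    for i, t in enumerate(field.times):
        p = directory / f"{prefix}_{i:03d}.vtp"
        write_vtp_surface(
            p, mesh,
            point_data={"WSS": field.vectors[:, i, :], **extra},
            time_value=float(t),
        )
        paths.append(p)
    return paths


def write_wss_csv(path, field) -> None:
    """Long-format CSV fallback: point_id, t, wx, wy, wz."""
    n_pts, n_t = field.vectors.shape[:2]
    rows = {
        "point_id": np.repeat(np.arange(n_pts), n_t),
        "t": np.tile(field.times, n_pts),
        "wx": field.vectors[:, :, 0].ravel(),
        "wy": field.vectors[:, :, 1].ravel(),
        "wz": field.vectors[:, :, 2].ravel(),
    }
    pd.DataFrame(rows).to_csv(path, index=False)


# -- centerlines, waveforms, tables ------------------------------------------


def write_centerline_csv(path, line: CenterlinePolyline) -> None:
    pd.DataFrame(line.points, columns=["x", "y", "z"]).to_csv(path, index=False)


def read_centerline_csv(path) -> CenterlinePolyline:
    df = pd.read_csv(path)
    return CenterlinePolyline(df[["x", "y", "z"]].to_numpy())


def write_waveform_csv(path, waveform: FlowWaveform) -> None:
    pd.DataFrame(
        {"time_s": waveform.times, "flow_ml_s": waveform.flows}
    ).to_csv(path, index=False)


def read_waveform_csv(path, heart_rate: float | None = None) -> FlowWaveform:
    """Two-column waveform CSV (`time_s`, `flow_ml_s`; mL/s = cm^3/s).

    If ``heart_rate`` is omitted it is inferred from the sample span,
    assuming the samples cover exactly one cycle.
    """
    df = pd.read_csv(path)
    t = df["time_s"].to_numpy()
    q = df["flow_ml_s"].to_numpy()
    if heart_rate is None:
        dt = np.median(np.diff(t))
        heart_rate = 60.0 / (t[-1] - t[0] + dt)
    return FlowWaveform(times=t - t[0], flows=q, heart_rate=heart_rate)


def write_sidecar(path, params: dict) -> None:
    """JSON sidecar with generation parameters, seed and generator id."""
    payload = dict(params)
    payload.setdefault("rng", "numpy.random.default_rng (PCG64)")
    Path(path).write_text(json.dumps(payload, indent=2, default=str))
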