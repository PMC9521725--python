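"""Voltage map construction, DeEP sphere placement, and map export.

The chamber surface is colored by local bipolar amplitude (peak-to-peak
of the last captured S1 beat), interpolated from electrode sites to mesh
vertices by inverse-distance weighting within an influence radius.
Vertices with no electrode in range carry NaN (no data). Displayed DeEP
points become spheres centered on their nearest mesh vertex with radius
growing linearly in the decrement, so larger spheres mean larger delays.

Geometry exports use open formats: VTK legacy ASCII and ASCII PLY for the
mesh with per-vertex voltage, CSV for the sphere table.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import trimesh
from scipy.spatial import cKDTree

from .config import MapConfig, PipelineConfig
from .core import DeEPPoint

__all__ = ["Sphere", "build_voltage_map", "place_deep_spheres", "export_map",
           "read_vtk", "read_ply", "read_spheres"]

SUPPORTED_FORMATS = ("vtk", "ply")


@dataclass(frozen=True)
class Sphere:
    center: tuple[float, float, float]
    radius: float
    value: float  # DeEP, ms
    channel: str


def build_voltage_map(mesh: trimesh.Trimesh,
                      electrode_positions: dict[str, np.ndarray],
                      electrode_voltages: dict[str, float],
                      config: MapConfig | None = None) -> np.ndarray:
    """Per-vertex bipolar voltage by inverse-distance weighting.

    Each vertex averages the voltages of electrodes within
    ``config.radius_mm``, weighted by 1/d^2; a vertex coincident with an
    electrode takes that electrode's value exactly. Uncovered vertices
    are NaN. A constant electrode field is reproduced exactly.
    """
    if config is None:
        config = PipelineConfig().map
    verts = np.asarray(mesh.vertices, dtype=float)
    values = np.full(len(verts), np.nan)
    names = [n for n in electrode_positions if n in electrode_voltages]
    if not names:
        warnings.warn("no electrodes with voltages: all-no-data map")
        return values
    pos = np.stack([np.asarray(electrode_positions[n], float) for n in names])
    volt = np.array([electrode_voltages[n] for n in names], dtype=float)

    d = np.linalg.norm(verts[:, None, :] - pos[None, :, :], axis=2)
    in_range = d <= config.radius_mm
    covered = in_range.any(axis=1)
    if not covered.any():
        warnings.warn("no electrode within radius of any vertex: "
                      "all-no-data map")
        return values
    for i in np.nonzero(covered)[0]:
        di = d[i, in_range[i]]
        vi = volt[in_range[i]]
        if np.any(di == 0.0):
            values[i] = float(vi[di == 0.0][0])
        else:
            w = 1.0 / di ** 2
            values[i] = float((w * vi).sum() / w.sum())
    return values


def peak_to_peak_voltage(signal: np.ndarray, fs: float, stim_time_ms: float,
                         window_ms: tuple[float, float] = (10.0, 150.0),
                         ) -> float:
    """Bipolar amplitude of one beat: peak-to-peak in a post-stimulus
    window that excludes the pacing artifact."""
    i0 = int(round((stim_time_ms + window_ms[0]) * fs / 1000.0))
    i1 = min(int(round((stim_time_ms + window_ms[1]) * fs / 1000.0)),
             len(signal))
    if i1 <= i0:
        return float("nan")
    seg = signal[i0:i1]
    return float(seg.max() - seg.min())


def place_deep_spheres(points: list[DeEPPoint], mesh: trimesh.Trimesh,
                       config: MapConfig | None = None) -> list[Sphere]:
    """One sphere per displayed point, on its nearest mesh vertex.

    radius = r_min + k * deep_value (strictly monotone in the decrement).
    Points farther than the projection limit from the mesh are excluded
    with a warning; non-displayed points yield no sphere.
    """
    if config is None:
        config = PipelineConfig().map
    tree = cKDTree(np.asarray(mesh.vertices, dtype=float))
    spheres: list[Sphere] = []
    for p in points:
        if not p.displayed:
            continue
        dist, idx = tree.query(np.asarray(p.position, dtype=float))
        if dist > config.projection_limit_mm:
            warnings.warn(
                f"DeEP point {p.channel!r} is {dist:.1f} mm off-mesh "
                f"(limit {config.projection_limit_mm} mm); excluded")
            continue
        center = tuple(float(c) for c in mesh.vertices[idx])
        radius = config.sphere_r_min + config.sphere_k * p.deep_value
        spheres.append(Sphere(center=center, radius=radius,
                              value=p.deep_value, channel=p.channel))
    return spheres


# ---------------------------------------------------------------------------
# export / import

def _write_vtk(mesh: trimesh.Trimesh, voltages: np.ndarray, path: Path) -> None:
    v = np.asarray(mesh.vertices, dtype=float)
    f = np.asarray(mesh.faces, dtype=int)
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\n")
        fh.write("chamber voltage map\nASCII\nDATASET POLYDATA\n")
        fh.write(f"POINTS {len(v)} double\n")
        for p in v:
            fh.write(f"{p[0]:.9g} {p[1]:.9g} {p[2]:.9g}\n")
        fh.write(f"POLYGONS {len(f)} {4 * len(f)}\n")
        for tri in f:
            fh.write(f"3 {tri[0]} {tri[1]} {tri[2]}\n")
        fh.write(f"POINT_DATA {len(v)}\n")
        fh.write("SCALARS voltage double 1\nLOOKUP_TABLE default\n")
        for val in voltages:
            fh.write(f"{val:.9g}\n")


def read_vtk(path: str | Path) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Read back a legacy-ASCII VTK polydata file written by export_map."""
    tokens: list[str] = []
    with open(path) as fh:
        lines = fh.readlines()
    i = 0
    verts = faces = scalars = None
    while i < len(lines):
        line = lines[i].strip()
        if line.startswith("POINTS"):
            n = int(line.split()[1])
            vals = []
            i += 1
            while len(vals) < 3 * n:
                vals.extend(float(x) for x in lines[i].split())
                i += 1
            verts = np.array(vals).reshape(n, 3)
            continue
        if line.startswith("POLYGONS"):
            n = int(line.split()[1])
            rows = []
            i += 1
            for _ in range(n):
                parts = lines[i].split()
                rows.append([int(x) for x in parts[1:1 + int(parts[0])]])
                i += 1
            faces = np.array(rows, dtype=int)
            continue
        if line.startswith("SCALARS"):
            i += 2  # skip LOOKUP_TABLE
            vals = []
            while i < len(lines) and len(vals) < len(verts):
                vals.extend(float(x) for x in lines[i].split())
                i += 1
            scalars = np.array(vals)
            continue
        i += 1
    return verts, faces, scalars


def _write_ply(mesh: trimesh.Trimesh, voltages: np.ndarray, path: Path) -> None:
    v = np.asarray(mesh.vertices, dtype=float)
    f = np.asarray(mesh.faces, dtype=int)
    with open(path, "w") as fh:
        fh.write("ply\nformat ascii 1.0\n")
        fh.write(f"element vertex {len(v)}\n")
        fh.write("property double x\nproperty double y\nproperty double z\n")
        fh.write("property double voltage\n")
        fh.write(f"element face {len(f)}\n")
        fh.write("property list uchar int vertex_indices\nend_header\n")
        for p, val in zip(v, voltages):
            fh.write(f"{p[0]:.9g} {p[1]:.9g} {p[2]:.9g} {val:.9g}\n")
        for tri in f:
            fh.write(f"3 {tri[0]} {tri[1]} {tri[2]}\n")


def read_ply(path: str | Path) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Read back an ASCII PLY with a per-vertex voltage property."""
    with open(path) as fh:
        lines = [ln.strip() for ln in fh]
    n_v = n_f = 0
    for i, ln in enumerate(lines):
        if ln.startswith("element vertex"):
            n_v = int(ln.split()[2])
        elif ln.startswith("element face"):
            n_f = int(ln.split()[2])
        elif ln == "end_header":
            body = i + 1
            break
    vert_rows = np.array([[float(x) for x in lines[body + j].split()]
                          for j in range(n_v)])
    faces = np.array([[int(x) for x in lines[body + n_v + j].split()[1:4]]
                      for j in range(n_f)], dtype=int)
    return vert_rows[:, :3], faces, vert_rows[:, 3]


def read_spheres(path: str | Path) -> list[Sphere]:
    spheres = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            spheres.append(Sphere(
                center=(float(row["x"]), float(row["y"]), float(row["z"])),
                radius=float(row["radius_mm"]),
                value=float(row["deep_ms"]),
                channel=row["channel"],
            ))
    return spheres


def export_map(mesh: trimesh.Trimesh, voltages: np.ndarray,
               spheres: list[Sphere], out_dir: str | Path,
               fmt: str = "vtk", config: MapConfig | None = None,
               ) -> dict[str, Path]:
    """Write the voltage-mapped mesh and the sphere table.

    ``fmt`` selects the geometry format ("vtk" legacy ASCII or "ply");
    the sphere table is always CSV. Values survive a round-trip to at
    least 6 significant digits. Color thresholds (scar/border, mV) go
    into a small JSON sidecar as display metadata only.
    """
    if fmt not in SUPPORTED_FORMATS:
        raise ValueError(
            f"unsupported format {fmt!r}; supported: {SUPPORTED_FORMATS}")
    if config is None:
        config = PipelineConfig().map
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    geom = out / f"voltage_map.{fmt}"
    if fmt == "vtk":
        _write_vtk(mesh, voltages, geom)
    else:
        _write_ply(mesh, voltages, geom)
    paths["geometry"] = geom

    sph = out / "deep_spheres.csv"
    with open(sph, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["channel", "x", "y", "z", "radius_mm", "deep_ms"])
        for s in spheres:
            writer.writerow([s.channel, f"{s.center[0]:.9g}",
                             f"{s.center[1]:.9g}", f"{s.center[2]:.9g}",
                             f"{s.radius:.9g}", f"{s.value:.9g}"])
    paths["spheres"] = sph

    meta = out / "display_metadata.json"
    meta.write_text(
        '{"scar_threshold_mv": %g, "border_threshold_mv": %g}\n'
        % (config.scar_threshold_mv, config.border_threshold_mv))
    paths["metadata"] = meta
    return paths
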