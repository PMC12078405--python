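"""Meshes, time-resolved vector fields, and on-disk case format.

The on-disk layout of a case is a directory containing

* ``surface.vtk`` — legacy-ASCII VTK POLYDATA with the sac surface
  (triangles), a ``sac_mask`` point-data scalar and one ``wss`` vector
  array per phase file;
* ``volume.vtk`` — legacy-ASCII VTK UNSTRUCTURED_GRID with the tetrahedral
  volume mesh and a ``sac_mask`` cell-data scalar;
* ``wss_phase_<k>.vtk`` / ``velocity_phase_<k>.vtk`` — one file per cardiac
  phase carrying the ``wss`` (surface, Pa) or ``velocity`` (volume, mm/s)
  point-data vector array;
* ``manifest.json`` tying the files into one cardiac cycle.

Units are millimetres for coordinates, pascals for wall shear stress and
millimetres/second for velocity; the manifest records the unit strings and
they are validated at read time.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "SurfaceMesh",
    "VolumeMesh",
    "TimeResolvedField",
    "CaseManifest",
    "Case",
    "read_case",
    "write_case",
    "FormatError",
    "StructuralError",
]

EXPECTED_UNITS = {"length": "mm", "wss": "Pa", "velocity": "mm/s"}


class FormatError(ValueError):
    """A file did not parse as the expected VTK dataset/array layout."""


class StructuralError(ValueError):
    """Cross-file inconsistency (node counts, missing phases, bad indices)."""


def _triangle_areas(vertices: np.ndarray, triangles: np.ndarray) -> np.ndarray:
    p0, p1, p2 = (vertices[triangles[:, k]] for k in range(3))
    return 0.5 * np.linalg.norm(np.cross(p1 - p0, p2 - p0), axis=1)


@dataclass
class SurfaceMesh:
    """Triangulated aneurysm-sac surface.

    ``sac_mask`` marks the vertices belonging to the aneurysm sac; parent
    vessel / flow-extension vertices are False and excluded from sac-level
    aggregates.  Vertex areas are barycentric-lumped: one third of the area
    of each incident triangle, which partitions the total surface area
    exactly.
    """

    vertices: np.ndarray          # (n_v, 3) float, mm
    triangles: np.ndarray         # (n_t, 3) int
    sac_mask: np.ndarray | None = None  # (n_v,) bool
    _vertex_areas: np.ndarray | None = field(default=None, repr=False, compare=False)
    _boundary: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.triangles = np.asarray(self.triangles, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise ValueError("vertices must be (n, 3)")
        if self.triangles.ndim != 2 or self.triangles.shape[1] != 3:
            raise ValueError("triangles must be (m, 3)")
        if self.triangles.size and (
            self.triangles.min() < 0 or self.triangles.max() >= self.n_vertices
        ):
            raise StructuralError("triangle indices out of range")
        if self.sac_mask is None:
            self.sac_mask = np.ones(self.n_vertices, dtype=bool)
        else:
            self.sac_mask = np.asarray(self.sac_mask, dtype=bool)
            if self.sac_mask.shape != (self.n_vertices,):
                raise ValueError("sac_mask must have one entry per vertex")

    @property
    def n_vertices(self) -> int:
        return self.vertices.shape[0]

    @property
    def n_triangles(self) -> int:
        return self.triangles.shape[0]

    @property
    def triangle_areas(self) -> np.ndarray:
        return _triangle_areas(self.vertices, self.triangles)

    @property
    def vertex_areas(self) -> np.ndarray:
        """Barycentric-lumped vertex areas (mm**2); sums to the total area."""
        if self._vertex_areas is None:
            areas = np.zeros(self.n_vertices)
            np.add.at(areas, self.triangles.ravel(),
                      np.repeat(self.triangle_areas / 3.0, 3))
            self._vertex_areas = areas
        return self._vertex_areas

    @property
    def boundary_vertices(self) -> np.ndarray:
        """Boolean mask of vertices on an open boundary (edge with one face)."""
        if self._boundary is None:
            edges = np.sort(
                self.triangles[:, [0, 1, 1, 2, 2, 0]].reshape(-1, 2), axis=1
            )
            uniq, counts = np.unique(edges, axis=0, return_counts=True)
            mask = np.zeros(self.n_vertices, dtype=bool)
            mask[uniq[counts == 1].ravel()] = True
            self._boundary = mask
        return self._boundary

    @property
    def total_area(self) -> float:
        return float(self.triangle_areas.sum())

    @property
    def sac_area(self) -> float:
        return float(self.vertex_areas[self.sac_mask].sum())


@dataclass
class VolumeMesh:
    """Tetrahedral volume mesh with a per-cell sac mask."""

    nodes: np.ndarray            # (n_n, 3) float, mm
    cells: np.ndarray            # (n_c, 4) int
    sac_mask: np.ndarray | None = None  # (n_c,) bool
    _cell_volumes: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.nodes = np.asarray(self.nodes, dtype=float)
        self.cells = np.asarray(self.cells, dtype=np.int64)
        if self.nodes.ndim != 2 or self.nodes.shape[1] != 3:
            raise ValueError("nodes must be (n, 3)")
        if self.cells.ndim != 2 or self.cells.shape[1] != 4:
            raise ValueError("cells must be (m, 4) tetrahedra")
        if self.cells.size and (
            self.cells.min() < 0 or self.cells.max() >= self.n_nodes
        ):
            raise StructuralError("cell indices out of range")
        if self.sac_mask is None:
            self.sac_mask = np.ones(self.n_cells, dtype=bool)
        else:
            self.sac_mask = np.asarray(self.sac_mask, dtype=bool)
            if self.sac_mask.shape != (self.n_cells,):
                raise ValueError("sac_mask must have one entry per cell")

    @property
    def n_nodes(self) -> int:
        return self.nodes.shape[0]

    @property
    def n_cells(self) -> int:
        return self.cells.shape[0]

    @property
    def cell_volumes(self) -> np.ndarray:
        """Signed-determinant tet volumes (mm**3), oriented positive."""
        if self._cell_volumes is None:
            p = self.nodes[self.cells]
            v = np.einsum(
                "ij,ij->i",
                np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0]),
                p[:, 3] - p[:, 0],
            ) / 6.0
            self._cell_volumes = np.abs(v)
        return self._cell_volumes

    @property
    def sac_volume(self) -> float:
        return float(self.cell_volumes[self.sac_mask].sum())


@dataclass
class TimeResolvedField:
    """Vector values per node per cardiac phase.

    ``values`` has shape (n_phases, n_nodes, 3).  Phase times live in
    [0, T); when a case is written without explicit times they default to
    uniform spacing over the period.
    """

    values: np.ndarray
    phase_times: np.ndarray
    period: float
    kind: str  # "wss" | "velocity"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.phase_times = np.asarray(self.phase_times, dtype=float)
        if self.values.ndim != 3 or self.values.shape[2] != 3:
            raise ValueError("values must be (n_phases, n_nodes, 3)")
        if self.phase_times.shape != (self.n_phases,):
            raise ValueError("phase_times must have one entry per phase")
        if np.any(np.diff(self.phase_times) <= 0):
            raise ValueError("phase_times must be strictly increasing")
        if self.phase_times[0] < 0 or self.phase_times[-1] >= self.period:
            raise ValueError("phase_times must lie in [0, period)")
        if self.kind not in ("wss", "velocity"):
            raise ValueError(f"unknown field kind {self.kind!r}")

    @property
    def n_phases(self) -> int:
        return self.values.shape[0]

    @property
    def n_nodes(self) -> int:
        return self.values.shape[1]

    def magnitudes(self) -> np.ndarray:
        """(n_phases, n_nodes) vector magnitudes."""
        return np.linalg.norm(self.values, axis=2)


@dataclass
class CaseManifest:
    case_id: str
    group_label: str                   # "thrombosed" | "control"
    surface_path: str
    volume_path: str
    wss_paths: list[str]
    velocity_paths: list[str]
    period: float
    phase_times: list[float]
    peak_systole_phase: int
    systole_window: tuple[int, int]    # inclusive phase-index range
    units: dict = field(default_factory=lambda: dict(EXPECTED_UNITS))

    def validate(self) -> None:
        if self.group_label not in ("thrombosed", "control"):
            raise ValueError(f"bad group_label {self.group_label!r}")
        lo, hi = self.systole_window
        if not (0 <= lo <= hi < len(self.phase_times)):
            raise ValueError("systole_window out of range")
        if not (lo <= self.peak_systole_phase <= hi):
            raise ValueError("peak_systole_phase outside systole_window")
        if len(self.wss_paths) != len(self.phase_times):
            raise StructuralError("one wss file per phase required")
        if len(self.velocity_paths) != len(self.phase_times):
            raise StructuralError("one velocity file per phase required")
        for key, expected in EXPECTED_UNITS.items():
            got = self.units.get(key)
            if got != expected:
                raise FormatError(f"unit mismatch for {key}: {got!r} != {expected!r}")


@dataclass
class Case:
    """One aneurysm dataset: meshes plus time-resolved WSS and velocity."""

    case_id: str
    group_label: str
    surface: SurfaceMesh
    volume: VolumeMesh
    wss: TimeResolvedField
    velocity: TimeResolvedField
    peak_systole_phase: int
    systole_window: tuple[int, int]

    def validate(self) -> None:
        if self.wss.n_nodes != self.surface.n_vertices:
            raise StructuralError("wss field node count != surface vertex count")
        if self.velocity.n_nodes != self.volume.n_nodes:
            raise StructuralError("velocity field node count != volume node count")
        if self.wss.n_phases != self.velocity.n_phases:
            raise StructuralError("wss and velocity phase counts differ")
        lo, hi = self.systole_window
        if not (0 <= lo <= self.peak_systole_phase <= hi < self.wss.n_phases):
            raise ValueError("inconsistent systole window / peak phase")


# ----------------------------------------------------------------------------
# Legacy-ASCII VTK writer/reader (POLYDATA and UNSTRUCTURED_GRID subsets).
# Numbers are written with repr-precision so a round trip is lossless to
# double precision.

def _fmt(arr: np.ndarray, per_line: int) -> str:
    flat = np.asarray(arr, dtype=float).ravel()
    parts = [f"{x:.17g}" for x in flat]
    lines = [
        " ".join(parts[i:i + per_line]) for i in range(0, len(parts), per_line)
    ]
    return "\n".join(lines)


def _write_vtk(
    path: Path,
    *,
    dataset: str,
    points: np.ndarray,
    cells: np.ndarray,
    point_vectors: dict[str, np.ndarray],
    point_scalars: dict[str, np.ndarray],
    cell_scalars: dict[str, np.ndarray],
    title: str,
) -> None:
    n_pts = points.shape[0]
    n_cells, nodes_per_cell = cells.shape
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\n")
        fh.write(f"{title}\n")
        fh.write("ASCII\n")
        fh.write(f"DATASET {dataset}\n")
        fh.write(f"POINTS {n_pts} double\n")
        fh.write(_fmt(points, 3) + "\n")
        size = n_cells * (nodes_per_cell + 1)
        if dataset == "POLYDATA":
            fh.write(f"POLYGONS {n_cells} {size}\n")
        else:
            fh.write(f"CELLS {n_cells} {size}\n")
        for row in cells:
            fh.write(f"{nodes_per_cell} " + " ".join(str(int(i)) for i in row) + "\n")
        if dataset == "UNSTRUCTURED_GRID":
            fh.write(f"CELL_TYPES {n_cells}\n")
            fh.write("\n".join(["10"] * n_cells) + "\n")  # VTK_TETRA
        if point_vectors or point_scalars:
            fh.write(f"POINT_DATA {n_pts}\n")
            for name, arr in point_scalars.items():
                fh.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
                fh.write(_fmt(arr, 9) + "\n")
            for name, arr in point_vectors.items():
                fh.write(f"VECTORS {name} double\n")
                fh.write(_fmt(arr, 3) + "\n")
        if cell_scalars:
            fh.write(f"CELL_DATA {n_cells}\n")
            for name, arr in cell_scalars.items():
                fh.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
                fh.write(_fmt(arr, 9) + "\n")


def _read_vtk(path: Path) -> dict:
    """Parse the legacy-ASCII VTK subset written by :func:`_write_vtk`.

    Returns a dict with keys points, cells, dataset, point_scalars,
    point_vectors, cell_scalars.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"VTK file not found: {path}")
    with open(path) as fh:
        tokens = fh.read().split()
    pos = 0

    def take(n: int) -> list[str]:
        nonlocal pos
        out = tokens[pos:pos + n]
        if len(out) < n:
            raise FormatError(f"truncated VTK file: {path}")
        pos += n
        return out

    out: dict = {
        "points": None, "cells": None, "dataset": None,
        "point_scalars": {}, "point_vectors": {}, "cell_scalars": {},
    }
    n_pts = n_cells = 0
    section = None  # POINT_DATA | CELL_DATA
    while pos < len(tokens):
        tok = tokens[pos]
        if tok == "DATASET":
            out["dataset"] = take(2)[1]
        elif tok == "POINTS":
            _, n, _ = take(3)
            n_pts = int(n)
            vals = np.array(take(3 * n_pts), dtype=float)
            out["points"] = vals.reshape(n_pts, 3)
        elif tok in ("POLYGONS", "CELLS"):
            _, n, size = take(3)
            n_cells, size = int(n), int(size)
            raw = np.array(take(size), dtype=np.int64)
            cells = []
            i = 0
            while i < size:
                k = int(raw[i])
                cells.append(raw[i + 1:i + 1 + k])
                i += k + 1
            out["cells"] = np.array(cells, dtype=np.int64)
        elif tok == "CELL_TYPES":
            _, n = take(2)
            take(int(n))
        elif tok == "POINT_DATA":
            take(2)
            section = "point"
        elif tok == "CELL_DATA":
            take(2)
            section = "cell"
        elif tok == "SCALARS":
            _, name, _dtype, _comps = take(4)
            take(2)  # LOOKUP_TABLE default
            n = n_pts if section == "point" else n_cells
            arr = np.array(take(n), dtype=float)
            key = "point_scalars" if section == "point" else "cell_scalars"
            out[key][name] = arr
        elif tok == "VECTORS":
            _, name, _dtype = take(3)
            n = n_pts if section == "point" else n_cells
            arr = np.array(take(3 * n), dtype=float).reshape(n, 3)
            key = "point_vectors" if section == "point" else "cell_vectors"
            out.setdefault(key, {})[name] = arr
        else:
            pos += 1
    if out["points"] is None or out["cells"] is None:
        raise FormatError(f"not a supported VTK dataset: {path}")
    return out


# ----------------------------------------------------------------------------
# Case-level read/write

def write_case(case: Case, directory: str | Path) -> Path:
    """Write a :class:`Case` to ``directory``; returns the manifest path.

    The write is validating: NaN/Inf anywhere in a field raises before any
    file is produced, and ``read_case(write_case(c))`` reproduces every
    number to double precision.
    """
    case.validate()
    for f in (case.wss, case.velocity):
        if not np.all(np.isfinite(f.values)):
            raise ValueError(f"non-finite values in {f.kind} field; refusing to write")
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)

    surface_path = directory / "surface.vtk"
    _write_vtk(
        surface_path, dataset="POLYDATA",
        points=case.surface.vertices, cells=case.surface.triangles,
        point_vectors={}, point_scalars={"sac_mask": case.surface.sac_mask.astype(float)},
        cell_scalars={}, title=f"{case.case_id} sac surface (mm)",
    )
    volume_path = directory / "volume.vtk"
    _write_vtk(
        volume_path, dataset="UNSTRUCTURED_GRID",
        points=case.volume.nodes, cells=case.volume.cells,
        point_vectors={}, point_scalars={},
        cell_scalars={"sac_mask": case.volume.sac_mask.astype(float)},
        title=f"{case.case_id} volume mesh (mm)",
    )
    wss_paths, vel_paths = [], []
    for k in range(case.wss.n_phases):
        p = directory / f"wss_phase_{k:03d}.vtk"
        _write_vtk(
            p, dataset="POLYDATA",
            points=case.surface.vertices, cells=case.surface.triangles,
            point_vectors={"wss": case.wss.values[k]}, point_scalars={},
            cell_scalars={}, title=f"{case.case_id} wss phase {k} (Pa)",
        )
        wss_paths.append(p.name)
        p = directory / f"velocity_phase_{k:03d}.vtk"
        _write_vtk(
            p, dataset="UNSTRUCTURED_GRID",
            points=case.volume.nodes, cells=case.volume.cells,
            point_vectors={"velocity": case.velocity.values[k]}, point_scalars={},
            cell_scalars={}, title=f"{case.case_id} velocity phase {k} (mm/s)",
        )
        vel_paths.append(p.name)

    manifest = CaseManifest(
        case_id=case.case_id,
        group_label=case.group_label,
        surface_path=surface_path.name,
        volume_path=volume_path.name,
        wss_paths=wss_paths,
        velocity_paths=vel_paths,
        period=case.wss.period,
        phase_times=[float(t) for t in case.wss.phase_times],
        peak_systole_phase=case.peak_systole_phase,
        systole_window=case.systole_window,
    )
    manifest_path = directory / "manifest.json"
    payload = {
        "case_id": manifest.case_id,
        "group_label": manifest.group_label,
        "surface": manifest.surface_path,
        "volume": manifest.volume_path,
        "wss_phases": manifest.wss_paths,
        "velocity_phases": manifest.velocity_paths,
        "period_s": manifest.period,
        "phase_times_s": manifest.phase_times,
        "peak_systole_phase": manifest.peak_systole_phase,
        "systole_window": list(manifest.systole_window),
        "units": manifest.units,
    }
    with open(manifest_path, "w") as fh:
        json.dump(payload, fh, indent=2)
    return manifest_path


def read_manifest(manifest_path: str | Path) -> CaseManifest:
    manifest_path = Path(manifest_path)
    if not manifest_path.exists():
        raise FileNotFoundError(f"manifest not found: {manifest_path}")
    with open(manifest_path) as fh:
        raw = json.load(fh)
    manifest = CaseManifest(
        case_id=raw["case_id"],
        group_label=raw["group_label"],
        surface_path=raw["surface"],
        volume_path=raw["volume"],
        wss_paths=list(raw["wss_phases"]),
        velocity_paths=list(raw["velocity_phases"]),
        period=float(raw["period_s"]),
        phase_times=[float(t) for t in raw["phase_times_s"]],
        peak_systole_phase=int(raw["peak_systole_phase"]),
        systole_window=tuple(raw["systole_window"]),
        units=dict(raw.get("units", EXPECTED_UNITS)),
    )
    manifest.validate()
    return manifest


def _read_phase_series(
    directory: Path, names: list[str], array: str, n_nodes: int
) -> np.ndarray:
    phases = []
    for k, name in enumerate(names):
        data = _read_vtk(directory / name)
        vectors = data.get("point_vectors", {})
        if array not in vectors:
            raise FormatError(
                f"{directory / name}: expected point-data vector array {array!r}"
            )
        arr = vectors[array]
        if arr.shape[0] != n_nodes:
            raise StructuralError(
                f"phase {k} ({name}): {arr.shape[0]} nodes, expected {n_nodes}"
            )
        phases.append(arr)
    return np.stack(phases)


def read_case(manifest_path: str | Path) -> Case:
    """Load a case directory back into memory.

    Cell-associated sac masks stay cell-associated (volume); the surface
    sac mask is point-associated.  A vector array carried as cell data is
    not supported for fields — the internal convention is node-associated.
    """
    manifest_path = Path(manifest_path)
    manifest = read_manifest(manifest_path)
    directory = manifest_path.parent

    sdata = _read_vtk(directory / manifest.surface_path)
    if sdata["dataset"] != "POLYDATA":
        raise FormatError("surface file must be POLYDATA")
    sac = sdata["point_scalars"].get("sac_mask")
    surface = SurfaceMesh(
        vertices=sdata["points"], triangles=sdata["cells"],
        sac_mask=None if sac is None else sac > 0.5,
    )

    vdata = _read_vtk(directory / manifest.volume_path)
    if vdata["dataset"] != "UNSTRUCTURED_GRID":
        raise FormatError("volume file must be UNSTRUCTURED_GRID")
    csac = vdata["cell_scalars"].get("sac_mask")
    volume = VolumeMesh(
        nodes=vdata["points"], cells=vdata["cells"],
        sac_mask=None if csac is None else csac > 0.5,
    )

    times = np.asarray(manifest.phase_times, dtype=float)
    wss = TimeResolvedField(
        values=_read_phase_series(directory, manifest.wss_paths, "wss",
                                  surface.n_vertices),
        phase_times=times, period=manifest.period, kind="wss",
    )
    velocity = TimeResolvedField(
        values=_read_phase_series(directory, manifest.velocity_paths, "velocity",
                                  volume.n_nodes),
        phase_times=times, period=manifest.period, kind="velocity",
    )
    case = Case(
        case_id=manifest.case_id, group_label=manifest.group_label,
        surface=surface, volume=volume, wss=wss, velocity=velocity,
        peak_systole_phase=manifest.peak_systole_phase,
        systole_window=manifest.systole_window,
    )
    case.validate()
    return case
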