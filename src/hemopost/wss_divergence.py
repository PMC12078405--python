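"""Surface divergence of the normalized WSS field and its temporal variation.

The WSS vector at each sac vertex is normalized to unit length, and the
divergence of the resulting direction field is evaluated on the triangulated
surface: on each triangle the field is interpolated linearly (P1 shape
functions), the gradient of each Cartesian component is taken within the
triangle plane, and the divergence — the sum of the in-plane partials of the
three components — is constant per triangle.  Vertex values are the
area-weighted average over incident triangles, which is exact for fields
linear over a planar patch.

Positive divergence marks elongational (stretching) shear patterns on the
sac wall, negative marks compressive ones.  The topological shear variation
index (TSVI) at a vertex is the root-mean-square, over one cardiac cycle,
of the deviation of the instantaneous divergence from its cycle mean —
zero iff the divergence pattern is temporally frozen.

Boundary vertices of an open surface patch have incomplete one-rings and
are excluded from spatial averages.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .field_io import SurfaceMesh, TimeResolvedField
from .quadrature import cycle_mean
from .wss_metrics import TemporalStatisticError

__all__ = [
    "DivergenceMetrics",
    "normalize_wss",
    "surface_divergence",
    "compute_nwss_div_series",
    "compute_tsvi",
    "compute_divergence_metrics",
    "MeshQualityError",
]

DEFAULT_EPS_NORM = 1e-12  # Pa; vectors shorter than this normalize to zero


class MeshQualityError(ValueError):
    """Degenerate (zero-area) triangles make the P1 gradient singular."""


@dataclass
class DivergenceMetrics:
    nwss_div: np.ndarray        # (n_phases, n_v) instantaneous divergence, 1/mm
    mean_nwss_div: float        # spatio-temporal sac average, 1/mm
    tsvi: np.ndarray            # (n_v,) temporal RMS deviation, 1/mm
    mean_tsvi: float            # spatial sac average of TSVI, 1/mm
    degenerate_counts: np.ndarray  # (n_phases,) zero-shear vertices per phase


def normalize_wss(
    values: np.ndarray, eps: float = DEFAULT_EPS_NORM
) -> tuple[np.ndarray, np.ndarray]:
    """Unit-normalize vectors along the last axis.

    Returns ``(unit, degenerate)`` where degenerate marks vectors with
    magnitude <= eps; those become zero vectors.
    """
    values = np.asarray(values, dtype=float)
    mags = np.linalg.norm(values, axis=-1)
    degenerate = mags <= eps
    safe = np.where(degenerate, 1.0, mags)
    unit = values / safe[..., None]
    unit[degenerate] = 0.0
    return unit, degenerate


class _SurfaceOperator:
    """Cached per-triangle P1 shape-function gradients for one mesh."""

    def __init__(self, mesh: SurfaceMesh):
        tri = mesh.triangles
        p0, p1, p2 = (mesh.vertices[tri[:, k]] for k in range(3))
        n = np.cross(p1 - p0, p2 - p0)
        two_a = np.linalg.norm(n, axis=1)
        bad = np.nonzero(two_a <= 1e-14)[0]
        if bad.size:
            raise MeshQualityError(
                f"zero-area triangles at indices {bad.tolist()[:20]}"
            )
        n_hat = n / two_a[:, None]
        # grad of barycentric shape function i: n̂ × (opposite edge) / (2A)
        self.grads = np.stack(
            [
                np.cross(n_hat, p2 - p1) / two_a[:, None],
                np.cross(n_hat, p0 - p2) / two_a[:, None],
                np.cross(n_hat, p1 - p0) / two_a[:, None],
            ],
            axis=1,
        )  # (n_t, 3 vertices, 3 xyz)
        self.areas = 0.5 * two_a
        self.mesh = mesh
        # vertex accumulation: total incident area per vertex
        vert_area = np.zeros(mesh.n_vertices)
        np.add.at(vert_area, tri.ravel(), np.repeat(self.areas, 3))
        self.vertex_incident_area = vert_area

    def divergence(self, field: np.ndarray) -> np.ndarray:
        """Per-vertex divergence of a per-vertex vector field (…, n_v, 3)."""
        tri = self.mesh.triangles
        vals = field[..., tri, :]                     # (..., n_t, 3 verts, 3 xyz)
        div_tri = np.einsum("...tvc,tvc->...t", vals, self.grads)
        out_shape = field.shape[:-2] + (self.mesh.n_vertices,)
        contrib = div_tri * self.areas                # (..., n_t)
        flat_c = contrib.reshape(-1, tri.shape[0])
        flat_out = np.zeros((flat_c.shape[0], self.mesh.n_vertices))
        for k in range(3):
            np.add.at(flat_out, (slice(None), tri[:, k]), flat_c)
        flat_out /= self.vertex_incident_area
        return flat_out.reshape(out_shape)


_operator_cache: dict[int, _SurfaceOperator] = {}


def _get_operator(mesh: SurfaceMesh) -> _SurfaceOperator:
    key = id(mesh)
    op = _operator_cache.get(key)
    if op is None or op.mesh is not mesh:
        op = _SurfaceOperator(mesh)
        _operator_cache.clear()
        _operator_cache[key] = op
    return op


def surface_divergence(field: np.ndarray, mesh: SurfaceMesh) -> np.ndarray:
    """Discrete tangential divergence of a per-vertex vector field.

    ``field`` has shape (..., n_vertices, 3); the result has shape
    (..., n_vertices).  Per-triangle divergence from P1 gradients restricted
    to the triangle plane, area-weighted onto vertices; exact for fields
    linear over a planar patch.
    """
    field = np.asarray(field, dtype=float)
    if field.shape[-2] != mesh.n_vertices:
        raise ValueError("field must be defined on all vertices")
    return _get_operator(mesh).divergence(field)


def compute_nwss_div_series(
    wss: TimeResolvedField,
    mesh: SurfaceMesh,
    eps: float = DEFAULT_EPS_NORM,
) -> tuple[np.ndarray, np.ndarray]:
    """Instantaneous normalized-WSS divergence for every phase.

    Returns ``(div_series, degenerate)`` with shapes (n_phases, n_v) and
    (n_phases, n_v); degenerate marks zero-shear vertices per phase.
    """
    unit, degenerate = normalize_wss(wss.values, eps)
    div = surface_divergence(unit, mesh)
    return div, degenerate


def compute_tsvi(
    div_series: np.ndarray, phase_times: np.ndarray, period: float
) -> np.ndarray:
    """Temporal RMS deviation of the divergence at each vertex (1/mm)."""
    div_series = np.asarray(div_series, dtype=float)
    if div_series.shape[0] < 2:
        raise TemporalStatisticError("TSVI requires at least 2 phases")
    mean = cycle_mean(div_series, phase_times, period)
    var = cycle_mean((div_series - mean) ** 2, phase_times, period)
    return np.sqrt(np.maximum(var, 0.0))


def compute_divergence_metrics(
    wss: TimeResolvedField,
    mesh: SurfaceMesh,
    eps: float = DEFAULT_EPS_NORM,
) -> DivergenceMetrics:
    """Full divergence characterization of one case.

    ``mean_nwss_div`` averages the instantaneous divergence over all phases
    (periodic quadrature) and then over the sac area; ``mean_tsvi`` is the
    area-weighted sac average of the per-vertex TSVI.  Sac averages exclude
    open-boundary vertices and vertices with zero shear at any phase.
    """
    div, degenerate = compute_nwss_div_series(wss, mesh, eps)
    tsvi = compute_tsvi(div, wss.phase_times, wss.period)

    areas = mesh.vertex_areas
    ok = mesh.sac_mask & ~mesh.boundary_vertices & ~degenerate.any(axis=0)
    if not ok.any():
        raise ValueError("no valid sac vertices for divergence averaging")
    w = areas[ok]
    time_avg = cycle_mean(div, wss.phase_times, wss.period)
    mean_div = float(np.sum(time_avg[ok] * w) / w.sum())
    mean_tsvi = float(np.sum(tsvi[ok] * w) / w.sum())
    return DivergenceMetrics(
        nwss_div=div,
        mean_nwss_div=mean_div,
        tsvi=tsvi,
        mean_tsvi=mean_tsvi,
        degenerate_counts=degenerate.sum(axis=1),
    )
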