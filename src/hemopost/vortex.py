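"""Vortex-core segmentation and temporal-persistence statistics.

Swirling regions are identified per cardiac phase from the cell-wise
velocity-gradient tensor J = ∇u (P1 gradients on each tetrahedron, exact
for linear velocity fields).  With S = (J + Jᵀ)/2 and Ω = (J − Jᵀ)/2, the
λ2 criterion marks a cell as vortical when the middle eigenvalue of
S² + Ω² is negative; the Q criterion (Q = ½(‖Ω‖² − ‖S‖²) > 0) is available
as an alternative.  Both depend on velocity only through its gradient, so
adding a uniform translation changes nothing.

Cores are the face-connected components of the thresholded criterion field
restricted to the sac: cells with λ2 < −f · max(−λ2) (f the normalized
threshold fraction, max taken over the whole cycle by default so cores are
comparable across phases).  Temporal persistence is quantified by the
degree of volume overlap (DVO) between the core regions of adjacent
phases — by default the Jaccard ratio intersection/union of core volumes —
averaged over consecutive phase pairs of the systole window (TADVO), along
with the temporally averaged total core volume and core count.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components

from .field_io import StructuralError, TimeResolvedField, VolumeMesh
from .wss_metrics import TemporalStatisticError

__all__ = [
    "VortexCoreSet",
    "VortexSummary",
    "compute_velocity_gradients",
    "compute_lambda2",
    "compute_q_criterion",
    "segment_cores",
    "compute_dvo",
    "summarize_vortex",
    "analyze_vortices",
    "MeshQualityError",
]


class MeshQualityError(ValueError):
    """Degenerate (zero-volume) tetrahedra make the P1 gradient singular."""


@dataclass
class VortexCoreSet:
    """Segmented swirling regions at one cardiac phase."""

    phase: int
    core_cells: np.ndarray       # (n_c,) bool
    labels: np.ndarray           # (n_c,) int, -1 outside cores, 0..k-1 inside
    core_volumes: np.ndarray     # (k,) mm^3 per label, descending
    n_cores: int
    criterion_field: np.ndarray  # (n_c,) lambda2 (or -Q) per cell
    mesh_id: int = field(default=0, repr=False)

    @property
    def total_volume(self) -> float:
        return float(self.core_volumes.sum())


@dataclass
class VortexSummary:
    tadvo: float          # mean DVO over adjacent systole-window phase pairs
    tadvo_std: float      # sample SD of those DVO values
    vortex_v: float       # temporally averaged total core volume (mm^3)
    num_core: float       # temporally averaged core count
    dvo_series: np.ndarray = field(default_factory=lambda: np.empty(0))
    any_empty_pair: bool = False


class _TetOperator:
    """Cached per-cell shape-function gradients and face adjacency."""

    def __init__(self, mesh: VolumeMesh):
        self.mesh = mesh
        p = mesh.nodes[mesh.cells]            # (n_c, 4, 3)
        e = p[:, 1:] - p[:, :1]               # (n_c, 3, 3) edge matrix rows
        det = np.linalg.det(e)
        bad = np.nonzero(np.abs(det) <= 1e-14)[0]
        if bad.size:
            raise MeshQualityError(
                f"zero-volume tetrahedra at indices {bad.tolist()[:20]}"
            )
        inv = np.linalg.inv(e)                # columns are grads of bary 1..3
        g123 = np.swapaxes(inv, 1, 2)         # (n_c, 3 funcs, 3 xyz)
        g0 = -g123.sum(axis=1, keepdims=True)
        self.grads = np.concatenate([g0, g123], axis=1)  # (n_c, 4, 3)

    def adjacency(self) -> tuple[np.ndarray, np.ndarray]:
        """Pairs of face-adjacent cell indices (i, j) with i < j."""
        cells = self.mesh.cells
        faces = np.sort(
            cells[:, [0, 1, 2, 0, 1, 3, 0, 2, 3, 1, 2, 3]].reshape(-1, 3), axis=1
        )
        owner = np.repeat(np.arange(cells.shape[0]), 4)
        order = np.lexsort(faces.T)
        faces, owner = faces[order], owner[order]
        same = np.all(faces[1:] == faces[:-1], axis=1)
        return owner[:-1][same], owner[1:][same]


_tet_cache: dict[int, _TetOperator] = {}


def _get_tet_operator(mesh: VolumeMesh) -> _TetOperator:
    op = _tet_cache.get(id(mesh))
    if op is None or op.mesh is not mesh:
        op = _TetOperator(mesh)
        _tet_cache.clear()
        _tet_cache[id(mesh)] = op
    return op


def compute_velocity_gradients(
    node_velocity: np.ndarray, mesh: VolumeMesh
) -> np.ndarray:
    """Cell-wise velocity-gradient tensor J[a, b] = ∂u_a/∂x_b, shape (n_c, 3, 3)."""
    node_velocity = np.asarray(node_velocity, dtype=float)
    if node_velocity.shape != (mesh.n_nodes, 3):
        raise ValueError("velocity must be defined on all nodes")
    op = _get_tet_operator(mesh)
    u = node_velocity[mesh.cells]              # (n_c, 4, 3)
    return np.einsum("niA,nib->nAb", u, op.grads)


def compute_lambda2(node_velocity: np.ndarray, mesh: VolumeMesh) -> np.ndarray:
    """λ2 per cell: middle eigenvalue of S² + Ω²; vortex cells have λ2 < 0."""
    j = compute_velocity_gradients(node_velocity, mesh)
    s = 0.5 * (j + np.swapaxes(j, 1, 2))
    w = 0.5 * (j - np.swapaxes(j, 1, 2))
    m = s @ s + w @ w
    return np.linalg.eigvalsh(m)[:, 1]


def compute_q_criterion(node_velocity: np.ndarray, mesh: VolumeMesh) -> np.ndarray:
    """Q per cell: ½(‖Ω‖² − ‖S‖²); vortex cells have Q > 0."""
    j = compute_velocity_gradients(node_velocity, mesh)
    s = 0.5 * (j + np.swapaxes(j, 1, 2))
    w = 0.5 * (j - np.swapaxes(j, 1, 2))
    return 0.5 * (
        np.einsum("nab,nab->n", w, w) - np.einsum("nab,nab->n", s, s)
    )


def segment_cores(
    criterion: np.ndarray,
    mesh: VolumeMesh,
    threshold_fraction: float,
    phase: int = 0,
    reference_magnitude: float | None = None,
    min_cells: int = 1,
) -> VortexCoreSet:
    """Threshold a vortex-criterion field and label face-connected cores.

    ``criterion`` follows the λ2 sign convention (vortical where negative;
    pass −Q to use the Q criterion).  Vortex cells are those with
    criterion < −threshold_fraction · M where M is the strongest negative
    magnitude — per phase by default, or ``reference_magnitude`` when the
    caller normalizes over the whole cycle.  Components are restricted to
    sac cells, discarded below ``min_cells``, and labelled deterministically
    by descending volume (ties: lowest member cell index).
    """
    if not (0.0 < threshold_fraction < 1.0):
        raise ValueError("threshold_fraction must be in (0, 1)")
    criterion = np.asarray(criterion, dtype=float)
    if criterion.shape != (mesh.n_cells,):
        raise ValueError("criterion must be per cell")
    sac = mesh.sac_mask
    neg = criterion < 0
    if reference_magnitude is None:
        relevant = neg & sac
        reference_magnitude = float(-criterion[relevant].min()) if relevant.any() else 0.0
    labels = np.full(mesh.n_cells, -1, dtype=np.int64)
    if reference_magnitude <= 0:
        return VortexCoreSet(
            phase=phase, core_cells=np.zeros(mesh.n_cells, dtype=bool),
            labels=labels, core_volumes=np.empty(0), n_cores=0,
            criterion_field=criterion, mesh_id=id(mesh),
        )
    vortex = sac & (criterion < -threshold_fraction * reference_magnitude)

    ii, jj = _get_tet_operator(mesh).adjacency()
    keep = vortex[ii] & vortex[jj]
    ii, jj = ii[keep], jj[keep]
    n = mesh.n_cells
    graph = coo_matrix(
        (np.ones(len(ii)), (ii, jj)), shape=(n, n)
    )
    n_comp, comp = connected_components(graph, directed=False)

    vols = mesh.cell_volumes
    comp_ids = np.unique(comp[vortex])
    parts = []
    for cid in comp_ids:
        members = np.nonzero(vortex & (comp == cid))[0]
        if members.size < min_cells:
            continue
        parts.append((float(vols[members].sum()), int(members.min()), members))
    parts.sort(key=lambda t: (-t[0], t[1]))
    core_volumes = np.array([p[0] for p in parts])
    for lab, (_, _, members) in enumerate(parts):
        labels[members] = lab
    core_cells = labels >= 0
    return VortexCoreSet(
        phase=phase, core_cells=core_cells, labels=labels,
        core_volumes=core_volumes, n_cores=len(parts),
        criterion_field=criterion, mesh_id=id(mesh),
    )


def compute_dvo(
    a: VortexCoreSet,
    b: VortexCoreSet,
    cell_volumes: np.ndarray,
    mode: str = "jaccard",
) -> float:
    """Degree of volume overlap between the core regions of two phases.

    ``jaccard``: volume(A∩B)/volume(A∪B); ``mean``: volume(A∩B) divided by
    the mean of the two core volumes.  Both lie in [0, 1].  When both
    phases have no cores the flow is (trivially) temporally consistent and
    the DVO is defined as 1.
    """
    if a.mesh_id != b.mesh_id or a.core_cells.shape != b.core_cells.shape:
        raise StructuralError("DVO requires core sets on the same mesh")
    inter = float(cell_volumes[a.core_cells & b.core_cells].sum())
    va = float(cell_volumes[a.core_cells].sum())
    vb = float(cell_volumes[b.core_cells].sum())
    if va == 0.0 and vb == 0.0:
        return 1.0
    if mode == "jaccard":
        union = va + vb - inter
        return inter / union if union > 0 else 1.0
    if mode == "mean":
        return inter / (0.5 * (va + vb))
    raise ValueError(f"unknown DVO mode {mode!r}")


def summarize_vortex(
    core_sets: list[VortexCoreSet],
    systole_window: tuple[int, int],
    cell_volumes: np.ndarray,
    dvo_mode: str = "jaccard",
) -> VortexSummary:
    """TADVO and temporally averaged core volume/count over the window.

    ``core_sets`` is indexed by phase; the window is an inclusive phase
    range and must contain at least two phases.
    """
    lo, hi = systole_window
    window = [cs for cs in core_sets if lo <= cs.phase <= hi]
    if len(window) < 2:
        raise TemporalStatisticError("systole window must contain >= 2 phases")
    window.sort(key=lambda cs: cs.phase)
    dvo = np.array([
        compute_dvo(window[k], window[k + 1], cell_volumes, dvo_mode)
        for k in range(len(window) - 1)
    ])
    any_empty = any(
        cs.n_cores == 0 and nxt.n_cores == 0
        for cs, nxt in zip(window[:-1], window[1:])
    )
    return VortexSummary(
        tadvo=float(dvo.mean()),
        tadvo_std=float(dvo.std(ddof=1)) if dvo.size > 1 else 0.0,
        vortex_v=float(np.mean([cs.total_volume for cs in window])),
        num_core=float(np.mean([cs.n_cores for cs in window])),
        dvo_series=dvo,
        any_empty_pair=any_empty,
    )


def analyze_vortices(
    velocity: TimeResolvedField,
    mesh: VolumeMesh,
    threshold_fraction: float = 0.2,
    systole_window: tuple[int, int] | None = None,
    criterion: str = "lambda2",
    normalization: str = "cycle",
    min_cells: int = 1,
    dvo_mode: str = "jaccard",
) -> tuple[list[VortexCoreSet], VortexSummary]:
    """Segment cores at every phase and summarize temporal persistence.

    ``normalization='cycle'`` thresholds every phase against the strongest
    negative criterion value of the whole cycle (cores comparable across
    phases); ``'phase'`` normalizes each phase against its own extremum.
    """
    if systole_window is None:
        systole_window = (0, velocity.n_phases - 1)
    crit_fields = []
    for k in range(velocity.n_phases):
        if criterion == "lambda2":
            c = compute_lambda2(velocity.values[k], mesh)
        elif criterion == "q":
            c = -compute_q_criterion(velocity.values[k], mesh)
        else:
            raise ValueError(f"unknown vortex criterion {criterion!r}")
        crit_fields.append(c)
    ref: float | None = None
    if normalization == "cycle":
        neg_max = 0.0
        for c in crit_fields:
            rel = mesh.sac_mask & (c < 0)
            if rel.any():
                neg_max = max(neg_max, float(-c[rel].min()))
        ref = neg_max
    elif normalization != "phase":
        raise ValueError(f"unknown normalization {normalization!r}")
    core_sets = [
        segment_cores(
            c, mesh, threshold_fraction, phase=k,
            reference_magnitude=ref, min_cells=min_cells,
        )
        for k, c in enumerate(crit_fields)
    ]
    summary = summarize_vortex(core_sets, systole_window, mesh.cell_volumes, dvo_mode)
    return core_sets, summary
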