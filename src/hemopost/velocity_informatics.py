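"""Velocity informatics: texture features of the sac velocity field.

The sac velocity at peak systole is resampled onto an axis-aligned voxel
grid (barycentric interpolation within each tetrahedron, exact for linear
fields) and encoded as two scalar channels:

* ``Magnitude`` — |u| in mm/s;
* ``Direction`` — angle in degrees [0, 180] between u and the sac's
  dominant-flow axis (first principal axis of the in-sac velocity vectors,
  signed so the mean projection is non-negative).

Each channel is quantized to ``n_levels`` gray levels by equal-width
binning between the in-mask minimum and maximum, and three standard
texture-feature families are computed on the quantized volume:

* GLCM — gray-level co-occurrence matrices over the 13 unique 3D offsets
  at Chebyshev distance 1, symmetric and normalized, 24 features averaged
  over offsets;
* GLRLM — gray-level run-length matrices over the same 13 directions,
  runs truncated at the mask boundary, 16 features averaged over
  directions;
* GLSZM — gray-level size-zone matrix with 26-connected zones, 16
  features (single matrix, no direction averaging).

Feature definitions follow the standard (IBSI-consistent) formulas and the
naming used by common radiomics tooling (GLCM full names; GLRLM/GLSZM
abbreviations such as HGLRE, LAE, SZNU).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .field_io import VolumeMesh

__all__ = [
    "GrayLevelVolume",
    "voxelize_sac",
    "quantize",
    "glcm_features",
    "glrlm_features",
    "glszm_features",
    "vi_pipeline",
    "GLCM_FEATURE_NAMES",
    "GLRLM_FEATURE_NAMES",
    "GLSZM_FEATURE_NAMES",
    "OFFSETS_3D",
    "DegenerateInputError",
]

# the 13 unique 3D offsets at Chebyshev distance 1 (half of the 26)
OFFSETS_3D: tuple[tuple[int, int, int], ...] = tuple(
    (a, b, c)
    for a in (-1, 0, 1) for b in (-1, 0, 1) for c in (-1, 0, 1)
    if (a, b, c) > (0, 0, 0)
)

GLCM_FEATURE_NAMES = (
    "Autocorrelation", "ClusterProminence", "ClusterShade", "ClusterTendency",
    "Contrast", "Correlation", "DifferenceAverage", "DifferenceEntropy",
    "DifferenceVariance", "Id", "Idm", "Idmn", "Idn", "Imc1", "Imc2",
    "InverseVariance", "JointAverage", "JointEnergy", "JointEntropy",
    "MCC", "MaximumProbability", "SumAverage", "SumEntropy", "SumSquares",
)
GLRLM_FEATURE_NAMES = (
    "SRE", "LRE", "GLN", "GLNN", "RLN", "RLNN", "RunPercentage",
    "GrayLevelVariance", "RunVariance", "RunEntropy",
    "LGLRE", "HGLRE", "SRLGLE", "SRHGLE", "LRLGLE", "LRHGLE",
)
GLSZM_FEATURE_NAMES = (
    "SAE", "LAE", "GLN", "GLNN", "SZNU", "SZNN", "ZonePercentage",
    "GrayLevelVariance", "ZoneVariance", "ZoneEntropy",
    "LGLZE", "HGLZE", "SALGLE", "SAHGLE", "LALGLE", "LAHGLE",
)


class DegenerateInputError(ValueError):
    """Mask too small/disconnected to form any neighbor pair or run."""


@dataclass
class GrayLevelVolume:
    """Quantized voxel image of one channel of the sac velocity content."""

    voxels: np.ndarray      # (nx, ny, nz) int; 1..n_levels in mask, 0 outside
    spacing: float          # mm, isotropic
    mask: np.ndarray        # (nx, ny, nz) bool
    channel: str            # "magnitude" | "direction"
    n_levels: int

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.voxels.shape != self.mask.shape:
            raise ValueError("voxels and mask shapes differ")
        if not self.mask.any():
            raise ValueError("mask is empty")
        inside = self.voxels[self.mask]
        if inside.min() < 1 or inside.max() > self.n_levels:
            raise ValueError("in-mask gray levels must lie in 1..n_levels")


# ----------------------------------------------------------------------------
# Voxelization

def dominant_flow_axis(velocities: np.ndarray) -> np.ndarray:
    """First principal axis of a set of velocity vectors, mean-aligned."""
    v = np.asarray(velocities, dtype=float)
    _, _, vt = np.linalg.svd(v - 0.0, full_matrices=False)
    axis = vt[0]
    if float(v.mean(axis=0) @ axis) < 0:
        axis = -axis
    return axis


def voxelize_sac(
    node_velocity: np.ndarray,
    mesh: VolumeMesh,
    spacing: float | None = None,
    grid_divisor: int = 64,
    axis: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, float]:
    """Resample the sac velocity onto a voxel grid.

    Returns ``(magnitude, direction_deg, mask, spacing)``.  The grid is
    axis-aligned, covers the sac bounding box padded by one voxel, and has
    isotropic spacing (default: max sac extent / ``grid_divisor``).  Voxel
    centers are located in the sac tetrahedra; in-sac voxels carry the
    barycentric interpolation of the node velocities, everything else is
    masked out.
    """
    node_velocity = np.asarray(node_velocity, dtype=float)
    if node_velocity.shape != (mesh.n_nodes, 3):
        raise ValueError("velocity must be defined on all nodes")
    if not mesh.sac_mask.any():
        raise ValueError("sac_mask is empty")
    sac_cells = np.nonzero(mesh.sac_mask)[0]
    sac_nodes = np.unique(mesh.cells[sac_cells])
    lo = mesh.nodes[sac_nodes].min(axis=0)
    hi = mesh.nodes[sac_nodes].max(axis=0)
    extent = float((hi - lo).max())
    if spacing is None:
        spacing = extent / grid_divisor
    if spacing <= 0 or spacing > extent:
        raise ValueError("spacing must be positive and no larger than the sac extent")

    origin = lo - spacing  # one-voxel pad
    shape = np.ceil((hi - origin) / spacing).astype(int) + 2
    vel = np.full((*shape, 3), np.nan)
    filled = np.zeros(tuple(shape), dtype=bool)

    nodes = mesh.nodes
    for ci in sac_cells:
        quad = mesh.cells[ci]
        p = nodes[quad]                       # (4, 3)
        cl = np.floor((p.min(axis=0) - origin) / spacing).astype(int)
        ch = np.ceil((p.max(axis=0) - origin) / spacing).astype(int)
        cl = np.maximum(cl, 0)
        ch = np.minimum(ch, shape - 1)
        if np.any(ch < cl):
            continue
        ix, iy, iz = np.meshgrid(
            *(np.arange(a, b + 1) for a, b in zip(cl, ch)), indexing="ij"
        )
        centers = origin + (np.stack([ix, iy, iz], axis=-1) + 0.5) * spacing
        pts = centers.reshape(-1, 3)
        # barycentric coordinates wrt the tet
        t = np.column_stack([p[1] - p[0], p[2] - p[0], p[3] - p[0]])
        try:
            bary123 = np.linalg.solve(t, (pts - p[0]).T).T
        except np.linalg.LinAlgError:
            continue
        b0 = 1.0 - bary123.sum(axis=1)
        bary = np.column_stack([b0, bary123])
        inside = np.all(bary >= -1e-9, axis=1)
        if not inside.any():
            continue
        interp = bary[inside] @ node_velocity[quad]
        idx = np.stack([ix, iy, iz], axis=-1).reshape(-1, 3)[inside]
        vel[idx[:, 0], idx[:, 1], idx[:, 2]] = interp
        filled[idx[:, 0], idx[:, 1], idx[:, 2]] = True

    if not filled.any():
        raise ValueError("no voxel centers fell inside the sac; spacing too coarse")
    magnitude = np.zeros(tuple(shape))
    magnitude[filled] = np.linalg.norm(vel[filled], axis=-1)

    if axis is None:
        axis = dominant_flow_axis(node_velocity[sac_nodes])
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    direction = np.zeros(tuple(shape))
    v_in = vel[filled]
    norms = np.linalg.norm(v_in, axis=-1)
    cosang = np.zeros(len(v_in))
    nz = norms > 0
    cosang[nz] = (v_in[nz] @ axis) / norms[nz]
    cosang[~nz] = 1.0  # zero velocity: angle 0 by convention
    direction[filled] = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
    return magnitude, direction, filled, float(spacing)


def quantize(volume: np.ndarray, mask: np.ndarray, n_levels: int,
             channel: str = "magnitude", spacing: float = 1.0) -> GrayLevelVolume:
    """Equal-width gray-level quantization between the in-mask min and max.

    Bins are half-open except the top bin, which is closed; a constant
    volume maps to level 1 everywhere.
    """
    if n_levels < 2:
        raise ValueError("n_levels must be >= 2")
    volume = np.asarray(volume, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    inside = volume[mask]
    if not np.all(np.isfinite(inside)):
        raise ValueError("in-mask values must be finite")
    vmin, vmax = float(inside.min()), float(inside.max())
    voxels = np.zeros(volume.shape, dtype=np.int64)
    if vmax == vmin:
        voxels[mask] = 1
    else:
        edges = np.linspace(vmin, vmax, n_levels + 1)
        voxels[mask] = np.digitize(inside, edges[1:-1], right=False) + 1
    return GrayLevelVolume(
        voxels=voxels, spacing=spacing, mask=mask,
        channel=channel, n_levels=n_levels,
    )


# ----------------------------------------------------------------------------
# GLCM

def _xlog2x(p: np.ndarray) -> np.ndarray:
    out = np.zeros_like(p)
    nz = p > 0
    out[nz] = p[nz] * np.log2(p[nz])
    return out


def _glcm_matrix(gl: GrayLevelVolume, offset: tuple[int, int, int]) -> np.ndarray:
    """Symmetric normalized co-occurrence matrix for one offset (or None)."""
    img = gl.voxels
    mask = gl.mask
    ng = int(img[mask].max())
    sl_a = tuple(
        slice(max(0, -d), img.shape[k] - max(0, d)) for k, d in enumerate(offset)
    )
    sl_b = tuple(
        slice(max(0, d), img.shape[k] + min(0, d)) for k, d in enumerate(offset)
    )
    a, b = img[sl_a], img[sl_b]
    ok = mask[sl_a] & mask[sl_b]
    if not ok.any():
        return None
    pairs = a[ok] - 1 + (b[ok] - 1) * ng
    counts = np.bincount(pairs, minlength=ng * ng).reshape(ng, ng).T
    counts = counts + counts.T
    return counts / counts.sum()


def _glcm_single(p: np.ndarray) -> dict[str, float]:
    ng = p.shape[0]
    i = np.arange(1, ng + 1)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    px = p.sum(axis=1)
    mu = float((ii * p).sum())            # == mean of px by symmetry
    sigma2 = float(((ii - mu) ** 2 * p).sum())
    sigma = np.sqrt(sigma2)

    # difference distribution p_{|i-j|}
    k_diff = np.arange(ng)
    p_diff = np.array([p[np.abs(ii - jj) == k].sum() for k in k_diff])
    diff_avg = float((k_diff * p_diff).sum())
    # sum distribution p_{i+j}
    k_sum = np.arange(2, 2 * ng + 1)
    p_sum = np.array([p[ii + jj == k].sum() for k in k_sum])

    hxy = float(-_xlog2x(p).sum())
    px_py = np.outer(px, px)
    nzb = (p > 0) & (px_py > 0)
    hxy1 = float(-(p[nzb] * np.log2(px_py[nzb])).sum())
    hxy2 = float(-_xlog2x(px_py).sum())
    hx = float(-_xlog2x(px).sum())

    if hx > 0:
        imc1 = (hxy - hxy1) / hx
    else:
        imc1 = 0.0
    imc2 = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - hxy)))))

    if sigma > 0:
        corr = float(((ii - mu) * (jj - mu) * p).sum() / sigma2)
    else:
        corr = 1.0

    # MCC: second-largest eigenvalue magnitude of Q
    # Q(i,j) = sum_k p(i,k) p(j,k) / (px(i) py(k)); p symmetric so py = px
    active = px > 0
    pa = p[np.ix_(active, active)]
    pxa = px[active]
    m = pa / pxa[:, None]
    q = m @ m
    if q.shape[0] > 1:
        ev = np.sort(np.linalg.eigvals(q).real)
        mcc = float(np.sqrt(max(0.0, ev[-2])))
    else:
        mcc = 1.0

    absdiff = np.abs(ii - jj)
    off_diag = absdiff > 0
    return {
        "Autocorrelation": float((ii * jj * p).sum()),
        "ClusterProminence": float(((ii + jj - 2 * mu) ** 4 * p).sum()),
        "ClusterShade": float(((ii + jj - 2 * mu) ** 3 * p).sum()),
        "ClusterTendency": float(((ii + jj - 2 * mu) ** 2 * p).sum()),
        "Contrast": float(((ii - jj) ** 2 * p).sum()),
        "Correlation": corr,
        "DifferenceAverage": diff_avg,
        "DifferenceEntropy": float(-_xlog2x(p_diff).sum()),
        "DifferenceVariance": float(((k_diff - diff_avg) ** 2 * p_diff).sum()),
        "Id": float((p / (1.0 + absdiff)).sum()),
        "Idm": float((p / (1.0 + absdiff ** 2)).sum()),
        "Idmn": float((p / (1.0 + (absdiff / ng) ** 2)).sum()),
        "Idn": float((p / (1.0 + absdiff / ng)).sum()),
        "Imc1": imc1,
        "Imc2": imc2,
        "InverseVariance": float((p[off_diag] / absdiff[off_diag] ** 2).sum()),
        "JointAverage": mu,
        "JointEnergy": float((p ** 2).sum()),
        "JointEntropy": hxy,
        "MCC": mcc,
        "MaximumProbability": float(p.max()),
        "SumAverage": float((k_sum * p_sum).sum()),
        "SumEntropy": float(-_xlog2x(p_sum).sum()),
        "SumSquares": sigma2,
    }


def glcm_features(gl: GrayLevelVolume) -> dict[str, float]:
    """24 co-occurrence features, averaged over the 13 unique 3D offsets."""
    per_offset = []
    for off in OFFSETS_3D:
        p = _glcm_matrix(gl, off)
        if p is not None:
            per_offset.append(_glcm_single(p))
    if not per_offset:
        raise DegenerateInputError("mask yields no valid neighbor pairs")
    return {
        name: float(np.mean([f[name] for f in per_offset]))
        for name in GLCM_FEATURE_NAMES
    }


# ----------------------------------------------------------------------------
# GLRLM

def _run_lengths(gl: GrayLevelVolume, direction: tuple[int, int, int]):
    """(level, length) arrays of maximal in-mask runs along one direction."""
    img, mask = gl.voxels, gl.mask
    coords = np.argwhere(mask)
    d = np.array(direction)
    t = coords @ d                           # position along the line (x |d|^2 steps)
    line_key = coords * (d @ d) - t[:, None] * d  # constant along a line
    levels = img[mask]
    order = np.lexsort((t, *line_key.T))
    t_s = t[order]
    key_s = line_key[order]
    lev_s = levels[order]
    step = d @ d
    same_line = np.all(key_s[1:] == key_s[:-1], axis=1)
    contiguous = (t_s[1:] - t_s[:-1]) == step
    same_level = lev_s[1:] == lev_s[:-1]
    brk = ~(same_line & contiguous & same_level)
    boundaries = np.concatenate([[0], np.nonzero(brk)[0] + 1, [len(t_s)]])
    lengths = np.diff(boundaries)
    run_levels = lev_s[boundaries[:-1]]
    return run_levels, lengths


def _glrlm_single(run_levels: np.ndarray, lengths: np.ndarray,
                  n_voxels: int) -> dict[str, float]:
    i = run_levels.astype(float)
    r = lengths.astype(float)
    nr = float(len(r))
    gl_counts = np.bincount(run_levels)
    rl_counts = np.bincount(lengths)
    gln = float((gl_counts.astype(float) ** 2).sum())
    rln = float((rl_counts.astype(float) ** 2).sum())
    mu_i = i.sum() / nr
    mu_r = r.sum() / nr
    # run-probability entropy over the (i, r) matrix
    pair = run_levels.astype(np.int64) * (int(lengths.max()) + 1) + lengths
    pair_counts = np.bincount(pair)
    pp = pair_counts[pair_counts > 0] / nr
    return {
        "SRE": float((1.0 / r ** 2).sum() / nr),
        "LRE": float((r ** 2).sum() / nr),
        "GLN": gln / nr,
        "GLNN": gln / nr ** 2,
        "RLN": rln / nr,
        "RLNN": rln / nr ** 2,
        "RunPercentage": nr / n_voxels,
        "GrayLevelVariance": float(((i - mu_i) ** 2).sum() / nr),
        "RunVariance": float(((r - mu_r) ** 2).sum() / nr),
        "RunEntropy": float(-(pp * np.log2(pp)).sum()),
        "LGLRE": float((1.0 / i ** 2).sum() / nr),
        "HGLRE": float((i ** 2).sum() / nr),
        "SRLGLE": float((1.0 / (i ** 2 * r ** 2)).sum() / nr),
        "SRHGLE": float((i ** 2 / r ** 2).sum() / nr),
        "LRLGLE": float((r ** 2 / i ** 2).sum() / nr),
        "LRHGLE": float((i ** 2 * r ** 2).sum() / nr),
    }


def glrlm_features(gl: GrayLevelVolume) -> dict[str, float]:
    """16 run-length features, averaged over the 13 directions."""
    n_vox = int(gl.mask.sum())
    if n_vox < 2:
        raise DegenerateInputError("need at least 2 in-mask voxels")
    per_dir = []
    for d in OFFSETS_3D:
        levels, lengths = _run_lengths(gl, d)
        per_dir.append(_glrlm_single(levels, lengths, n_vox))
    return {
        name: float(np.mean([f[name] for f in per_dir]))
        for name in GLRLM_FEATURE_NAMES
    }


# ----------------------------------------------------------------------------
# GLSZM

def _zones(gl: GrayLevelVolume):
    """(level, size) arrays of 26-connected equal-level zones in the mask."""
    structure = np.ones((3, 3, 3), dtype=bool)
    levels_present = np.unique(gl.voxels[gl.mask])
    zone_levels, zone_sizes = [], []
    for lev in levels_present:
        lab, n = ndimage.label(gl.mask & (gl.voxels == lev), structure=structure)
        if n == 0:
            continue
        sizes = np.bincount(lab.ravel())[1:]
        zone_levels.extend([int(lev)] * n)
        zone_sizes.extend(sizes.tolist())
    return np.array(zone_levels), np.array(zone_sizes)


def glszm_features(gl: GrayLevelVolume) -> dict[str, float]:
    """16 size-zone features from 26-connected equal-level zones."""
    n_vox = int(gl.mask.sum())
    if n_vox < 1:
        raise DegenerateInputError("empty mask")
    zl, zs = _zones(gl)
    i = zl.astype(float)
    s = zs.astype(float)
    nz = float(len(s))
    gl_counts = np.bincount(zl)
    sz_counts = np.bincount(zs)
    gln = float((gl_counts.astype(float) ** 2).sum())
    szn = float((sz_counts.astype(float) ** 2).sum())
    mu_i = i.sum() / nz
    mu_s = s.sum() / nz
    pair = zl.astype(np.int64) * (int(zs.max()) + 1) + zs
    pair_counts = np.bincount(pair)
    pp = pair_counts[pair_counts > 0] / nz
    return {
        "SAE": float((1.0 / s ** 2).sum() / nz),
        "LAE": float((s ** 2).sum() / nz),
        "GLN": gln / nz,
        "GLNN": gln / nz ** 2,
        "SZNU": szn / nz,
        "SZNN": szn / nz ** 2,
        "ZonePercentage": nz / n_vox,
        "GrayLevelVariance": float(((i - mu_i) ** 2).sum() / nz),
        "ZoneVariance": float(((s - mu_s) ** 2).sum() / nz),
        "ZoneEntropy": float(-(pp * np.log2(pp)).sum()),
        "LGLZE": float((1.0 / i ** 2).sum() / nz),
        "HGLZE": float((i ** 2).sum() / nz),
        "SALGLE": float((1.0 / (i ** 2 * s ** 2)).sum() / nz),
        "SAHGLE": float((i ** 2 / s ** 2).sum() / nz),
        "LALGLE": float((s ** 2 / i ** 2).sum() / nz),
        "LAHGLE": float((i ** 2 * s ** 2).sum() / nz),
    }


# ----------------------------------------------------------------------------
# Pipeline

def texture_features(gl: GrayLevelVolume) -> dict[str, float]:
    """All 56 features of one channel, keyed ``GLCM.*`` / ``GLRLM.*`` / ``GLSZM.*``."""
    out: dict[str, float] = {}
    for name, val in glcm_features(gl).items():
        out[f"GLCM.{name}"] = val
    for name, val in glrlm_features(gl).items():
        out[f"GLRLM.{name}"] = val
    for name, val in glszm_features(gl).items():
        out[f"GLSZM.{name}"] = val
    return out


def vi_pipeline(
    node_velocity: np.ndarray,
    mesh: VolumeMesh,
    n_levels: int = 32,
    spacing: float | None = None,
    grid_divisor: int = 64,
    axis: np.ndarray | None = None,
) -> dict[str, float]:
    """Voxelize → quantize → texture features for both channels.

    Returns 112 named values keyed ``Magnitude_GLCM.Autocorrelation`` etc.
    Deterministic for fixed inputs and configuration.
    """
    mag, direction, mask, sp = voxelize_sac(
        node_velocity, mesh, spacing=spacing, grid_divisor=grid_divisor, axis=axis
    )
    out: dict[str, float] = {}
    for channel, vol in (("Magnitude", mag), ("Direction", direction)):
        gl = quantize(vol, mask, n_levels, channel=channel.lower(), spacing=sp)
        for key, val in texture_features(gl).items():
            out[f"{channel}_{key}"] = val
    return out
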