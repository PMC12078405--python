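"""Naive reference implementations of the texture-feature families.

Deliberately slow and structurally independent of the package: matrices
are built by explicit Python loops over voxels (dict counting, BFS flood
fill) and features are evaluated directly from the standard definitions.
Used only to cross-check the vectorized implementations on tiny volumes.
"""

from __future__ import annotations

import math
from collections import defaultdict

import numpy as np

OFFSETS = [
    (a, b, c)
    for a in (-1, 0, 1) for b in (-1, 0, 1) for c in (-1, 0, 1)
    if (a, b, c) > (0, 0, 0)
]
NEIGHBORS_26 = [
    (a, b, c)
    for a in (-1, 0, 1) for b in (-1, 0, 1) for c in (-1, 0, 1)
    if (a, b, c) != (0, 0, 0)
]


def _in_bounds(pos, shape):
    return all(0 <= p < s for p, s in zip(pos, shape))


def _log2(x: float) -> float:
    return math.log2(x) if x > 0 else 0.0


# ---------------------------------------------------------------- GLCM

def glcm_matrix(img: np.ndarray, mask: np.ndarray, offset) -> dict:
    """Symmetric co-occurrence counts {(i, j): c} for one offset."""
    counts: dict = defaultdict(float)
    shape = img.shape
    for x in range(shape[0]):
        for y in range(shape[1]):
            for z in range(shape[2]):
                if not mask[x, y, z]:
                    continue
                nb = (x + offset[0], y + offset[1], z + offset[2])
                if not _in_bounds(nb, shape) or not mask[nb]:
                    continue
                a, b = int(img[x, y, z]), int(img[nb])
                counts[(a, b)] += 1.0
                counts[(b, a)] += 1.0
    return dict(counts)


def glcm_features_single(counts: dict, ng: int) -> dict:
    total = sum(counts.values())
    p = {k: v / total for k, v in counts.items()}
    px = defaultdict(float)
    for (i, j), v in p.items():
        px[i] += v
    mu = sum(i * v for i, v in px.items())
    sigma2 = sum((i - mu) ** 2 * v for i, v in px.items())

    p_diff = defaultdict(float)
    p_sum = defaultdict(float)
    for (i, j), v in p.items():
        p_diff[abs(i - j)] += v
        p_sum[i + j] += v
    da = sum(k * v for k, v in p_diff.items())

    hxy = -sum(v * _log2(v) for v in p.values())
    hxy1 = -sum(v * _log2(px[i] * px[j]) for (i, j), v in p.items())
    hxy2 = -sum(
        px[i] * px[j] * _log2(px[i] * px[j]) for i in px for j in px
    )
    hx = -sum(v * _log2(v) for v in px.values())
    imc1 = (hxy - hxy1) / hx if hx > 0 else 0.0
    imc2 = math.sqrt(max(0.0, 1.0 - math.exp(-2.0 * (hxy2 - hxy))))

    sigma = math.sqrt(sigma2)
    if sigma > 0:
        corr = sum((i - mu) * (j - mu) * v for (i, j), v in p.items()) / sigma2
    else:
        corr = 1.0

    levels = sorted(px)
    if len(levels) > 1:
        q = np.zeros((len(levels), len(levels)))
        for a, i in enumerate(levels):
            for b, j in enumerate(levels):
                q[a, b] = sum(
                    p.get((i, k), 0.0) * p.get((j, k), 0.0) / (px[i] * px[k])
                    for k in levels
                )
        ev = sorted(np.linalg.eigvals(q).real)
        mcc = math.sqrt(max(0.0, ev[-2]))
    else:
        mcc = 1.0

    return {
        "Autocorrelation": sum(i * j * v for (i, j), v in p.items()),
        "ClusterProminence": sum((i + j - 2 * mu) ** 4 * v for (i, j), v in p.items()),
        "ClusterShade": sum((i + j - 2 * mu) ** 3 * v for (i, j), v in p.items()),
        "ClusterTendency": sum((i + j - 2 * mu) ** 2 * v for (i, j), v in p.items()),
        "Contrast": sum((i - j) ** 2 * v for (i, j), v in p.items()),
        "Correlation": corr,
        "DifferenceAverage": da,
        "DifferenceEntropy": -sum(v * _log2(v) for v in p_diff.values()),
        "DifferenceVariance": sum((k - da) ** 2 * v for k, v in p_diff.items()),
        "Id": sum(v / (1.0 + abs(i - j)) for (i, j), v in p.items()),
        "Idm": sum(v / (1.0 + (i - j) ** 2) for (i, j), v in p.items()),
        "Idmn": sum(v / (1.0 + ((i - j) / ng) ** 2) for (i, j), v in p.items()),
        "Idn": sum(v / (1.0 + abs(i - j) / ng) for (i, j), v in p.items()),
        "Imc1": imc1,
        "Imc2": imc2,
        "InverseVariance": sum(
            v / (i - j) ** 2 for (i, j), v in p.items() if i != j
        ),
        "JointAverage": mu,
        "JointEnergy": sum(v * v for v in p.values()),
        "JointEntropy": hxy,
        "MCC": mcc,
        "MaximumProbability": max(p.values()),
        "SumAverage": sum(k * v for k, v in p_sum.items()),
        "SumEntropy": -sum(v * _log2(v) for v in p_sum.values()),
        "SumSquares": sigma2,
    }


def glcm_features(img: np.ndarray, mask: np.ndarray) -> dict:
    ng = int(img[mask].max())
    per = []
    for off in OFFSETS:
        counts = glcm_matrix(img, mask, off)
        if counts:
            per.append(glcm_features_single(counts, ng))
    return {k: float(np.mean([f[k] for f in per])) for k in per[0]}


# ---------------------------------------------------------------- GLRLM

def run_length_matrix(img: np.ndarray, mask: np.ndarray, direction) -> dict:
    """Run counts {(level, length): n} along one direction, by walking."""
    counts: dict = defaultdict(int)
    shape = img.shape
    d = direction
    for x in range(shape[0]):
        for y in range(shape[1]):
            for z in range(shape[2]):
                if not mask[x, y, z]:
                    continue
                lev = int(img[x, y, z])
                prev = (x - d[0], y - d[1], z - d[2])
                if (_in_bounds(prev, shape) and mask[prev]
                        and int(img[prev]) == lev):
                    continue  # not a run start
                length = 1
                cur = (x + d[0], y + d[1], z + d[2])
                while (_in_bounds(cur, shape) and mask[cur]
                       and int(img[cur]) == lev):
                    length += 1
                    cur = (cur[0] + d[0], cur[1] + d[1], cur[2] + d[2])
                counts[(lev, length)] += 1
    return dict(counts)


def glrlm_features_single(counts: dict, n_voxels: int) -> dict:
    nr = float(sum(counts.values()))
    gl = defaultdict(float)
    rl = defaultdict(float)
    for (i, r), c in counts.items():
        gl[i] += c
        rl[r] += c
    mu_i = sum(i * c for (i, r), c in counts.items()) / nr
    mu_r = sum(r * c for (i, r), c in counts.items()) / nr
    return {
        "SRE": sum(c / r ** 2 for (i, r), c in counts.items()) / nr,
        "LRE": sum(c * r ** 2 for (i, r), c in counts.items()) / nr,
        "GLN": sum(v ** 2 for v in gl.values()) / nr,
        "GLNN": sum(v ** 2 for v in gl.values()) / nr ** 2,
        "RLN": sum(v ** 2 for v in rl.values()) / nr,
        "RLNN": sum(v ** 2 for v in rl.values()) / nr ** 2,
        "RunPercentage": nr / n_voxels,
        "GrayLevelVariance": sum(
            (i - mu_i) ** 2 * c for (i, r), c in counts.items()
        ) / nr,
        "RunVariance": sum(
            (r - mu_r) ** 2 * c for (i, r), c in counts.items()
        ) / nr,
        "RunEntropy": -sum(
            (c / nr) * _log2(c / nr) for c in counts.values()
        ),
        "LGLRE": sum(c / i ** 2 for (i, r), c in counts.items()) / nr,
        "HGLRE": sum(c * i ** 2 for (i, r), c in counts.items()) / nr,
        "SRLGLE": sum(c / (i ** 2 * r ** 2) for (i, r), c in counts.items()) / nr,
        "SRHGLE": sum(c * i ** 2 / r ** 2 for (i, r), c in counts.items()) / nr,
        "LRLGLE": sum(c * r ** 2 / i ** 2 for (i, r), c in counts.items()) / nr,
        "LRHGLE": sum(c * i ** 2 * r ** 2 for (i, r), c in counts.items()) / nr,
    }


def glrlm_features(img: np.ndarray, mask: np.ndarray) -> dict:
    n_vox = int(mask.sum())
    per = [
        glrlm_features_single(run_length_matrix(img, mask, d), n_vox)
        for d in OFFSETS
    ]
    return {k: float(np.mean([f[k] for f in per])) for k in per[0]}


# ---------------------------------------------------------------- GLSZM

def zones(img: np.ndarray, mask: np.ndarray) -> list[tuple[int, int]]:
    """(level, size) of 26-connected equal-level zones via BFS flood fill."""
    shape = img.shape
    seen = np.zeros(shape, dtype=bool)
    out = []
    for x in range(shape[0]):
        for y in range(shape[1]):
            for z in range(shape[2]):
                if not mask[x, y, z] or seen[x, y, z]:
                    continue
                lev = int(img[x, y, z])
                stack = [(x, y, z)]
                seen[x, y, z] = True
                size = 0
                while stack:
                    cx, cy, cz = stack.pop()
                    size += 1
                    for dx, dy, dz in NEIGHBORS_26:
                        nb = (cx + dx, cy + dy, cz + dz)
                        if (_in_bounds(nb, shape) and mask[nb]
                                and not seen[nb] and int(img[nb]) == lev):
                            seen[nb] = True
                            stack.append(nb)
                out.append((lev, size))
    return out


def glszm_features(img: np.ndarray, mask: np.ndarray) -> dict:
    zs = zones(img, mask)
    nz = float(len(zs))
    n_vox = int(mask.sum())
    counts: dict = defaultdict(int)
    for lev, size in zs:
        counts[(lev, size)] += 1
    gl = defaultdict(float)
    sz = defaultdict(float)
    for (i, s), c in counts.items():
        gl[i] += c
        sz[s] += c
    mu_i = sum(i * c for (i, s), c in counts.items()) / nz
    mu_s = sum(s * c for (i, s), c in counts.items()) / nz
    return {
        "SAE": sum(c / s ** 2 for (i, s), c in counts.items()) / nz,
        "LAE": sum(c * s ** 2 for (i, s), c in counts.items()) / nz,
        "GLN": sum(v ** 2 for v in gl.values()) / nz,
        "GLNN": sum(v ** 2 for v in gl.values()) / nz ** 2,
        "SZNU": sum(v ** 2 for v in sz.values()) / nz,
        "SZNN": sum(v ** 2 for v in sz.values()) / nz ** 2,
        "ZonePercentage": nz / n_vox,
        "GrayLevelVariance": sum(
            (i - mu_i) ** 2 * c for (i, s), c in counts.items()
        ) / nz,
        "ZoneVariance": sum(
            (s - mu_s) ** 2 * c for (i, s), c in counts.items()
        ) / nz,
        "ZoneEntropy": -sum(
            (c / nz) * _log2(c / nz) for c in counts.values()
        ),
        "LGLZE": sum(c / i ** 2 for (i, s), c in counts.items()) / nz,
        "HGLZE": sum(c * i ** 2 for (i, s), c in counts.items()) / nz,
        "SALGLE": sum(c / (i ** 2 * s ** 2) for (i, s), c in counts.items()) / nz,
        "SAHGLE": sum(c * i ** 2 / s ** 2 for (i, s), c in counts.items()) / nz,
        "LALGLE": sum(c * s ** 2 / i ** 2 for (i, s), c in counts.items()) / nz,
        "LAHGLE": sum(c * i ** 2 * s ** 2 for (i, s), c in counts.items()) / nz,
    }
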