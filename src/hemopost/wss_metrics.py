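"""Point-wise and sac-aggregated wall-shear-stress variants.

Per sac vertex, from the time-resolved WSS vector τ(t):

* TWSS  = (1/T) ∫ |τ| dt                      (Pa)    — time-averaged WSS
* OSI   = ½ (1 − |∫ τ dt| / ∫ |τ| dt)         (–)     — oscillatory shear index
* ECAP  = OSI / TWSS                          (1/Pa)  — endothelial activation potential
* RRT   = 1 / ((1 − 2·OSI) · TWSS)            (1/Pa)  — relative residence time

and the sac-level aggregates of these (spatial averages weighted by the
barycentric vertex areas, extrema, low-shear area, and the systolic WSS
statistics).  Vertices whose shear magnitude integrates to ~0 over the
cycle are flagged degenerate: OSI is reported as 0 there and the vertex is
excluded from spatial aggregates, since OSI/ECAP are undefined at zero
shear and silent zeros would bias the averages.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .field_io import SurfaceMesh, TimeResolvedField
from .quadrature import cycle_integral

__all__ = [
    "WSSPointMetrics",
    "SacSummary",
    "compute_twss",
    "compute_osi",
    "compute_ecap",
    "compute_rrt",
    "compute_point_metrics",
    "aggregate_sac",
    "TemporalStatisticError",
]

DEFAULT_EPS_TWSS = 1e-12      # Pa; below this, ECAP/RRT are undefined
DEFAULT_DELTA_OSI = 1e-12     # OSI within delta of 0.5 makes RRT infinite
DEFAULT_LSA_THRESHOLD = 0.4   # Pa; low-shear-area threshold


class TemporalStatisticError(ValueError):
    """Raised when a temporal statistic is requested with <2 phases."""


@dataclass
class WSSPointMetrics:
    """Per-vertex WSS metric fields plus degeneracy flags."""

    twss: np.ndarray                 # (n_v,) Pa
    osi: np.ndarray                  # (n_v,) dimensionless, [0, 0.5]
    ecap: np.ndarray                 # (n_v,) 1/Pa, NaN where undefined
    rrt: np.ndarray                  # (n_v,) 1/Pa, +inf where flagged-infinite
    degenerate: np.ndarray           # (n_v,) bool: zero shear over the cycle
    rrt_infinite: np.ndarray         # (n_v,) bool


@dataclass
class SacSummary:
    """Named scalar aggregates over the aneurysm sac (one row per case)."""

    values: dict[str, float] = field(default_factory=dict)
    n_degenerate: int = 0

    def __getitem__(self, key: str) -> float:
        return self.values[key]

    def keys(self):
        return self.values.keys()


def _require_phases(wss: TimeResolvedField) -> None:
    if wss.n_phases < 2:
        raise TemporalStatisticError(
            "temporal WSS statistics require at least 2 phases"
        )


def compute_twss(wss: TimeResolvedField) -> np.ndarray:
    """Time-averaged WSS magnitude per vertex (Pa)."""
    _require_phases(wss)
    return cycle_integral(wss.magnitudes(), wss.phase_times, wss.period) / wss.period


def compute_osi(
    wss: TimeResolvedField, eps: float = DEFAULT_EPS_TWSS
) -> tuple[np.ndarray, np.ndarray]:
    """Oscillatory shear index per vertex, clamped into [0, 0.5].

    Returns ``(osi, degenerate)``; degenerate vertices (cycle-integrated
    shear magnitude below ``eps * T``) get OSI 0 and should be excluded
    from spatial aggregates.
    """
    _require_phases(wss)
    vec_int = cycle_integral(wss.values, wss.phase_times, wss.period)
    mag_int = cycle_integral(wss.magnitudes(), wss.phase_times, wss.period)
    degenerate = mag_int <= eps * wss.period
    safe = np.where(degenerate, 1.0, mag_int)
    osi = 0.5 * (1.0 - np.linalg.norm(vec_int, axis=1) / safe)
    osi = np.clip(osi, 0.0, 0.5)
    osi[degenerate] = 0.0
    return osi, degenerate


def compute_ecap(
    osi: np.ndarray, twss: np.ndarray, eps: float = DEFAULT_EPS_TWSS
) -> np.ndarray:
    """ECAP = OSI / TWSS (1/Pa); NaN where TWSS <= eps (undefined)."""
    twss = np.asarray(twss, dtype=float)
    out = np.full_like(twss, np.nan)
    ok = twss > eps
    out[ok] = np.asarray(osi, dtype=float)[ok] / twss[ok]
    return out


def compute_rrt(
    osi: np.ndarray,
    twss: np.ndarray,
    eps: float = DEFAULT_EPS_TWSS,
    delta: float = DEFAULT_DELTA_OSI,
) -> tuple[np.ndarray, np.ndarray]:
    """RRT = 1 / ((1 − 2·OSI)·TWSS); returns ``(rrt, infinite_mask)``.

    Where OSI ≥ 0.5 − delta (purely oscillatory shear) or TWSS ≤ eps the
    value is +inf and the mask is set; such vertices are excluded from
    spatial means by default.
    """
    osi = np.asarray(osi, dtype=float)
    twss = np.asarray(twss, dtype=float)
    denom = (1.0 - 2.0 * osi) * twss
    infinite = (osi >= 0.5 - delta) | (twss <= eps) | (denom <= 0)
    rrt = np.full_like(twss, np.inf)
    rrt[~infinite] = 1.0 / denom[~infinite]
    return rrt, infinite


def compute_point_metrics(
    wss: TimeResolvedField, eps: float = DEFAULT_EPS_TWSS
) -> WSSPointMetrics:
    twss = compute_twss(wss)
    osi, degenerate = compute_osi(wss, eps)
    ecap = compute_ecap(osi, twss, eps)
    rrt, rrt_inf = compute_rrt(osi, twss, eps)
    return WSSPointMetrics(
        twss=twss, osi=osi, ecap=ecap, rrt=rrt,
        degenerate=degenerate, rrt_infinite=rrt_inf,
    )


def _weighted_mean(values: np.ndarray, weights: np.ndarray,
                   valid: np.ndarray) -> float:
    w = weights[valid]
    if w.sum() == 0:
        return float("nan")
    return float(np.sum(values[valid] * w) / w.sum())


def aggregate_sac(
    metrics: WSSPointMetrics,
    mesh: SurfaceMesh,
    wss: TimeResolvedField,
    peak_systole_phase: int,
    lsa_threshold: float = DEFAULT_LSA_THRESHOLD,
    systole_window: tuple[int, int] | None = None,
    systole_mode: str = "peak",
) -> SacSummary:
    """Sac-level scalar aggregates (one feature row fragment per case).

    ``STAWSS`` is the area-weighted sac average of TWSS; ``Mean_TAWSS`` is
    the same average taken over the whole surface (sac plus parent-vessel
    vertices) — the two coincide when the sac mask covers the mesh.  The
    systolic statistics use |τ| at ``peak_systole_phase``; with
    ``systole_mode="window"`` the spatial average is taken of the
    time-average of |τ| over ``systole_window`` instead.
    """
    if not np.any(mesh.sac_mask):
        raise ValueError("sac_mask is empty: no sac vertices to aggregate over")
    areas = mesh.vertex_areas
    sac = mesh.sac_mask
    valid = sac & ~metrics.degenerate

    mags = wss.magnitudes()
    if systole_mode == "peak":
        sys_mag = mags[peak_systole_phase]
    elif systole_mode == "window":
        if systole_window is None:
            raise ValueError("systole_mode='window' requires systole_window")
        lo, hi = systole_window
        sys_mag = mags[lo:hi + 1].mean(axis=0)
    else:
        raise ValueError(f"unknown systole_mode {systole_mode!r}")

    rrt_ok = valid & ~metrics.rrt_infinite
    ecap_ok = valid & np.isfinite(metrics.ecap)

    lsa = float(areas[sac & (metrics.twss < lsa_threshold)].sum())
    values = {
        "SA_OSI": _weighted_mean(metrics.osi, areas, valid),
        "SA_ECAP": _weighted_mean(metrics.ecap, areas, ecap_ok),
        "Max_ECAP": float(np.max(metrics.ecap[ecap_ok])) if ecap_ok.any() else float("nan"),
        "Min_ECAP": float(np.min(metrics.ecap[ecap_ok])) if ecap_ok.any() else float("nan"),
        "SA_RRT": _weighted_mean(metrics.rrt, areas, rrt_ok),
        "Max_RRT": float(np.max(metrics.rrt[rrt_ok])) if rrt_ok.any() else float("inf"),
        "STAWSS": _weighted_mean(metrics.twss, areas, sac),
        "Mean_TAWSS": _weighted_mean(metrics.twss, areas,
                                     np.ones(mesh.n_vertices, dtype=bool)),
        "Systole_STAWSS": _weighted_mean(sys_mag, areas, sac),
        "STAWSS_min": float(np.min(sys_mag[sac])),
        "STAWSS_max": float(np.max(sys_mag[sac])),
        "TA_LSA": lsa,
        "TA_LSA_fraction": lsa / mesh.sac_area if mesh.sac_area > 0 else float("nan"),
    }
    return SacSummary(values=values, n_degenerate=int((sac & metrics.degenerate).sum()))
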