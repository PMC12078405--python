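"""Synthetic meshes, analytic flow/WSS fields, and cohorts with known truth.

Every generator attaches a machine-readable ``expected`` record holding the
closed-form values the pipeline should reproduce (TWSS, OSI, divergence,
λ2 sign structure, planted cohort effects), so tests assert against the
generator's own bookkeeping rather than constants re-derived in test code.

Study conditions emulated by default: cardiac period 1.0 s sampled at 20
uniform phases; a matched cohort of 13 thrombosed / 13 control aneurysms
whose baseline feature distributions follow the control-group summary
statistics of the conventional-parameter comparison, with planted
standardized effects in Max_ECAP (+), STAWSS_min (−) and Mean_NWSS_Div (+)
— the three conventional parameters that separate the groups.  Matched
pairs share a pair-level random effect (within-pair correlation 0.5),
reflecting matching by aneurysm size and location.  Blood-property
constants (viscosity 0.004 Pa·s, density 1040 kg/m³) are recorded in the
metadata for fidelity although no flow solver is run here.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
import trimesh

from .field_io import Case, SurfaceMesh, TimeResolvedField, VolumeMesh
from .cohort_stats import CohortTable

__all__ = [
    "WaveformSpec",
    "CohortSpec",
    "make_sac_mesh",
    "make_box_mesh",
    "make_wss_field",
    "make_velocity_field",
    "make_case",
    "make_cohort",
    "BASELINE_FEATURES",
]

BLOOD_PROPERTIES = {"viscosity_Pa_s": 0.004, "density_kg_m3": 1040.0}

# Baseline (control-group) feature distributions: mean, SD. These are the
# conventional hemodynamic parameters of a non-thrombosed ICA-aneurysm
# cohort and define the fast-mode null distributions.
BASELINE_FEATURES: dict[str, tuple[float, float]] = {
    "SA_OSI": (0.02, 0.01),
    "Max_ECAP": (2.64, 2.16),
    "SA_ECAP": (0.06, 0.07),
    "Max_RRT": (144.85, 197.86),
    "SA_RRT": (1.28, 1.02),
    "Mean_TAWSS": (3.34, 2.08),
    "TA_LSA": (55.18, 25.68),
    "STAWSS": (4.09, 2.69),
    "STAWSS_min": (0.15, 0.23),
    "STAWSS_max": (100.68, 101.55),
    "TADVO": (0.54, 0.17),
    "Vortex_V": (849.64, 506.01),
    "Num_core": (5.63, 3.65),
    "Mean_NWSS_Div": (0.006, 0.021),
    "Mean_TSVI": (0.126, 0.026),
}

DEFAULT_EFFECTS: dict[str, float] = {
    "Max_ECAP": +1.5,
    "STAWSS_min": -1.5,
    "Mean_NWSS_Div": +1.5,
}


@dataclass
class WaveformSpec:
    """Temporal modulation s(t) applied to a spatial base pattern."""

    type: str = "pulsatile"     # steady | sinusoid | reversing | pulsatile
    amplitude: float = 1.0      # Pa (WSS) or mm/s (velocity)
    period: float = 1.0         # s
    n_phases: int = 20
    reversal_fraction: float = 0.5  # reversing type: fraction of T spent at +1

    def __post_init__(self) -> None:
        if self.amplitude <= 0:
            raise ValueError("amplitude must be positive")
        if self.n_phases < 2:
            raise ValueError("need at least 2 phases")
        if not (0.0 < self.reversal_fraction < 1.0):
            raise ValueError("reversal_fraction must be in (0, 1)")

    @property
    def phase_times(self) -> np.ndarray:
        return np.arange(self.n_phases) * self.period / self.n_phases

    def scalar(self) -> np.ndarray:
        """s(t) at the phase times; |s| <= 1 with max |s| = 1 except steady."""
        t = self.phase_times / self.period
        if self.type == "steady":
            return np.ones(self.n_phases)
        if self.type == "sinusoid":
            return np.sin(2 * np.pi * t)
        if self.type == "reversing":
            return np.where(t < self.reversal_fraction, 1.0, -1.0)
        if self.type == "pulsatile":
            # always-positive pulse peaking at t = T/4 (systole)
            return (1.0 + 0.9 * np.sin(2 * np.pi * t)) / 1.9
        raise ValueError(f"unknown waveform type {self.type!r}")

    def peak_phase(self) -> int:
        return int(np.argmax(np.abs(self.scalar())))

    def mean_abs(self) -> float:
        """Cycle mean of |s(t)| under the 20-phase periodic quadrature."""
        return float(np.mean(np.abs(self.scalar())))

    def osi_expected(self) -> float:
        """Closed-form OSI for a fixed-direction pattern scaled by s(t)."""
        s = self.scalar()
        num = abs(float(np.mean(s)))
        den = float(np.mean(np.abs(s)))
        return 0.5 * (1.0 - num / den) if den > 0 else 0.0


# ----------------------------------------------------------------------------
# Surface fixtures

def make_sac_mesh(
    kind: str = "icosphere",
    size: float = 5.0,
    refinement: int = 2,
) -> SurfaceMesh:
    """Triangulated surface fixtures.

    ``icosphere``: watertight sphere of radius ``size`` mm (10·4^n + 2
    vertices at subdivision n); ``open-dome``: the z > 0 half of an
    icosphere, with an open boundary loop; ``annulus-patch``: planar ring
    in the xy-plane with radii [size, 2·size], the fixture for the radial
    1/r divergence oracle.
    """
    if refinement < 0:
        raise ValueError("refinement must be >= 0")
    if kind == "icosphere":
        m = trimesh.creation.icosphere(subdivisions=refinement, radius=size)
        return SurfaceMesh(vertices=np.asarray(m.vertices),
                           triangles=np.asarray(m.faces))
    if kind == "open-dome":
        m = trimesh.creation.icosphere(subdivisions=refinement, radius=size)
        verts = np.asarray(m.vertices)
        faces = np.asarray(m.faces)
        keep = np.all(verts[faces][:, :, 2] > -1e-9, axis=1)
        faces = faces[keep]
        used = np.unique(faces)
        remap = -np.ones(len(verts), dtype=np.int64)
        remap[used] = np.arange(len(used))
        return SurfaceMesh(vertices=verts[used], triangles=remap[faces])
    if kind == "annulus-patch":
        n_r = 4 * 2 ** refinement
        n_t = 16 * 2 ** refinement
        radii = np.linspace(size, 2 * size, n_r + 1)
        theta = np.arange(n_t) * 2 * np.pi / n_t
        rr, tt = np.meshgrid(radii, theta, indexing="ij")
        # stagger alternate rings: the fully symmetric polar grid makes the
        # P1 divergence superconvergent (exact for the radial field), which
        # would hide discretization error from convergence checks
        tt = tt + (np.arange(n_r + 1)[:, None] % 2) * 0.3 * (2 * np.pi / n_t)
        verts = np.column_stack([
            (rr * np.cos(tt)).ravel(), (rr * np.sin(tt)).ravel(),
            np.zeros(rr.size),
        ])
        tris = []
        for i in range(n_r):
            for j in range(n_t):
                a = i * n_t + j
                b = i * n_t + (j + 1) % n_t
                c = (i + 1) * n_t + j
                d = (i + 1) * n_t + (j + 1) % n_t
                tris.append([a, b, d])
                tris.append([a, d, c])
        return SurfaceMesh(vertices=verts, triangles=np.array(tris))
    raise ValueError(f"unknown mesh kind {kind!r}")


# ----------------------------------------------------------------------------
# Volume fixture: box split into tetrahedra

_KUHN_TETS = (
    (0b000, 0b100, 0b110, 0b111),
    (0b000, 0b110, 0b010, 0b111),
    (0b000, 0b010, 0b011, 0b111),
    (0b000, 0b011, 0b001, 0b111),
    (0b000, 0b001, 0b101, 0b111),
    (0b000, 0b101, 0b100, 0b111),
)


def make_box_mesh(
    n: int = 10,
    extent: float = 10.0,
    center: np.ndarray | None = None,
    sac_region: str = "all",
) -> VolumeMesh:
    """Tetrahedral box mesh: n×n×n cubes, each split into 6 Kuhn tets.

    ``extent`` is the edge length in mm; ``sac_region='sphere'`` masks the
    cells whose centroid lies within the inscribed sphere, leaving a
    parent-vessel-like shell outside.
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    if center is None:
        center = np.zeros(3)
    coords = np.linspace(-extent / 2, extent / 2, n + 1)
    gx, gy, gz = np.meshgrid(coords, coords, coords, indexing="ij")
    nodes = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()]) + center

    def nid(i, j, k):
        return (i * (n + 1) + j) * (n + 1) + k

    cells = []
    for i in range(n):
        for j in range(n):
            for k in range(n):
                corner = {}
                for code in range(8):
                    di, dj, dk = (code >> 2) & 1, (code >> 1) & 1, code & 1
                    corner[code] = nid(i + di, j + dj, k + dk)
                for tet in _KUHN_TETS:
                    cells.append([corner[c] for c in tet])
    cells = np.array(cells, dtype=np.int64)
    mesh = VolumeMesh(nodes=nodes, cells=cells)
    if sac_region == "sphere":
        centroids = nodes[cells].mean(axis=1)
        r = np.linalg.norm(centroids - center, axis=1)
        mesh.sac_mask = r <= extent / 2
    elif sac_region != "all":
        raise ValueError(f"unknown sac_region {sac_region!r}")
    return mesh


# ----------------------------------------------------------------------------
# WSS fields

def make_wss_field(
    mesh: SurfaceMesh,
    waveform: WaveformSpec,
    pattern: str = "uniform",
    low: float = 0.2,
    high: float = 1.0,
) -> tuple[TimeResolvedField, dict]:
    """Time-resolved WSS field with closed-form expected metric values.

    Patterns: ``uniform`` — amplitude·ê_x everywhere; ``radial-source`` —
    unit radial direction (x, y, 0)/r scaled by the amplitude (on the
    annulus patch its normalized divergence is 1/r); ``two-region`` —
    ê_x direction with magnitude ``low·amplitude`` where x < 0 and
    ``high·amplitude`` elsewhere (low-shear-area fixture).
    Returns ``(field, expected)``.
    """
    verts = mesh.vertices
    n_v = mesh.n_vertices
    if pattern == "uniform":
        base = np.tile([1.0, 0.0, 0.0], (n_v, 1)) * waveform.amplitude
        mag = np.full(n_v, waveform.amplitude)
    elif pattern == "radial-source":
        r = np.linalg.norm(verts[:, :2], axis=1)
        r = np.where(r > 0, r, 1.0)
        base = np.column_stack([verts[:, 0] / r, verts[:, 1] / r,
                                np.zeros(n_v)]) * waveform.amplitude
        mag = np.full(n_v, waveform.amplitude)
    elif pattern == "two-region":
        scale = np.where(verts[:, 0] < 0, low, high) * waveform.amplitude
        base = np.column_stack([scale, np.zeros(n_v), np.zeros(n_v)])
        mag = scale
    else:
        raise ValueError(f"unknown pattern {pattern!r}")

    s = waveform.scalar()
    values = s[:, None, None] * base[None]
    fld = TimeResolvedField(values=values, phase_times=waveform.phase_times,
                            period=waveform.period, kind="wss")
    osi = waveform.osi_expected()
    twss = mag * waveform.mean_abs()
    expected = {
        "twss": twss,
        "osi": osi,
        "ecap": np.where(twss > 0, osi / twss, np.nan),
        "peak_phase": waveform.peak_phase(),
        "blood": dict(BLOOD_PROPERTIES),
    }
    if pattern == "radial-source":
        r = np.linalg.norm(verts[:, :2], axis=1)
        expected["nwss_div"] = np.where(r > 0, 1.0 / r, np.nan)
    return fld, expected


# ----------------------------------------------------------------------------
# Velocity fields

def _lamb_oseen(points: np.ndarray, center_xy: np.ndarray, rc: float,
                gamma: float) -> np.ndarray:
    """In-plane swirl of a Lamb-Oseen-like tube aligned with z (mm/s)."""
    dx = points[:, 0] - center_xy[0]
    dy = points[:, 1] - center_xy[1]
    r2 = dx * dx + dy * dy
    r = np.sqrt(r2)
    with np.errstate(divide="ignore", invalid="ignore"):
        u_theta = gamma / (2 * np.pi * r) * (1.0 - np.exp(-r2 / rc ** 2))
    u_theta = np.where(r > 1e-12, u_theta, 0.0)
    out = np.zeros((len(points), 3))
    out[:, 0] = -u_theta * dy / np.maximum(r, 1e-12)
    out[:, 1] = u_theta * dx / np.maximum(r, 1e-12)
    return out


def make_velocity_field(
    mesh: VolumeMesh,
    kind: str = "rigid-rotation",
    waveform: WaveformSpec | None = None,
    omega: float = 10.0,
    speed: float = 100.0,
    tube_radius: float = 1.0,
    tube_separation: float = 5.0,
    circulation: float = 500.0,
    jet_strength: float = 200.0,
    swirl_strength: float = 50.0,
    jet_width: float = 2.0,
) -> tuple[TimeResolvedField, dict]:
    """Analytic velocity fields with known vortex structure.

    Kinds: ``rigid-rotation`` (λ2 = −ω² in every cell), ``uniform``
    (no cores), ``lamb-oseen-tube`` (one core), ``two-tube`` (two disjoint
    cores for separation > 2 radii), ``jet-plus-recirculation`` (a
    Gaussian jet along x plus one swirling tube, the side-wall-aneurysm
    cartoon: inflow jet, outflow, recirculation zone).
    Returns ``(field, expected)``.
    """
    if waveform is None:
        waveform = WaveformSpec(type="steady", amplitude=1.0)
    pts = mesh.nodes
    expected: dict = {"blood": dict(BLOOD_PROPERTIES)}
    if kind == "rigid-rotation":
        base = np.column_stack([-omega * pts[:, 1], omega * pts[:, 0],
                                np.zeros(len(pts))])
        expected["lambda2"] = -omega ** 2
        expected["n_cores"] = 1
    elif kind == "uniform":
        base = np.tile([speed, 0.0, 0.0], (len(pts), 1))
        expected["lambda2"] = 0.0
        expected["n_cores"] = 0
    elif kind == "lamb-oseen-tube":
        base = _lamb_oseen(pts, np.zeros(2), tube_radius, circulation)
        expected["n_cores"] = 1
    elif kind == "two-tube":
        c = tube_separation / 2.0
        base = (_lamb_oseen(pts, np.array([-c, 0.0]), tube_radius, circulation)
                + _lamb_oseen(pts, np.array([c, 0.0]), tube_radius, circulation))
        expected["n_cores"] = 2 if tube_separation > 2 * tube_radius else 1
    elif kind == "jet-plus-recirculation":
        # a stronger inflow jet penetrates deeper into the sac, so the
        # high-velocity zone grows with jet momentum rather than merely
        # rescaling (min-max quantization would hide a pure rescaling)
        penetration = max(jet_width, jet_strength / 50.0)
        jet = jet_strength * np.exp(
            -(pts[:, 1] ** 2 + pts[:, 2] ** 2) / jet_width ** 2
        ) * np.exp(-pts[:, 0] ** 2 / penetration ** 2)
        base = np.column_stack([jet, np.zeros(len(pts)), np.zeros(len(pts))])
        swirl_center = np.array([0.0, 2.0 * jet_width])
        base += _lamb_oseen(pts, swirl_center, tube_radius,
                            swirl_strength * 2 * np.pi * tube_radius)
        expected["n_cores"] = 1
        expected["jet_strength"] = jet_strength
    else:
        raise ValueError(f"unknown velocity kind {kind!r}")

    s = waveform.scalar()
    values = s[:, None, None] * base[None]
    fld = TimeResolvedField(values=values, phase_times=waveform.phase_times,
                            period=waveform.period, kind="velocity")
    expected["peak_phase"] = waveform.peak_phase()
    return fld, expected


# ----------------------------------------------------------------------------
# Whole cases and cohorts

def make_case(
    case_id: str = "synthetic-000",
    group_label: str = "control",
    waveform: WaveformSpec | None = None,
    wss_pattern: str = "two-region",
    velocity_kind: str = "jet-plus-recirculation",
    surface_refinement: int = 2,
    volume_n: int = 8,
    **velocity_params,
) -> tuple[Case, dict]:
    """One complete synthetic aneurysm case (surface + volume + fields)."""
    if waveform is None:
        waveform = WaveformSpec(type="pulsatile", amplitude=2.0)
    surface = make_sac_mesh("icosphere", size=5.0, refinement=surface_refinement)
    volume = make_box_mesh(n=volume_n, extent=10.0, sac_region="sphere")
    wss, wss_expected = make_wss_field(surface, waveform, pattern=wss_pattern)
    vel_waveform = WaveformSpec(
        type=waveform.type, amplitude=1.0, period=waveform.period,
        n_phases=waveform.n_phases,
    )
    velocity, vel_expected = make_velocity_field(
        volume, kind=velocity_kind, waveform=vel_waveform, **velocity_params
    )
    peak = waveform.peak_phase()
    n_ph = waveform.n_phases
    window = (max(0, peak - max(1, n_ph // 8)), min(n_ph - 1, peak + max(1, n_ph // 8)))
    case = Case(
        case_id=case_id, group_label=group_label,
        surface=surface, volume=volume, wss=wss, velocity=velocity,
        peak_systole_phase=peak, systole_window=window,
    )
    case.validate()
    return case, {"wss": wss_expected, "velocity": vel_expected}


@dataclass
class CohortSpec:
    """Matched-cohort generator settings (fast mode)."""

    n_pairs: int = 13
    effects: dict[str, float] = dc_field(
        default_factory=lambda: dict(DEFAULT_EFFECTS)
    )
    pair_correlation: float = 0.5
    seed: int = 0
    baseline: dict[str, tuple[float, float]] = dc_field(
        default_factory=lambda: dict(BASELINE_FEATURES)
    )

    def __post_init__(self) -> None:
        if self.n_pairs < 2:
            raise ValueError("n_pairs must be >= 2")
        if not (0.0 <= self.pair_correlation < 1.0):
            raise ValueError("pair_correlation must be in [0, 1)")
        unknown = set(self.effects) - set(self.baseline)
        if unknown:
            raise ValueError(f"effects on unknown features: {sorted(unknown)}")


def make_cohort(spec: CohortSpec) -> tuple[CohortTable, dict]:
    """Fast-mode matched cohort: feature rows drawn from group distributions.

    Each feature value is μ + σ(√ρ·b_pair + √(1−ρ)·e) with b_pair shared
    within a matched pair (within-pair correlation ρ), plus d·σ added to
    the thrombosed member for planted effects d.  Returns the table and a
    truth record listing the planted shifts.  Byte-reproducible for a
    fixed seed.
    """
    rng = np.random.default_rng(spec.seed)
    rho = spec.pair_correlation
    rows = []
    for pair in range(spec.n_pairs):
        shared = {f: rng.standard_normal() for f in spec.baseline}
        for group in ("thrombosed", "control"):
            row = {
                "case_id": f"{group[:3]}-{pair:03d}",
                "group": group,
                "pair_id": pair,
            }
            for feat, (mu, sd) in spec.baseline.items():
                noise = (np.sqrt(rho) * shared[feat]
                         + np.sqrt(1.0 - rho) * rng.standard_normal())
                value = mu + sd * noise
                if group == "thrombosed":
                    value += spec.effects.get(feat, 0.0) * sd
                row[feat] = value
            rows.append(row)
    table = CohortTable(frame=pd.DataFrame(rows))
    truth = {
        "mode": "fast",
        "n_pairs": spec.n_pairs,
        "pair_correlation": rho,
        "effects_sd_units": dict(spec.effects),
        "shifted_features": sorted(k for k, v in spec.effects.items() if v != 0),
        "seed": spec.seed,
    }
    return table, truth


def make_field_cohort(
    n_pairs: int = 3,
    seed: int = 0,
    jet_effect: float = 1.5,
) -> tuple[list[tuple[Case, dict]], dict]:
    """Field-mode cohort: per-case flow fields with a planted jet-strength
    difference (thrombosed cases get stronger inflow jets).

    Much slower than fast mode — meshes and fields are generated and meant
    to be pushed through the full per-case pipeline; used for end-to-end
    smoke checks rather than statistical claims.
    """
    rng = np.random.default_rng(seed)
    base_jet, jet_sd = 150.0, 30.0
    cases = []
    for pair in range(n_pairs):
        pair_jitter = rng.normal(0.0, jet_sd)
        for group in ("thrombosed", "control"):
            jet = base_jet + pair_jitter + rng.normal(0.0, jet_sd * 0.5)
            if group == "thrombosed":
                jet += jet_effect * jet_sd
            case, expected = make_case(
                case_id=f"field-{group[:3]}-{pair:03d}",
                group_label=group,
                velocity_kind="jet-plus-recirculation",
                jet_strength=float(max(jet, 10.0)),
            )
            cases.append((case, expected))
    truth = {
        "mode": "field",
        "n_pairs": n_pairs,
        "jet_effect_sd_units": jet_effect,
        "seed": seed,
    }
    return cases, truth
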