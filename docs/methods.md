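# Methods

This note documents the models, numerical choices, and the synthetic
study conditions behind `hemopost`, in the order the pipeline runs them.

## Data model and units

Coordinates are in millimetres, WSS in pascals, velocity in mm/s; the
case manifest records the unit strings and the reader validates them.
Fields are node-associated: one 3-vector per surface vertex (WSS) or
volume node (velocity) per cardiac phase, with phase times in [0, T).
When phase times are absent they default to uniform spacing, matching the
common convention of exporting 20 equally spaced phases per cycle.
Per-vertex areas are barycentric-lumped (one third of each incident
triangle), which partitions the total area exactly. Whether a solver
exports WSS per vertex or per face is not standardized; the vertex
convention here is a package choice, and cell-associated input would need
averaging to nodes before use.

On disk a case is a directory of legacy-ASCII VTK files (POLYDATA for the
surface, UNSTRUCTURED_GRID for the tet mesh, one file per phase per
field) plus a JSON manifest. Legacy ASCII keeps the reader/writer
dependency-free and ParaView-compatible; numbers are written at full
double precision so a write/read round trip is lossless.

## Temporal quadrature

All cycle statistics use the periodic trapezoid rule: sample i carries
weight (t_{i+1} − t_{i−1})/2 with wrap-around, so weights sum to T
exactly and, for uniform spacing, every cycle average reduces to the
arithmetic mean over phases. For smooth periodic integrands this rule is
spectrally accurate; the test suite bounds the 20-phase error against a
1000-phase reference at 2%.

## WSS variants

TWSS, OSI, ECAP and RRT follow their standard definitions (README).
Degenerate vertices — cycle-integrated shear magnitude below 1e-12 Pa·s —
get OSI = 0 with a flag and are excluded from spatial aggregates; silent
zeros would bias sac averages of OSI and ECAP. RRT is +inf where
OSI ≥ 0.5 − 1e-12 or TWSS ≤ 1e-12 Pa and such vertices are excluded from
means (the Max_RRT of an all-infinite sac is reported as inf rather than
a capped sentinel). The low-shear area uses the 0.4 Pa threshold by
default and is reported both as absolute area (mm²) and as a fraction of
sac area.

Two averaging conventions are deliberately both emitted: `STAWSS`
(sac-masked average of TWSS) and `Mean_TAWSS` (whole-surface average);
they coincide when the mask covers the mesh. The systolic statistics
(`Systole_STAWSS`, `STAWSS_min`, `STAWSS_max`) use |τ| at the single
peak-systole phase by default; a config switch averages over the systole
window instead, covering the alternative reading of "at peak systole".

## Surface divergence and TSVI

The WSS direction field (τ/|τ|, zero and flagged below 1e-12 Pa) is
differentiated intrinsically: on each triangle the P1 interpolant's
gradient of each Cartesian component is taken within the triangle plane
and the divergence is their sum, constant per triangle; vertex values are
area-weighted averages over incident triangles. For a tangential field
this equals the sum of surface-restricted Cartesian partials, and it is
exact for fields linear over a planar patch. Open-boundary vertices have
incomplete one-rings and are excluded from sac averages, as are vertices
with zero shear at any phase.

TSVI is implemented as the RMS over the cycle of the deviation of the
instantaneous divergence from its cycle mean — i.e. the temporal standard
deviation under the periodic quadrature. (The compact printed form of
this index in the literature sometimes omits the square and the dt; the
RMS reading is the standard one and is what this package computes.)
`Mean_NWSS_Div` averages the instantaneous divergence over all phases and
then over the sac; restricting the temporal average to a window is
possible but not the default, since the elongational-vs-compressive
interpretation concerns the whole cycle.

The annulus benchmark deserves a note: on a perfectly symmetric polar
grid the vertex-averaged P1 divergence of the unit radial field is exact
to machine precision, so the fixture staggers alternate rings by 30% of
the angular step. That breaks the superconvergence and produces honest
first-order error (≈2.8% max at refinement 1, halving per refinement),
which is what the convergence tests measure.

## Vortex cores and persistence

The velocity-gradient tensor is computed per tetrahedron from P1 shape
gradients (exact for linear fields, hence rigid rotation yields λ2 = −ω²
in every cell). λ2 is the middle eigenvalue of S² + Ω²; the Q criterion
is a config alternative, and both depend only on the gradient, so a
uniform translation changes nothing — a property test enforces this.

Segmentation thresholds at λ2 < −f·M with f ∈ (0, 1) and M the strongest
negative magnitude over the whole cycle by default (per-phase
normalization is a config switch; cycle normalization keeps cores
comparable across phases). Components are face-connected, restricted to
sac cells (parent-vessel swirl excluded), and labelled by descending
volume with ties broken by lowest cell index, so labels are
deterministic. Raising f can only shrink the thresholded set, so total
core volume is monotone in f.

DVO between adjacent phases is Jaccard (intersection/union of core
volumes) by default; intersection over the mean volume is available.
When neither phase has cores the flow is trivially persistent and DVO is
defined as 1 (flagged), avoiding NaN propagation into TADVO. TADVO and
its SD, the averaged core volume and core count are taken over the
systole window; the 0.15–0.30 sweep (step 0.05) is run per case and a
stability flag records whether the TADVO range stays below 0.1. The
persistent-vortex fixture used to validate the sweep is a Lamb–Oseen
tube whose strength varies ±5% over the window — a vortex that is present
at every phase, as aneurysmal swirl is around peak systole.

## Velocity informatics

Peak-systole velocity is resampled onto an axis-aligned isotropic grid
(default spacing: max sac extent / 64) by locating voxel centers in the
sac tetrahedra and interpolating barycentrically (exact for linear
fields). Two channels are encoded: magnitude |u|, and the angle in
degrees [0, 180] between u and the sac's dominant-flow axis — the first
principal axis of the in-sac velocity vectors at peak systole, signed so
the mean projection is non-negative. The direction encoding is an
interface-compatible package choice (the axis is configurable: principal,
parent-vessel, or fixed); zero-velocity voxels get angle 0.

Each channel is quantized to 32 equal-width levels between the in-mask
min and max (constant volumes map to level 1; top bin closed). Min–max
binning makes the magnitude channel invariant to rescaling all
velocities, so group differences enter through the *shape* of the
velocity distribution, not its scale. GLCM uses the 13 unique 3D offsets
at distance 1, symmetric matrices, masked neighbor pairs only; GLRLM uses
the same 13 directions with runs truncated at the mask boundary; GLSZM
uses 26-connected equal-level zones. Features follow the
IBSI-consistent definitions, averaged per-feature over offsets/directions
(not matrix-merged), matching the common radiomics convention. The test
suite cross-checks all 56 per-channel features against an independent
naive implementation (loop-built matrices, BFS flood fill) at 1e-6
relative on random fixtures.

The jet-plus-recirculation fixture models a side-wall aneurysm cartoon:
a Gaussian inflow jet whose penetration depth grows with jet momentum,
plus a swirling tube for the recirculation zone. Penetration scaling is
what lets a stronger jet raise high-gray-level run emphasis (HGLRE) under
scale-free quantization: a purely rescaled jet would leave every feature
unchanged.

## Cohort statistics

Per-feature two-sided Wilcoxon tests: paired signed-rank when pair ids
form a perfect matching (the matched-cohort default), unpaired rank-sum
otherwise. Exact distributions are used whenever sample size and ties
permit (combined n ≤ 30 tie-free for rank-sum; scipy's exact signed-rank
path for the paired case), with tie-corrected normal approximation beyond
that. Summaries are mean ± sample SD (n − 1). Features constant across
both groups get p = 1 with a degeneracy flag; non-finite values are
excluded pairwise with counts noted. No multiple-testing correction
drives the significance flag — the comparison is exploratory — but a
Benjamini–Hochberg column is emitted for transparency.

At 13 pairs the exact two-sided signed-rank test has achievable size
0.0478 at the nominal 0.05 level; the null-calibration test accounts for
this discreteness only through its binomial tolerance.

## Synthetic study conditions

The generators' defaults are the study conditions, not tuning knobs:
period 1.0 s, 20 phases, 13 matched pairs, blood properties (0.004 Pa·s,
1040 kg/m³) recorded in metadata although no solver runs. Fast-mode
cohorts draw each feature from a normal distribution whose mean and SD
are the non-thrombosed cohort summary values of the conventional
parameters, with planted standardized shifts of +1.5 SD in Max_ECAP,
−1.5 SD in STAWSS_min and +1.5 SD in Mean_NWSS_Div — the three
conventional parameters that discriminate thrombosed aneurysms, in the
observed directions. Matched pairs share a pair-level random effect
giving within-pair correlation 0.5: cohorts matched on size and location
are correlated by construction, and independent pairs would understate
the power of a paired design. Field-mode cohorts instead plant a
jet-strength difference and push generated fields through the actual
pipeline; they are ~100× slower and used for end-to-end smoke checks,
with fast mode carrying the statistical claims.

What fast mode does *not* emulate: marginal distributions of real
hemodynamic features are right-skewed (several have SD > mean), features
are mutually correlated, and effects arrive through the flow physics
rather than additively. Passing calibration and recovery tests therefore
demonstrates the validity of the testing machinery under the planted
conditions, not cohort-level claims about real aneurysms.

## Problem sizes and determinism

Tests and the acceptance script run on deliberately small fixtures —
icospheres at refinement 1–2 (42–162 vertices), box meshes of 5³–12³
cubes (750–10 368 tets), voxel grids of 12–32 per axis, 200–2000 cohort
replicates — sizes at which every closed-form check is already sharp.
The pipeline itself contains no randomness; all stochastic generators
take explicit seeds, and repeated cohort runs with the same config hash
are byte-identical (verified by test and acceptance script).

## Known limitations

- Surface divergence is first-order at vertices on irregular meshes;
  no higher-order reconstruction is attempted.
- The direction-channel encoding (angle to dominant axis) is one of
  several plausible encodings; results for that channel depend on it.
- DVO's denominator convention (union vs mean) changes TADVO values;
  both are available and the report records which was used.
- RRT at near-purely-oscillatory vertices is unbounded; exports flag
  rather than cap it, and downstream means exclude flagged vertices.
- The voxelizer assumes tetrahedral cells; other volume cell types would
  need pre-conversion.
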