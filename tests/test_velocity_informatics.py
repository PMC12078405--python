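"""Voxelization, quantization, and texture-feature checks.

The three feature families are cross-checked against the naive reference
implementation in tests/oracles/texture_oracle.py (explicit loop/BFS
construction of the matrices, features straight from the definitions).
"""

import numpy as np
import pytest

from hemopost.synthetic import WaveformSpec, make_box_mesh, make_velocity_field
from hemopost.velocity_informatics import (
    GLCM_FEATURE_NAMES,
    GLRLM_FEATURE_NAMES,
    GLSZM_FEATURE_NAMES,
    GrayLevelVolume,
    DegenerateInputError,
    glcm_features,
    glrlm_features,
    glszm_features,
    quantize,
    texture_features,
    vi_pipeline,
    voxelize_sac,
)

from oracles import texture_oracle as oracle


def _gl(img, mask, n_levels=None):
    img = np.asarray(img)
    mask = np.asarray(mask, dtype=bool)
    n = int(img[mask].max()) if n_levels is None else n_levels
    return GrayLevelVolume(voxels=np.where(mask, img, 0), spacing=1.0,
                           mask=mask, channel="magnitude", n_levels=n)


class TestVoxelize:
    def test_uniform_flow_constant_magnitude_zero_angle(self):
        mesh = make_box_mesh(n=6, extent=6.0)
        fld, _ = make_velocity_field(mesh, "uniform", speed=10.0,
                                     waveform=WaveformSpec(type="steady",
                                                           n_phases=2))
        mag, direction, mask, sp = voxelize_sac(fld.values[0], mesh,
                                                grid_divisor=16)
        assert mask.any()
        np.testing.assert_allclose(mag[mask], 10.0, rtol=1e-9)
        np.testing.assert_allclose(direction[mask], 0.0, atol=1e-6)

    def test_antiparallel_halves_are_bimodal_in_angle(self):
        mesh = make_box_mesh(n=6, extent=6.0)
        u = np.where(mesh.nodes[:, [0]] < 0, -10.0, 10.0) * np.array([[1.0, 0, 0]])
        mag, direction, mask, _ = voxelize_sac(
            u, mesh, grid_divisor=16, axis=np.array([1.0, 0, 0]))
        angles = direction[mask]
        # voxels straddling the interface interpolate through zero; the
        # bulk is exactly 0 or 180
        bulk = (angles < 1e-6) | (np.abs(angles - 180.0) < 1e-6)
        assert bulk.mean() > 0.7
        assert (angles < 1e-6).any() and (np.abs(angles - 180.0) < 1e-6).any()

    def test_linear_shear_interpolates_exactly(self):
        """Barycentric interpolation reproduces u = (γ·y, 0, 0) at centers."""
        mesh = make_box_mesh(n=6, extent=6.0)
        gamma = 3.0
        u = np.column_stack([gamma * mesh.nodes[:, 1],
                             np.zeros(mesh.n_nodes), np.zeros(mesh.n_nodes)])
        mag, _, mask, sp = voxelize_sac(u, mesh, grid_divisor=16,
                                        axis=np.array([1.0, 0, 0]))
        idx = np.argwhere(mask)
        lo = mesh.nodes.min(axis=0)
        origin = lo - sp
        y = origin[1] + (idx[:, 1] + 0.5) * sp
        np.testing.assert_allclose(mag[mask], np.abs(gamma * y), atol=1e-6)

    def test_spacing_larger_than_extent_rejected(self):
        mesh = make_box_mesh(n=4, extent=4.0)
        u = np.ones((mesh.n_nodes, 3))
        with pytest.raises(ValueError, match="spacing"):
            voxelize_sac(u, mesh, spacing=100.0)


class TestQuantize:
    def test_constant_volume_maps_to_level_one(self):
        vol = np.full((3, 3, 3), 7.5)
        mask = np.ones((3, 3, 3), dtype=bool)
        gl = quantize(vol, mask, 32)
        assert np.all(gl.voxels[mask] == 1)

    def test_integer_ramp_aligns_with_bins(self):
        vol = np.arange(32, dtype=float).reshape(2, 4, 4)
        mask = np.ones_like(vol, dtype=bool)
        gl = quantize(vol, mask, 32)
        np.testing.assert_array_equal(np.sort(gl.voxels[mask]),
                                      np.arange(1, 33))

    def test_matches_bruteforce_binning(self, rng):
        vol = rng.normal(size=(5, 5, 5))
        mask = rng.random((5, 5, 5)) > 0.3
        mask[0, 0, 0] = True
        n_levels = 8
        gl = quantize(vol, mask, n_levels)
        vmin, vmax = vol[mask].min(), vol[mask].max()
        width = (vmax - vmin) / n_levels
        for v, lev in zip(vol[mask], gl.voxels[mask]):
            expected = min(int((v - vmin) // width) + 1, n_levels)
            assert lev == expected

    def test_outside_mask_is_zero(self, rng):
        vol = rng.normal(size=(4, 4, 4))
        mask = np.zeros((4, 4, 4), dtype=bool)
        mask[:2] = True
        gl = quantize(vol, mask, 4)
        assert np.all(gl.voxels[~mask] == 0)


class TestFeatureCollapses:
    """Degenerate images with hand-computable feature values."""

    def test_constant_image_glcm(self):
        gl = _gl(np.ones((4, 4, 4), dtype=int), np.ones((4, 4, 4), dtype=bool))
        f = glcm_features(gl)
        assert f["JointEnergy"] == pytest.approx(1.0)
        assert f["JointEntropy"] == pytest.approx(0.0, abs=1e-12)
        assert f["Id"] == pytest.approx(1.0)
        assert f["Idm"] == pytest.approx(1.0)
        assert f["DifferenceAverage"] == pytest.approx(0.0, abs=1e-12)
        assert f["DifferenceEntropy"] == pytest.approx(0.0, abs=1e-12)

    def test_alternating_strip_glcm_hand_count(self):
        """1D strip 1,2,1,2,…: P = {(1,2): ½, (2,1): ½} for the axial offset."""
        img = np.zeros((8, 1, 1), dtype=int)
        img[::2] = 1
        img[1::2] = 2
        mask = np.ones_like(img, dtype=bool)
        from hemopost.velocity_informatics import _glcm_matrix, _glcm_single
        gl = _gl(img, mask)
        p = _glcm_matrix(gl, (1, 0, 0))
        np.testing.assert_allclose(p, [[0.0, 0.5], [0.5, 0.0]])
        f = _glcm_single(p)
        assert f["DifferenceAverage"] == pytest.approx(1.0)
        assert f["JointEnergy"] == pytest.approx(0.5)

    def test_constant_rows_glrlm_hand_count(self):
        """Constant 4×4×1 image: 4 axial runs of length 4, RP = 4/16."""
        img = np.ones((4, 4, 1), dtype=int)
        mask = np.ones_like(img, dtype=bool)
        gl = _gl(img, mask)
        from hemopost.velocity_informatics import _run_lengths, _glrlm_single
        levels, lengths = _run_lengths(gl, (1, 0, 0))
        assert len(lengths) == 4 and np.all(lengths == 4)
        f = _glrlm_single(levels, lengths, 16)
        assert f["RunPercentage"] == pytest.approx(4 / 16)
        assert f["LRE"] == pytest.approx(16.0)

    def test_no_equal_neighbors_all_runs_length_one(self):
        img = np.arange(1, 9).reshape(8, 1, 1)
        gl = _gl(img, np.ones_like(img, dtype=bool))
        from hemopost.velocity_informatics import _run_lengths, _glrlm_single
        levels, lengths = _run_lengths(gl, (1, 0, 0))
        assert np.all(lengths == 1)
        f = _glrlm_single(levels, lengths, 8)
        assert f["SRE"] == pytest.approx(1.0)
        assert f["LRE"] == pytest.approx(1.0)

    def test_constant_image_glszm_single_zone(self):
        shape = (3, 4, 5)
        v = int(np.prod(shape))
        gl = _gl(np.ones(shape, dtype=int), np.ones(shape, dtype=bool))
        f = glszm_features(gl)
        assert f["ZonePercentage"] == pytest.approx(1.0 / v)
        assert f["LAE"] == pytest.approx(v ** 2)
        assert f["ZoneEntropy"] == pytest.approx(0.0, abs=1e-12)

    def test_checkerboard_zones_match_flood_fill(self):
        x, y, z = np.indices((4, 4, 2))
        img = 1 + (x + y + z) % 2
        mask = np.ones_like(img, dtype=bool)
        gl = _gl(img, mask)
        mine = glszm_features(gl)
        ref = oracle.glszm_features(np.where(mask, img, 0), mask)
        for k in ref:
            assert mine[k] == pytest.approx(ref[k], rel=1e-12)

    def test_single_voxel_mask_glcm_degenerate(self):
        mask = np.zeros((3, 3, 3), dtype=bool)
        mask[1, 1, 1] = True
        gl = _gl(np.ones((3, 3, 3), dtype=int), mask)
        with pytest.raises(DegenerateInputError):
            glcm_features(gl)


class TestOracleAgreement:
    @pytest.mark.parametrize("seed", range(10))
    def test_all_56_features_match_reference(self, seed):
        """Vectorized features vs the naive reference on random 6×6×6 volumes."""
        rng = np.random.default_rng(seed)
        img = rng.integers(1, 6, size=(6, 6, 6))
        mask = rng.random((6, 6, 6)) > 0.2
        mask[0, 0, 0] = True
        arr = np.where(mask, img, 0)
        gl = _gl(arr, mask, n_levels=5)
        checks = [
            (glcm_features(gl), oracle.glcm_features(arr, mask),
             GLCM_FEATURE_NAMES),
            (glrlm_features(gl), oracle.glrlm_features(arr, mask),
             GLRLM_FEATURE_NAMES),
            (glszm_features(gl), oracle.glszm_features(arr, mask),
             GLSZM_FEATURE_NAMES),
        ]
        for mine, ref, names in checks:
            assert set(mine) == set(names)
            for k in names:
                assert mine[k] == pytest.approx(ref[k], rel=1e-6, abs=1e-12), k

    def test_feature_name_sets_are_complete(self):
        assert len(GLCM_FEATURE_NAMES) == 24
        assert len(GLRLM_FEATURE_NAMES) == 16
        assert len(GLSZM_FEATURE_NAMES) == 16
        # the names reported for the cohort comparison are all present
        for name in ("Autocorrelation", "ClusterTendency", "DifferenceAverage",
                     "DifferenceEntropy", "Id", "Idm", "Imc1", "JointAverage",
                     "JointEnergy", "JointEntropy", "SumAverage", "SumEntropy",
                     "SumSquares", "InverseVariance"):
            assert name in GLCM_FEATURE_NAMES
        for name in ("GLNN", "HGLRE", "LRE", "LRHGLE", "LRLGLE", "LGLRE",
                     "RLN", "RLNN", "RunPercentage", "RunVariance", "SRE",
                     "SRHGLE", "SRLGLE"):
            assert name in GLRLM_FEATURE_NAMES
        for name in ("LAE", "LALGLE", "SZNU", "ZonePercentage",
                     "ZoneVariance", "GLNN", "ZoneEntropy"):
            assert name in GLSZM_FEATURE_NAMES


class TestInvariances:
    def test_mask_respected_under_grid_enlargement(self, rng):
        img = rng.integers(1, 5, size=(5, 5, 5))
        mask = rng.random((5, 5, 5)) > 0.3
        mask[2, 2, 2] = True
        big_img = np.zeros((9, 9, 9), dtype=img.dtype)
        big_mask = np.zeros((9, 9, 9), dtype=bool)
        big_img[2:7, 2:7, 2:7] = img
        big_mask[2:7, 2:7, 2:7] = mask
        a = texture_features(_gl(np.where(mask, img, 0), mask, 4))
        b = texture_features(_gl(np.where(big_mask, big_img, 0), big_mask, 4))
        for k in a:
            assert a[k] == pytest.approx(b[k], rel=1e-12), k

    def test_level_permutation_preserves_count_based_features(self, rng):
        img = rng.integers(1, 5, size=(6, 6, 6))
        mask = np.ones((6, 6, 6), dtype=bool)
        perm = {1: 3, 2: 1, 3: 4, 4: 2}
        img2 = np.vectorize(perm.get)(img)
        f1 = glrlm_features(_gl(img, mask, 4))
        f2 = glrlm_features(_gl(img2, mask, 4))
        # run-structure features ignore which level a run has
        for k in ("RLN", "RLNN", "RunPercentage", "SRE", "LRE", "GLN", "GLNN"):
            assert f1[k] == pytest.approx(f2[k], rel=1e-12)
        # intensity-weighted features change
        assert f1["HGLRE"] != pytest.approx(f2["HGLRE"], rel=1e-6)

    def test_velocity_rescaling_leaves_features_unchanged(self):
        """Min–max quantization makes the magnitude channel scale-free."""
        mesh = make_box_mesh(n=6, extent=6.0)
        fld, _ = make_velocity_field(
            mesh, "jet-plus-recirculation", jet_strength=150.0,
            waveform=WaveformSpec(type="steady", n_phases=2))
        f1 = vi_pipeline(fld.values[0], mesh, n_levels=8, grid_divisor=12)
        f2 = vi_pipeline(2.0 * fld.values[0], mesh, n_levels=8, grid_divisor=12)
        for k in f1:
            assert f1[k] == pytest.approx(f2[k], rel=1e-9), k

    def test_pipeline_deterministic(self):
        mesh = make_box_mesh(n=6, extent=6.0)
        fld, _ = make_velocity_field(
            mesh, "jet-plus-recirculation",
            waveform=WaveformSpec(type="steady", n_phases=2))
        a = vi_pipeline(fld.values[0], mesh, n_levels=8, grid_divisor=12)
        b = vi_pipeline(fld.values[0].copy(), mesh, n_levels=8, grid_divisor=12)
        assert a == b
        assert len(a) == 112

    def test_stronger_jet_raises_high_gray_level_run_emphasis(self):
        """A stronger inflow jet shifts more voxels into high-velocity levels."""
        mesh = make_box_mesh(n=8, extent=8.0)
        feats = {}
        for jet in (80.0, 400.0):
            fld, _ = make_velocity_field(
                mesh, "jet-plus-recirculation", jet_strength=jet,
                swirl_strength=50.0,
                waveform=WaveformSpec(type="steady", n_phases=2))
            feats[jet] = vi_pipeline(fld.values[0], mesh, n_levels=16,
                                     grid_divisor=16)
        assert feats[400.0]["Magnitude_GLRLM.HGLRE"] > \
            feats[80.0]["Magnitude_GLRLM.HGLRE"]
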