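"""λ2/Q vortex criteria, core segmentation, DVO, and persistence summaries."""

import numpy as np
import pytest

from hemopost.field_io import StructuralError, TimeResolvedField
from hemopost.synthetic import WaveformSpec, make_box_mesh, make_velocity_field
from hemopost.vortex import (
    analyze_vortices,
    compute_dvo,
    compute_lambda2,
    compute_q_criterion,
    segment_cores,
    summarize_vortex,
)
from hemopost.wss_metrics import TemporalStatisticError


@pytest.fixture(scope="module")
def box():
    return make_box_mesh(n=8, extent=8.0)


def _steady(n_phases=3):
    return WaveformSpec(type="steady", amplitude=1.0, n_phases=n_phases)


class TestLambda2:
    def test_rigid_rotation_closed_form(self, box):
        """u = ω×r: S = 0, Ω² eigenvalues (−ω², −ω², 0) → λ2 = −ω²."""
        fld, expected = make_velocity_field(box, "rigid-rotation", omega=10.0,
                                            waveform=_steady())
        l2 = compute_lambda2(fld.values[0], box)
        np.testing.assert_allclose(l2, expected["lambda2"], rtol=1e-9)
        assert expected["lambda2"] == -100.0

    def test_uniform_translation_gives_zero(self, box):
        fld, _ = make_velocity_field(box, "uniform", waveform=_steady())
        l2 = compute_lambda2(fld.values[0], box)
        np.testing.assert_allclose(l2, 0.0, atol=1e-10)

    def test_pure_planar_strain_has_no_vortex_cells(self, box):
        """u = (αx, −αy, 0): Ω = 0, S² eigenvalues (α², α², 0) → λ2 ≥ 0."""
        alpha = 3.0
        u = np.column_stack([alpha * box.nodes[:, 0], -alpha * box.nodes[:, 1],
                             np.zeros(box.n_nodes)])
        l2 = compute_lambda2(u, box)
        assert np.all(l2 >= -1e-9)
        cores = segment_cores(l2, box, 0.2)
        assert cores.n_cores == 0

    def test_galilean_invariance(self, box, rng):
        """Adding uniform translation leaves λ2, Q, cores, DVO unchanged."""
        u = rng.normal(size=(box.n_nodes, 3)) * 10
        shift = np.array([123.0, -45.0, 6.0])
        np.testing.assert_allclose(compute_lambda2(u, box),
                                   compute_lambda2(u + shift, box), atol=1e-10)
        np.testing.assert_allclose(compute_q_criterion(u, box),
                                   compute_q_criterion(u + shift, box),
                                   atol=1e-10)
        a = segment_cores(compute_lambda2(u, box), box, 0.2)
        b = segment_cores(compute_lambda2(u + shift, box), box, 0.2)
        np.testing.assert_array_equal(a.labels, b.labels)
        assert compute_dvo(a, b, box.cell_volumes) == 1.0


class TestSegmentation:
    def test_rigid_rotation_single_core_spans_sac(self, box):
        fld, _ = make_velocity_field(box, "rigid-rotation", omega=5.0,
                                     waveform=_steady())
        l2 = compute_lambda2(fld.values[0], box)
        cores = segment_cores(l2, box, 0.9)  # uniform λ2: any fraction < 1
        assert cores.n_cores == 1
        assert cores.core_cells.sum() == box.n_cells
        assert cores.total_volume == pytest.approx(box.cell_volumes.sum())

    def test_two_tubes_give_two_cores_with_volume_bookkeeping(self):
        mesh = make_box_mesh(n=12, extent=12.0)
        fld, expected = make_velocity_field(
            mesh, "two-tube", tube_radius=1.0, tube_separation=6.0,
            waveform=_steady(),
        )
        l2 = compute_lambda2(fld.values[0], mesh)
        cores = segment_cores(l2, mesh, 0.2)
        assert cores.n_cores == expected["n_cores"] == 2
        # labels partition the core cells; volumes agree with cell sums
        for lab in range(cores.n_cores):
            members = cores.labels == lab
            assert cores.core_volumes[lab] == pytest.approx(
                mesh.cell_volumes[members].sum()
            )
        assert np.all(np.diff(cores.core_volumes) <= 1e-12)

    def test_no_negative_lambda2_yields_empty_set(self, box):
        fld, _ = make_velocity_field(box, "uniform", waveform=_steady())
        l2 = compute_lambda2(fld.values[0], box)
        cores = segment_cores(l2, box, 0.2)
        assert cores.n_cores == 0
        assert not cores.core_cells.any()

    def test_threshold_monotonicity(self):
        mesh = make_box_mesh(n=10, extent=10.0)
        fld, _ = make_velocity_field(mesh, "lamb-oseen-tube", tube_radius=2.0,
                                     waveform=_steady())
        l2 = compute_lambda2(fld.values[0], mesh)
        vols = [segment_cores(l2, mesh, f).total_volume
                for f in (0.1, 0.2, 0.3, 0.5, 0.8)]
        assert all(a >= b for a, b in zip(vols, vols[1:]))

    def test_deterministic_labels_across_runs(self, box, rng):
        u = rng.normal(size=(box.n_nodes, 3)) * 20
        l2 = compute_lambda2(u, box)
        a = segment_cores(l2, box, 0.15)
        b = segment_cores(l2.copy(), box, 0.15)
        np.testing.assert_array_equal(a.labels, b.labels)
        np.testing.assert_array_equal(a.core_volumes, b.core_volumes)

    def test_sac_restriction_excludes_parent_vessel_swirl(self):
        mesh = make_box_mesh(n=8, extent=8.0, sac_region="sphere")
        fld, _ = make_velocity_field(mesh, "rigid-rotation", omega=5.0,
                                     waveform=_steady())
        l2 = compute_lambda2(fld.values[0], mesh)
        cores = segment_cores(l2, mesh, 0.5)
        assert cores.core_cells.sum() == mesh.sac_mask.sum()
        assert cores.total_volume == pytest.approx(mesh.sac_volume)


class TestDVO:
    def _cores(self, mesh, cells):
        labels = np.full(mesh.n_cells, -1)
        labels[cells] = 0
        mask = np.zeros(mesh.n_cells, dtype=bool)
        mask[cells] = True
        from hemopost.vortex import VortexCoreSet
        return VortexCoreSet(
            phase=0, core_cells=mask, labels=labels,
            core_volumes=np.array([mesh.cell_volumes[cells].sum()]),
            n_cores=1, criterion_field=np.zeros(mesh.n_cells),
            mesh_id=id(mesh),
        )

    def test_identical_disjoint_and_half_overlap(self, box):
        vols = box.cell_volumes
        a_cells = np.arange(0, 40)
        b_cells = np.arange(40, 80)
        half = np.arange(0, 20)
        a = self._cores(box, a_cells)
        assert compute_dvo(a, a, vols) == 1.0
        assert compute_dvo(a, self._cores(box, b_cells), vols) == 0.0
        # Kuhn tets are equal-volume, so half the cells is half the volume
        dvo = compute_dvo(a, self._cores(box, half), vols)
        assert dvo == pytest.approx(0.5, rel=1e-12)

    def test_symmetry(self, box, rng):
        a = self._cores(box, rng.choice(box.n_cells, 50, replace=False))
        b = self._cores(box, rng.choice(box.n_cells, 70, replace=False))
        assert compute_dvo(a, b, box.cell_volumes) == \
            compute_dvo(b, a, box.cell_volumes)

    def test_mean_denominator_mode(self, box):
        a = self._cores(box, np.arange(0, 40))
        b = self._cores(box, np.arange(20, 60))
        vols = box.cell_volumes
        jac = compute_dvo(a, b, vols, mode="jaccard")
        mean = compute_dvo(a, b, vols, mode="mean")
        assert jac == pytest.approx(1.0 / 3.0, rel=1e-12)
        assert mean == pytest.approx(0.5, rel=1e-12)

    def test_mesh_mismatch_rejected(self, box):
        other = make_box_mesh(n=8, extent=8.0)
        a = self._cores(box, np.arange(10))
        b = self._cores(other, np.arange(10))
        with pytest.raises(StructuralError):
            compute_dvo(a, b, box.cell_volumes)


class TestSummaries:
    def test_frozen_vortex_tadvo_one_std_zero(self, box):
        fld, _ = make_velocity_field(box, "rigid-rotation", omega=5.0,
                                     waveform=_steady(5))
        sets, summary = analyze_vortices(fld, box, systole_window=(0, 4))
        assert summary.tadvo == 1.0
        assert summary.tadvo_std == 0.0
        assert summary.num_core == 1.0

    def test_translating_vortex_tadvo_zero(self):
        """Tube jumping by more than its diameter each phase: disjoint cores."""
        mesh = make_box_mesh(n=12, extent=12.0)
        frames = []
        for cx in (-4.0, 0.0, 4.0):
            shifted = mesh.nodes.copy()
            shifted[:, 0] -= cx
            from hemopost.synthetic import _lamb_oseen
            frames.append(_lamb_oseen(shifted, np.zeros(2), 0.8, 300.0))
        fld = TimeResolvedField(values=np.stack(frames),
                                phase_times=np.array([0.0, 1 / 3, 2 / 3]),
                                period=1.0, kind="velocity")
        _, summary = analyze_vortices(fld, mesh, threshold_fraction=0.3,
                                      systole_window=(0, 2))
        assert summary.tadvo == 0.0

    def test_window_too_short_raises(self, box):
        fld, _ = make_velocity_field(box, "rigid-rotation", waveform=_steady())
        sets, _ = analyze_vortices(fld, box, systole_window=(0, 2))
        with pytest.raises(TemporalStatisticError):
            summarize_vortex(sets, (1, 1), box.cell_volumes)

    def test_threshold_sweep_stability_on_persistent_vortex(self):
        """TADVO varies by < 0.1 over the 0.15–0.30 threshold sweep.

        The fixture is a vortex tube present at every phase whose strength
        varies a few percent over the window, as aneurysmal swirl does
        around peak systole.
        """
        mesh = make_box_mesh(n=10, extent=10.0)
        from hemopost.synthetic import _lamb_oseen
        base = _lamb_oseen(mesh.nodes, np.zeros(2), 2.0, 500.0)
        t = np.arange(8) / 8
        s = 1.0 + 0.05 * np.sin(2 * np.pi * t)
        fld = TimeResolvedField(values=s[:, None, None] * base[None],
                                phase_times=t, period=1.0, kind="velocity")
        tadvos = []
        for f in (0.15, 0.20, 0.25, 0.30):
            _, summ = analyze_vortices(fld, mesh, threshold_fraction=f,
                                       systole_window=(0, 7))
            tadvos.append(summ.tadvo)
        assert max(tadvos) - min(tadvos) < 0.1
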