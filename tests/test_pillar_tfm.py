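"""Pillar detection, sub-pixel localization, tracking, drift and forces."""

import numpy as np
import pytest

from mechanoquant import pillar_tfm as tfm
from mechanoquant import synthetic_data as synth


def _render_spot(shape, x0, y0, sigma=1.5, amp=1000.0, bg=100.0):
    yy, xx = np.mgrid[0:shape[0], 0:shape[1]]
    return bg + amp * np.exp(-((xx - x0) ** 2 + (yy - y0) ** 2)
                             / (2 * sigma**2))


def _tracks_from_scene(scene, stack, **kw):
    """Track in truth order so estimates align with the truth arrays."""
    return tfm.track_pillars(stack, scene.rest_positions,
                             spacing_px=12.0,
                             reference_flags=scene.reference_flags,
                             pixel_size_um=scene.pixel_size_um, **kw)


class TestDetect:
    def test_noise_free_lattice_detected_exactly(self, static_scene):
        stack = synth.gen_pillar_timelapse(static_scene)
        found = tfm.detect_pillars(stack[0], spacing_hint_px=12)
        assert found.shape[0] == static_scene.n_pillars
        # every detection within 1 px of a distinct rest position
        from scipy.spatial import cKDTree
        d, idx = cKDTree(static_scene.rest_positions).query(found)
        assert d.max() < 1.0
        assert len(set(idx)) == static_scene.n_pillars

    def test_noisy_lattice_count_within_five_percent(self):
        scene = synth.make_pillar_scene(n_rows=10, n_cols=10, n_frames=1,
                                        snr=10.0, max_displacement_px=0.0,
                                        seed=21)
        stack = synth.gen_pillar_timelapse(scene)
        found = tfm.detect_pillars(stack[0], spacing_hint_px=12)
        assert abs(found.shape[0] - 100) <= 5

    def test_blank_frame_raises(self):
        with pytest.raises(ValueError, match="blank|no pillar"):
            tfm.detect_pillars(np.full((64, 64), 7.0), spacing_hint_px=12)


class TestLocalize:
    def test_noise_free_subpixel_centre_recovered(self):
        frame = _render_spot((41, 41), 10.30, 20.70)
        x, y, _, ok = tfm.localize_center(frame, (10, 21), window_px=11)
        assert ok
        assert abs(x - 10.30) < 1e-3 and abs(y - 20.70) < 1e-3

    def test_integer_centre_symmetric_window_exact(self):
        frame = _render_spot((31, 31), 15.0, 15.0)
        x, y, _, ok = tfm.localize_center(frame, (15, 15), window_px=11)
        assert ok
        assert x == pytest.approx(15.0, abs=1e-9)
        assert y == pytest.approx(15.0, abs=1e-9)

    def test_window_clipped_by_edge_raises(self):
        frame = _render_spot((31, 31), 3.0, 3.0)
        with pytest.raises(ValueError, match="edge"):
            tfm.localize_center(frame, (3, 3), window_px=11)

    def test_precision_near_cramer_rao_bound(self):
        # Additive-noise CRLB for an isotropic Gaussian spot is
        # sqrt(2/pi) * noise/amplitude px per coordinate, independent of
        # the PSF width; the LSQ fit should be close to efficient.
        rng = np.random.default_rng(11)
        amp, snr = 1000.0, 10.0
        errs = []
        for _ in range(300):
            x0 = 15 + rng.uniform(-0.5, 0.5)
            y0 = 15 + rng.uniform(-0.5, 0.5)
            frame = _render_spot((31, 31), x0, y0, amp=amp) \
                + rng.normal(0, amp / snr, (31, 31))
            x, y, _, _ = tfm.localize_center(frame, (15, 15), window_px=15)
            errs.extend([x - x0, y - y0])
        rmse = float(np.sqrt(np.mean(np.square(errs))))
        crlb = np.sqrt(2 / np.pi) / snr
        assert rmse < 1.25 * crlb

    @pytest.mark.parametrize("snr,bound", [(20.0, 0.05), (50.0, 0.02)])
    def test_rmse_below_bound_at_high_snr(self, snr, bound):
        rng = np.random.default_rng(4)
        errs = []
        for _ in range(200):
            x0 = 15 + rng.uniform(-0.5, 0.5)
            y0 = 15 + rng.uniform(-0.5, 0.5)
            frame = _render_spot((31, 31), x0, y0) \
                + rng.normal(0, 1000.0 / snr, (31, 31))
            x, y, _, _ = tfm.localize_center(frame, (15, 15), window_px=15)
            errs.extend([x - x0, y - y0])
        assert float(np.sqrt(np.mean(np.square(errs)))) < bound

    def test_rmse_monotone_in_snr(self):
        rng = np.random.default_rng(8)
        rmses = []
        for snr in (5.0, 10.0, 20.0, 50.0):
            errs = []
            for _ in range(150):
                x0 = 15 + rng.uniform(-0.5, 0.5)
                y0 = 15 + rng.uniform(-0.5, 0.5)
                frame = _render_spot((31, 31), x0, y0) \
                    + rng.normal(0, 1000.0 / snr, (31, 31))
                x, y, _, _ = tfm.localize_center(frame, (15, 15),
                                                 window_px=15)
                errs.extend([x - x0, y - y0])
            rmses.append(np.sqrt(np.mean(np.square(errs))))
        # allow a little Monte-Carlo slack between adjacent levels
        assert all(rmses[i + 1] < rmses[i] * 1.1 for i in range(3))


class TestTrackAndDrift:
    def test_static_scene_tracks_constant(self, static_scene):
        stack = synth.gen_pillar_timelapse(static_scene)
        tracks = _tracks_from_scene(static_scene, stack)
        spread = np.nanmax(tracks.positions, axis=1) \
            - np.nanmin(tracks.positions, axis=1)
        assert np.nanmax(spread) < 1e-3

    def test_single_displaced_pillar_changes_only_that_track(self):
        scene = synth.make_pillar_scene(n_rows=4, n_cols=4, n_frames=12,
                                        snr=np.inf, max_displacement_px=0.0,
                                        seed=1)
        scene.displacements[10:, 5, 0] = 0.5
        stack = synth.gen_pillar_timelapse(scene)
        tracks = _tracks_from_scene(scene, stack)
        moved = np.nanmax(np.abs(
            tracks.positions - tracks.positions[:, :1, :]), axis=(1, 2))
        assert moved[5] == pytest.approx(0.5, abs=1e-3)
        assert np.all(np.delete(moved, 5) < 1e-3)
        drifted_at = np.flatnonzero(np.abs(
            tracks.positions[5, :, 0] - tracks.positions[5, 0, 0]) > 0.25)
        assert drifted_at.min() == 10

    def test_linear_drift_recovered_noise_free(self, small_scene):
        stack = synth.gen_pillar_timelapse(small_scene)
        tracks = _tracks_from_scene(small_scene, stack)
        drift = tfm.estimate_drift(tracks)
        assert np.allclose(drift.drift_px, small_scene.drift, atol=2e-3)
        assert np.all(drift.drift_px[0] == 0.0)

    def test_no_drift_gives_zero_trace(self, static_scene):
        stack = synth.gen_pillar_timelapse(static_scene)
        tracks = _tracks_from_scene(static_scene, stack)
        drift = tfm.estimate_drift(tracks)
        assert np.all(np.abs(drift.drift_px) < 1e-3)

    def test_missing_reference_pillars_rejected(self, static_scene):
        stack = synth.gen_pillar_timelapse(static_scene)
        tracks = tfm.track_pillars(stack, static_scene.rest_positions,
                                   spacing_px=12.0)
        with pytest.raises(ValueError, match="cell-free"):
            tfm.estimate_drift(tracks)


class TestDisplacementsAndForces:
    def test_frame_zero_displacement_always_zero(self, small_scene):
        stack = synth.gen_pillar_timelapse(small_scene)
        tracks = _tracks_from_scene(small_scene, stack)
        u = tfm.compute_displacements(tracks, tfm.estimate_drift(tracks))
        assert np.all(u[:, 0, :] == 0.0)

    def test_pure_drift_scene_has_zero_displacements(self):
        scene = synth.make_pillar_scene(n_rows=4, n_cols=4, n_frames=10,
                                        snr=np.inf, max_displacement_px=0.0,
                                        drift_per_frame_px=(0.2, 0.1), seed=4)
        stack = synth.gen_pillar_timelapse(scene)
        tracks = _tracks_from_scene(scene, stack)
        u = tfm.compute_displacements(tracks, tfm.estimate_drift(tracks))
        assert np.nanmax(np.abs(u)) < 5e-3 * scene.pixel_size_um * 10

    def test_translation_invariance_of_displacements(self, small_scene):
        stack = synth.gen_pillar_timelapse(small_scene)
        tracks = _tracks_from_scene(small_scene, stack)
        u1 = tfm.compute_displacements(tracks, tfm.estimate_drift(tracks))
        shifted = tfm.PillarTrackSet(
            pillar_ids=tracks.pillar_ids,
            positions=tracks.positions + np.array([3.7, -1.2]),
            residuals=tracks.residuals, ok=tracks.ok,
            reference_flags=tracks.reference_flags,
            pixel_size_um=tracks.pixel_size_um)
        u2 = tfm.compute_displacements(shifted, tfm.estimate_drift(shifted))
        assert np.allclose(u1, u2, atol=1e-9)

    def test_linear_spring_law_and_stiffness_scaling(self):
        u = np.zeros((2, 3, 2))
        u[0, 2] = (0.3, 0.0)
        f1 = tfm.displacements_to_forces(u, 10.0)
        assert f1.peak_forces_nn[0] == pytest.approx(3.0)
        assert f1.peak_forces_nn[1] == 0.0
        f2 = tfm.displacements_to_forces(u, 20.0)
        assert np.allclose(f2.forces_nn, 2 * f1.forces_nn)
        assert np.allclose(f2.peak_forces_nn, 2 * f1.peak_forces_nn)

    def test_force_magnitude_equals_stiffness_times_displacement(self):
        rng = np.random.default_rng(0)
        u = rng.normal(size=(5, 4, 2))
        field = tfm.displacements_to_forces(u, 7.5)
        assert np.allclose(np.linalg.norm(field.forces_nn, axis=2),
                           7.5 * np.linalg.norm(u, axis=2))

    def test_nonpositive_stiffness_rejected(self):
        with pytest.raises(ValueError, match="stiffness"):
            tfm.displacements_to_forces(np.zeros((1, 2, 2)), 0.0)

    def test_mostly_missing_pillars_excluded_from_summary(self):
        u = np.zeros((2, 10, 2))
        u[1, 5:, :] = np.nan          # 50% missing
        field = tfm.displacements_to_forces(u, 10.0)
        assert field.cell_summary["n_pillars"] == 1
        assert field.cell_summary["n_excluded_missing"] == 1
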