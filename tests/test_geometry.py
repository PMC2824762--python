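"""Superposition, axis fitting, tilt and axial-span geometry."""

import math

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from clampdna.dna_builder import build_bform_duplex
from clampdna.geometry import (
    FrameMismatchError,
    GeometryError,
    InsufficientDataError,
    RigidTransform,
    apply_transform,
    axial_span,
    fit_helical_axis,
    kabsch_superpose,
    min_bp_to_span,
    ring_axis,
    tilt_angle,
)
from clampdna.synthetic_data import (
    SyntheticClampSpec,
    make_synthetic_clamp,
    make_tilted_duplex,
)


class TestKabsch:
    def test_identity_on_identical_point_sets(self, rng):
        pts = rng.normal(0, 10, (8, 3))
        t, rmsd = kabsch_superpose(pts, pts)
        np.testing.assert_allclose(t.rotation, np.eye(3), atol=1e-9)
        np.testing.assert_allclose(t.translation, 0, atol=1e-9)
        assert rmsd < 1e-9

    def test_recovers_known_transform(self, rng):
        pts = rng.normal(0, 10, (10, 3))
        t0 = RigidTransform.random(rng)
        t, rmsd = kabsch_superpose(pts, t0.apply(pts))
        assert np.abs(t.rotation - t0.rotation).max() < 1e-6
        assert np.abs(t.translation - t0.translation).max() < 1e-6
        assert rmsd < 1e-6

    def test_rmsd_beats_rotation_grid_oracle(self, rng):
        """Kabsch is the global optimum: no rotation on a coarse grid
        (with centroid-matching translation) does better, and the grid's
        best is within its own resolution of the Kabsch minimum."""
        mobile = rng.normal(0, 5, (4, 3))
        target = RigidTransform.random(rng).apply(mobile) \
            + rng.normal(0, 0.3, (4, 3))
        _, rmsd = kabsch_superpose(mobile, target)

        m0 = mobile - mobile.mean(axis=0)
        t0 = target - target.mean(axis=0)
        step = 9.0  # degrees
        angles = np.arange(0.0, 360.0, step)
        half = np.arange(0.0, 180.0 + step, step)
        best = np.inf
        for a in angles:
            for b in half:
                for c in angles:
                    R = Rotation.from_euler("zyz", [a, b, c],
                                            degrees=True).as_matrix()
                    val = np.sqrt(np.mean(np.sum((m0 @ R.T - t0) ** 2,
                                                 axis=1)))
                    best = min(best, val)
        assert rmsd <= best + 1e-12
        # grid resolution bound: rotating by half a step moves a point by
        # at most r * step/2 radians
        r_max = np.linalg.norm(m0, axis=1).max()
        assert best - rmsd <= r_max * math.radians(step)

    def test_collinear_points_rejected(self):
        line = np.array([[0.0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]])
        with pytest.raises(GeometryError):
            kabsch_superpose(line, line + 1.0)

    def test_too_few_points_rejected(self):
        pts = np.eye(3)[:2]
        with pytest.raises(InsufficientDataError):
            kabsch_superpose(pts, pts)

    def test_mismatched_correspondence_rejected(self, rng):
        a, b = rng.normal(size=(5, 3)), rng.normal(size=(6, 3))
        with pytest.raises(ValueError):
            kabsch_superpose(a, b)


class TestApplyTransform:
    def test_identity_leaves_coordinates(self, ring3):
        s = apply_transform(RigidTransform.identity(), ring3)
        np.testing.assert_array_equal(s.coords(), ring3.coords())

    def test_isometry(self, ring3, rng):
        t = RigidTransform.random(rng)
        a = ring3.coords()
        b = apply_transform(t, ring3).coords()
        da = np.linalg.norm(a[None, :, :] - a[:, None, :], axis=-1)
        db = np.linalg.norm(b[None, :, :] - b[:, None, :], axis=-1)
        np.testing.assert_allclose(da, db, atol=1e-9)

    def test_composition(self, ring3, rng):
        t1, t2 = RigidTransform.random(rng), RigidTransform.random(rng)
        two_step = apply_transform(t2, apply_transform(t1, ring3))
        one_step = apply_transform(t2 @ t1, ring3)
        np.testing.assert_allclose(two_step.coords(), one_step.coords(),
                                   atol=1e-9)


class TestHelicalAxis:
    def test_collinear_points_on_z(self):
        pts = np.column_stack([np.zeros(6), np.zeros(6), np.arange(6.0)])
        h = fit_helical_axis(pts)
        np.testing.assert_allclose(h.direction, [0, 0, 1], atol=1e-12)
        assert h.fit_rms < 1e-12

    def test_orientation_follows_point_order(self):
        pts = np.column_stack([np.zeros(6), np.zeros(6), -np.arange(6.0)])
        h = fit_helical_axis(pts)
        np.testing.assert_allclose(h.direction, [0, 0, -1], atol=1e-12)

    def test_built_duplex_axis(self):
        d = build_bform_duplex("ACGTACGTACGTACG")
        h = fit_helical_axis(d.bp_centers)
        assert tilt_angle(h.direction, np.array([0, 0, 1.0])) < 0.5

    def test_rotation_equivariance(self, rng):
        d = build_bform_duplex("ACGTACGTAC")
        t = RigidTransform.random(rng)
        h0 = fit_helical_axis(d.bp_centers)
        h1 = fit_helical_axis(t.apply(d.bp_centers))
        np.testing.assert_allclose(h1.direction, t.rotation @ h0.direction,
                                   atol=1e-6)

    def test_fewer_than_four_points_rejected(self):
        with pytest.raises(InsufficientDataError):
            fit_helical_axis(np.zeros((3, 3)))


class TestRingAxis:
    def test_exact_c3_recovery(self, ring3):
        ax = ring_axis(ring3, n_fold=3)
        assert tilt_angle(ax.direction, np.array([0, 0, 1.0])) < 1e-6
        assert ax.quality < 1e-6

    def test_exact_c6_recovery(self, ring6):
        ax = ring_axis(ring6, n_fold=6)
        assert tilt_angle(ax.direction, np.array([0, 0, 1.0])) < 1e-6
        assert ax.quality < 1e-6

    def test_symmetry_and_plane_methods_agree(self, ring3):
        a = ring_axis(ring3, 3, method="symmetry")
        b = ring_axis(ring3, 3, method="plane")
        assert tilt_angle(a.direction, b.direction) < 3.0

    def test_equivariance_under_rotation(self, ring3, rng):
        t = RigidTransform.random(rng)
        moved = apply_transform(t, ring3)
        a0 = ring_axis(ring3, 3)
        a1 = ring_axis(moved, 3)
        assert tilt_angle(a1.direction, t.rotation @ a0.direction) < 1e-6

    def test_proximal_markers_orient_direction(self, ring3):
        ax0 = ring_axis(ring3, 3)
        # markers below the ring = proximal face on the -z side
        markers = np.array([[10.0, 0.0, -30.0]])
        ax = ring_axis(ring3, 3, proximal_markers=markers)
        assert ax.direction @ np.array([0, 0, 1.0]) > 0
        assert ax.axial_coordinates(markers)[0] < 0
        del ax0

    def test_wrong_chain_count_needs_unit_map(self, ring3):
        with pytest.raises(ValueError, match="unit"):
            ring_axis(ring3, n_fold=6)


class TestTiltAngle:
    def test_parallel_and_orthogonal(self):
        z = np.array([0, 0, 1.0])
        assert tilt_angle(z, z) == pytest.approx(0.0)
        assert tilt_angle(np.array([1.0, 0, 0]), z) == pytest.approx(90.0)

    def test_sign_of_axes_ignored(self):
        z = np.array([0, 0, 1.0])
        v = np.array([0.0, np.sin(0.3), np.cos(0.3)])
        assert tilt_angle(v, z) == pytest.approx(tilt_angle(-v, z))
        assert tilt_angle(v, z) <= 90.0

    @pytest.mark.parametrize("tilt", [0, 10, 20, 22, 40, 60])
    def test_recovery_on_synthetic_fixture(self, ring3, tilt):
        d = make_tilted_duplex(ring3, tilt=tilt, offset=0.0, length=25, seed=7)
        ax = ring_axis(ring3, 3)
        h = fit_helical_axis(d.bp_centers)
        assert abs(tilt_angle(h, ax) - tilt) < 0.5


class TestAxialSpan:
    def test_long_duplex_goes_through(self, ring3):
        d = make_tilted_duplex(ring3, tilt=0.0, offset=0.0, length=30, seed=1)
        ax = ring_axis(ring3, 3)
        rep = axial_span(d, ax, ring3)
        assert rep.classification == "through"
        assert rep.monotone

    def test_truncation_series_partial_and_opening(self, ring3):
        """Shortening the duplex from the blunt end walks the terminal
        base pair back from 'through' to 'partial' to 'opening'."""
        ax = ring_axis(ring3, 3)
        d = make_tilted_duplex(ring3, tilt=0.0, offset=0.0, length=30, seed=1)
        rep = axial_span(d, ax, ring3)
        rise = 3.38
        thickness = rep.clamp_thickness
        n_partial = int(thickness / rise) - 2       # safely between planes
        rep_partial = axial_span(d.bp_centers[:n_partial], ax, ring3)
        assert rep_partial.classification == "partial"
        rep_opening = axial_span(d.bp_centers[:1], ax, ring3)
        assert rep_opening.classification == "opening"

    def test_frame_mismatch_detected(self, ring3):
        d = build_bform_duplex("ACGTACGTAC")  # at the origin-frame z-axis
        far = d.bp_centers + np.array([500.0, 0, 0])
        ax = ring_axis(ring3, 3)
        with pytest.raises(FrameMismatchError):
            axial_span(far, ax, ring3)


class TestMinBpToSpan:
    def test_closed_form_at_zero_tilt(self, ring3):
        d = make_tilted_duplex(ring3, tilt=0.0, offset=0.0, length=30, seed=1)
        ax = ring_axis(ring3, 3)
        rep = axial_span(d, ax, ring3)
        search = min_bp_to_span(d, ax, ring3)
        assert search.bounded
        assert search.min_bp == math.ceil(rep.clamp_thickness / 3.38)

    def test_tilted_needs_at_least_as_many_bp(self, ring3):
        ax = ring_axis(ring3, 3)
        flat = min_bp_to_span(
            make_tilted_duplex(ring3, 0.0, 0.0, 30, seed=1), ax, ring3)
        steep = min_bp_to_span(
            make_tilted_duplex(ring3, 40.0, 0.0, 30, seed=1), ax, ring3)
        assert steep.min_bp >= flat.min_bp

    def test_short_duplex_reported_unbounded(self, ring3):
        ax = ring_axis(ring3, 3)
        d = make_tilted_duplex(ring3, tilt=0.0, offset=0.0, length=3, seed=1)
        search = min_bp_to_span(d, ax, ring3)
        assert not search.bounded and search.min_bp is None
        assert search.max_examined == 3


def test_measurements_invariant_under_common_rigid_transform(ring3, rng):
    """Tilt, span classification and thickness are frame-independent."""
    d = make_tilted_duplex(ring3, tilt=22.0, offset=0.0, length=20, seed=3)
    markers = np.array([[0.0, 0.0, -40.0]])   # proximal face marker
    ax = ring_axis(ring3, 3, proximal_markers=markers)
    rep0 = axial_span(d, ax, ring3)
    tilt0 = tilt_angle(fit_helical_axis(d.bp_centers), ax)

    t = RigidTransform.random(rng)
    ring_m = apply_transform(t, ring3)
    d_m = d.transformed(t)
    ax_m = ring_axis(ring_m, 3, proximal_markers=t.apply(markers))
    rep1 = axial_span(d_m, ax_m, ring_m)
    tilt1 = tilt_angle(fit_helical_axis(d_m.bp_centers), ax_m)

    assert abs(tilt0 - tilt1) < 1e-6
    assert rep1.classification == rep0.classification
    assert rep1.clamp_thickness == pytest.approx(rep0.clamp_thickness,
                                                 abs=1e-6)
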