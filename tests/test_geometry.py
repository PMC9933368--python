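"""Axis alignment, canonical resampling and dynamic-mesh interpolation."""

import numpy as np
import pytest

from cmrstrain import (ContourError, GeometryError, align_longitudinal_axis,
                       build_dynamic_mesh, generate_phantom,
                       resample_slice_fractions, rotation_matrix,
                       transform_rigid)
from cmrstrain.contours import CANONICAL_SLICE_FRACTIONS
from cmrstrain.geometry import DynamicMesh
from cmrstrain.phantom import PhantomConfig, endo_radius_ed


def _max_point_dev(a, b):
    return max(np.abs(sa.endo - sb.endo).max()
               for fa, fb in zip(a.frames, b.frames)
               for sa, sb in zip(fa.slices, fb.slices))


class TestAlignment:
    def test_already_aligned_is_identity(self, default_tracked):
        aligned = align_longitudinal_axis(default_tracked)
        assert _max_point_dev(default_tracked, aligned) < 1e-9

    def test_known_rotation_restores_axis(self, default_tracked):
        rot = rotation_matrix([1.0, -2.0, 0.5], 0.8)
        moved = transform_rigid(default_tracked, rot, [7.0, -3.0, 12.0])
        aligned = align_longitudinal_axis(moved)
        # endo centroids must be colinear with the z axis
        for fr in aligned.frames:
            for sl in fr.slices:
                ctr = sl.endo.mean(axis=0)
                assert np.hypot(ctr[0], ctr[1]) < 1e-6

    def test_translation_removed_apex_below_base(self, default_tracked):
        moved = transform_rigid(default_tracked, np.eye(3), [10.0, -5.0, 3.0])
        aligned = align_longitudinal_axis(moved)
        assert _max_point_dev(default_tracked, aligned) < 1e-9
        for fr in aligned.frames:
            assert fr.apex_z < fr.base_z
        assert aligned.frames[0].apex_z == pytest.approx(0.0, abs=1e-9)

    def test_degenerate_centroids_rejected(self, default_tracked):
        squashed = default_tracked.copy()
        for fr in squashed.frames:
            for sl in fr.slices:
                sl.endo[:, 2] = 0.0
                sl.endo[:, :2] = squashed.frames[0].slices[0].endo[:, :2]
        with pytest.raises(ContourError, match="orientable"):
            align_longitudinal_axis(squashed)


class TestResampling:
    def test_four_canonical_slices_per_frame(self, default_tracked):
        out = resample_slice_fractions(align_longitudinal_axis(default_tracked))
        for fr in out.frames:
            assert [s.slice_fraction for s in fr.slices] == list(
                CANONICAL_SLICE_FRACTIONS)

    def test_interpolation_at_knots_is_identity(self, default_tracked):
        aligned = align_longitudinal_axis(default_tracked)
        out = resample_slice_fractions(aligned)
        assert _max_point_dev(aligned, out) < 1e-9

    def test_linear_radius_profile_recovered_at_midplane(self):
        # slices at non-canonical fractions with radius linear in z:
        # the interpolated radius at f=0.5 must match the line
        from cmrstrain.contours import (CANONICAL_ANGLES_DEG, Frame,
                                        SliceContour, TrackedPointSet)
        angles = np.array(CANONICAL_ANGLES_DEG)
        L = 80.0
        tracked = TrackedPointSet("linear", [])
        for i in range(3):
            fr = Frame(i / 3, 0.0, L, [])
            for f in (0.3, 0.45, 0.7, 0.95):
                r = 10.0 + 15.0 * f  # linear taper
                pts = np.stack([r * np.cos(np.deg2rad(angles)),
                                r * np.sin(np.deg2rad(angles)),
                                np.full(12, f * L)], axis=1)
                fr.slices.append(SliceContour(f, angles.copy(), pts,
                                              pts * [1.3, 1.3, 1.0]))
            tracked.frames.append(fr)
        out = resample_slice_fractions(tracked,
                                       fractions=(0.3, 0.5, 0.7, 0.95))
        mid = out.frames[0].slices[1]
        assert mid.slice_fraction == 0.5
        radii = np.hypot(mid.endo[:, 0], mid.endo[:, 1])
        assert np.allclose(radii, 10.0 + 15.0 * 0.5, rtol=1e-3)

    def test_extrapolation_beyond_tolerance_rejected(self, default_tracked):
        aligned = align_longitudinal_axis(default_tracked)
        with pytest.raises(GeometryError, match="outside the tracked"):
            resample_slice_fractions(aligned, fractions=(0.25, 0.5, 0.75, 1.1))


class TestDynamicMesh:
    def test_default_grid_node_counts(self, default_mesh):
        t, z, th = default_mesh.shape
        assert (t, z, th) == (60, 60, 60)
        assert default_mesh.endo.shape == (60, 60, 60, 3)
        assert z * th == 3600  # nodes per boundary per time point

    def test_mesh_passes_through_control_points(self, canonical_tracked,
                                                default_mesh):
        for fr in canonical_tracked.frames[::5]:
            for sl in fr.slices:
                for k in range(0, 12, 3):
                    for b in ("endo", "epi"):
                        p = default_mesh.evaluate(b, fr.time_fraction,
                                                  sl.angles_deg[k],
                                                  sl.slice_fraction)
                        assert np.abs(p - getattr(sl, b)[k]).max() < 1e-9

    def test_circle_control_points_stay_on_circle(self):
        # periodic spline through 12 points of a circle of radius r:
        # exact at the control angles, within 0.5% in between
        from cmrstrain.contours import (CANONICAL_ANGLES_DEG, Frame,
                                        SliceContour, TrackedPointSet)
        angles = np.array(CANONICAL_ANGLES_DEG)
        r = 20.0
        tracked = TrackedPointSet("circle", [])
        for i in range(3):
            fr = Frame(i / 3, 0.0, 80.0, [])
            for f in CANONICAL_SLICE_FRACTIONS:
                pts = np.stack([r * np.cos(np.deg2rad(angles)),
                                r * np.sin(np.deg2rad(angles)),
                                np.full(12, f * 80.0)], axis=1)
                fr.slices.append(SliceContour(f, angles.copy(), pts,
                                              pts * [1.4, 1.4, 1.0]))
            tracked.frames.append(fr)
        mesh = build_dynamic_mesh(tracked)
        radii = np.hypot(mesh.endo[..., 0], mesh.endo[..., 1])
        on_ctrl = np.isin(mesh.theta_deg, angles)
        assert np.abs(radii[:, :, on_ctrl] - r).max() < 1e-9
        assert np.abs(radii / r - 1).max() < 0.005

    def test_static_input_gives_static_mesh(self, default_config):
        import dataclasses
        cfg = dataclasses.replace(default_config, lambda_c_es=1.0,
                                  lambda_l_es=1.0)
        mesh = build_dynamic_mesh(generate_phantom(cfg))
        assert np.abs(mesh.endo - mesh.endo[:1]).max() < 1e-9

    def test_too_few_frames_rejected(self, default_config):
        import dataclasses
        cfg = dataclasses.replace(default_config, n_frames=2)
        with pytest.raises((GeometryError, ContourError)):
            build_dynamic_mesh(generate_phantom(cfg))

    def test_self_intersecting_contour_rejected(self, canonical_tracked):
        bad = canonical_tracked.copy()
        sl = bad.frames[0].slices[0]
        sl.endo[[0, 6]] = sl.endo[[6, 0]]  # swap opposite points -> bowtie
        with pytest.raises(GeometryError, match="self-intersect"):
            build_dynamic_mesh(bad)

    def test_refinement_convergence(self, canonical_tracked):
        # doubling the angular/longitudinal sampling changes circumference
        # and meridian length by < 0.1 %
        from cmrstrain.strain import (_closed_arc_lengths,
                                      _meridian_arc_lengths)
        lo = build_dynamic_mesh(canonical_tracked, (12, 60, 60))
        hi = build_dynamic_mesh(canonical_tracked, (12, 120, 120))
        c_lo = _closed_arc_lengths(np.moveaxis(lo.endo, 2, -2), lo.theta_deg)
        c_hi = _closed_arc_lengths(np.moveaxis(hi.endo, 2, -2), hi.theta_deg)
        # apical-most and basal-most slices are shared between the grids
        assert np.abs(c_hi[:, [0, -1]] / c_lo[:, [0, -1]] - 1).max() < 1e-3
        m_lo = _meridian_arc_lengths(np.moveaxis(lo.endo, 1, 2),
                                     lo.z_fractions)
        m_hi = _meridian_arc_lengths(np.moveaxis(hi.endo, 1, 2),
                                     hi.z_fractions)
        assert np.abs(m_hi[:, ::2] / m_lo - 1).max() < 1e-3
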