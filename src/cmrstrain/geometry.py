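"""Axis alignment, canonical slice resampling and dynamic-mesh interpolation.

The pipeline stage between a raw feature-tracking result and the strain
computation:

1. :func:`align_longitudinal_axis` rigidly moves the tracked point set so
   the left-ventricular long axis coincides with +z (apex low, base high)
   and angular position 0 deg points at the anterior reference direction.
2. :func:`resample_slice_fractions` interpolates the tracked slices to the
   four canonical planes at 25/50/75/100 % of the apex-to-base distance,
   re-evaluated per frame so the planes follow the moving apex and base
   (partial through-plane-motion compensation).
3. :func:`build_dynamic_mesh` interpolates a smooth dynamic mesh -- a
   periodic cubic spline around each contour, a cubic spline through the
   slice levels, and a periodic cubic spline over the cardiac cycle --
   sampled on a regular (time x rotation x slice) grid, 60x60x60 by
   default (3600 nodes per boundary surface per time point).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import CubicSpline, interp1d

from .contours import (ContourError, Frame, SliceContour, TrackedPointSet,
                       CANONICAL_SLICE_FRACTIONS, rotation_matrix)

DEFAULT_GRID = (60, 60, 60)  # (T, Theta, Z)

#: Fraction of LV length by which canonical planes may extrapolate beyond
#: the tracked slice range (the basal 100 % plane can sit marginally
#: outside the tracked stack).
EXTRAPOLATION_TOLERANCE = 0.02


class GeometryError(ValueError):
    """Raised for degenerate or self-intersecting geometry."""


# ----------------------------------------------------------------------
# alignment


def _circular_mean_deg(angles_deg: np.ndarray) -> float:
    a = np.deg2rad(angles_deg)
    return float(np.rad2deg(np.arctan2(np.sin(a).mean(), np.cos(a).mean())))


def align_longitudinal_axis(tracked: TrackedPointSet) -> TrackedPointSet:
    """Rigidly align a tracked point set to the canonical frame.

    The line through the end-diastolic endocardial centroids of the
    most-apical and most-basal slices becomes the +z axis (apex at z = 0 at
    end-diastole); the in-plane rotation is fixed so that the control point
    labelled angle ``a`` lies at azimuth ``a`` (least-squares over all
    end-diastolic endo points), anchoring 0 deg at the anterior reference.
    """
    from .contours import _ed_axis_direction, transform_rigid

    u = _ed_axis_direction(tracked)
    # rotation taking the axis direction onto +z
    ez = np.array([0.0, 0.0, 1.0])
    c = float(np.clip(u @ ez, -1.0, 1.0))
    if c > 1 - 1e-15:
        r_axis = np.eye(3)
    elif c < -1 + 1e-15:
        r_axis = rotation_matrix([1.0, 0.0, 0.0], np.pi)
    else:
        r_axis = rotation_matrix(np.cross(u, ez), np.arccos(c))

    # in-plane rotation: remove the mean offset between point azimuths and
    # their angle labels, computed on the rotated end-diastolic endo points
    fr0 = tracked.frames[0]
    offsets = []
    for sl in fr0.slices:
        pts = sl.endo @ r_axis.T
        ctr = pts.mean(axis=0)
        az = np.rad2deg(np.arctan2(pts[:, 1] - ctr[1], pts[:, 0] - ctr[0]))
        offsets.append(((az - sl.angles_deg) + 180.0) % 360.0 - 180.0)
    delta = _circular_mean_deg(np.concatenate(offsets))
    rot = rotation_matrix(ez, -np.deg2rad(delta)) @ r_axis

    # translation: ED axis on x = y = 0, ED apex projection at z = 0
    order = np.argsort([s.slice_fraction for s in fr0.slices])
    lo = fr0.slices[order[0]].endo.mean(axis=0) @ rot.T
    hi = fr0.slices[order[-1]].endo.mean(axis=0) @ rot.T
    t_xy = -0.5 * (lo[:2] + hi[:2])
    t_z = -fr0.apex_z  # projections are rotation invariant
    return transform_rigid(tracked, rot, np.array([t_xy[0], t_xy[1], t_z]))


# ----------------------------------------------------------------------
# canonical slice resampling


def _merge_duplicate_slices(slices: list[SliceContour],
                            z: np.ndarray) -> tuple[list[SliceContour], np.ndarray]:
    """Average slices that share a z position before spline fitting."""
    out: list[SliceContour] = []
    zs: list[float] = []
    used = np.zeros(len(slices), dtype=bool)
    for i in range(len(slices)):
        if used[i]:
            continue
        same = np.abs(z - z[i]) < 1e-9
        used |= same
        grp = [slices[j] for j in np.flatnonzero(same)]
        merged = grp[0].copy()
        merged.endo = np.mean([g.endo for g in grp], axis=0)
        merged.epi = np.mean([g.epi for g in grp], axis=0)
        out.append(merged)
        zs.append(float(z[i]))
    return out, np.array(zs)


def resample_slice_fractions(
    tracked: TrackedPointSet,
    fractions: tuple[float, ...] = CANONICAL_SLICE_FRACTIONS,
    extrapolation_tolerance: float = EXTRAPOLATION_TOLERANCE,
) -> TrackedPointSet:
    """Interpolate each frame to slices at fixed apex-to-base fractions.

    Target planes sit at ``apex_z + f * (base_z - apex_z)`` with the
    frame-specific apex/base, so the planes track through-plane motion.
    Point coordinates are interpolated along z through the input slices
    (cubic through >= 4 slices, linear otherwise).  Planes outside the
    tracked z range are allowed only within ``extrapolation_tolerance``
    of the LV length.
    """
    out = TrackedPointSet(tracked.subject_id, [])
    angles = tracked.angles()
    for fi, fr in enumerate(tracked.frames):
        slices = sorted(fr.slices, key=lambda s: s.slice_fraction)
        z = np.array([s.endo[:, 2].mean() for s in slices])
        slices, z = _merge_duplicate_slices(slices, z)
        if len(slices) < 2:
            raise GeometryError(f"/frames/{fi}: need >= 2 distinct slice "
                                "levels to interpolate")
        length = fr.base_z - fr.apex_z
        targets = fr.apex_z + np.asarray(fractions) * length
        over = np.maximum(z[0] - targets, targets - z[-1]) / length
        if np.any(over > extrapolation_tolerance):
            raise GeometryError(
                f"/frames/{fi}: requested plane lies {over.max():.3f} of LV "
                f"length outside the tracked slices (tolerance "
                f"{extrapolation_tolerance})")
        new_fr = Frame(fr.time_fraction, fr.apex_z, fr.base_z, [])
        stack = {b: np.array([getattr(s, b) for s in slices])
                 for b in ("endo", "epi")}  # (n_slices, 12, 3)
        for f, zt in zip(fractions, targets):
            pts = {}
            for b, arr in stack.items():
                if len(slices) >= 4:
                    pts[b] = CubicSpline(z, arr, axis=0)(zt)
                else:
                    pts[b] = interp1d(z, arr, axis=0,
                                      fill_value="extrapolate")(zt)
            new_fr.slices.append(
                SliceContour(float(f), angles.copy(), pts["endo"], pts["epi"]))
        out.frames.append(new_fr)
    return out


# ----------------------------------------------------------------------
# dynamic mesh


def _check_simple_polygons(tracked: TrackedPointSet) -> None:
    from shapely.geometry import LinearRing

    for i, fr in enumerate(tracked.frames):
        for j, sl in enumerate(fr.slices):
            for name in ("endo", "epi"):
                ring = LinearRing(getattr(sl, name)[:, :2])
                if not ring.is_simple:
                    raise GeometryError(
                        f"/frames/{i}/slices/{j}/{name}: control polygon "
                        "self-intersects")


def _periodic_theta_spline(ctrl: np.ndarray, angles: np.ndarray) -> CubicSpline:
    """Periodic spline over the angular axis (axis=-2 of ``ctrl``)."""
    x = np.append(angles, angles[0] + 360.0)
    y = np.concatenate([ctrl, ctrl[..., :1, :]], axis=-2)
    return CubicSpline(x, y, axis=ctrl.ndim - 2, bc_type="periodic")


def _periodic_time_spline(values: np.ndarray, tf: np.ndarray) -> CubicSpline:
    """Periodic spline over the cardiac cycle (axis 0 of ``values``)."""
    x = np.append(tf, tf[0] + 1.0)
    y = np.concatenate([values, values[:1]], axis=0)
    return CubicSpline(x, y, axis=0, bc_type="periodic")


@dataclass
class DynamicMesh:
    """Spline-interpolated endo/epi surfaces on a (t, z, theta) grid.

    ``endo``/``epi`` have shape (T, Z, Theta, 3) in mm; ``z_fractions``
    run apex -> base over the tracked slice-fraction span and
    ``theta_deg`` is uniform in [0, 360).  The tracked control points and
    frame times are retained so the underlying spline surface can be
    evaluated exactly at arbitrary coordinates (:meth:`evaluate`).
    """

    endo: np.ndarray
    epi: np.ndarray
    time_fractions: np.ndarray
    theta_deg: np.ndarray
    z_fractions: np.ndarray
    subject_id: str = ""
    _ctrl: dict | None = None  # boundary -> (frames, slices, 12, 3)
    _ctrl_angles: np.ndarray | None = None
    _ctrl_fracs: np.ndarray | None = None
    _ctrl_times: np.ndarray | None = None

    @property
    def shape(self) -> tuple[int, int, int]:
        return (len(self.time_fractions), len(self.z_fractions),
                len(self.theta_deg))

    def surface(self, boundary: str) -> np.ndarray:
        if boundary not in ("endo", "epi"):
            raise ValueError("boundary must be 'endo' or 'epi'")
        return getattr(self, boundary)

    def evaluate(self, boundary: str, t_fraction: float, theta_deg: float,
                 z_fraction: float) -> np.ndarray:
        """Evaluate the underlying spline surface at one point exactly."""
        if self._ctrl is None:
            raise ValueError("mesh does not carry its control points")
        ctrl = self._ctrl[boundary]  # (F, S, 12, 3)
        th = _periodic_theta_spline(ctrl, self._ctrl_angles)(theta_deg % 360.0)
        zs = CubicSpline(self._ctrl_fracs, th, axis=1)(z_fraction)  # (F, 3)
        return _periodic_time_spline(zs, self._ctrl_times)(t_fraction % 1.0)


def build_dynamic_mesh(tracked: TrackedPointSet,
                       dims: tuple[int, int, int] = DEFAULT_GRID) -> DynamicMesh:
    """Interpolate the dynamic 3D mesh from a canonical tracked point set.

    Periodic cubic splines close each contour in theta and the cycle in
    time; a cubic spline spans the slice levels in z.  The mesh passes
    through every control point exactly at the control angles, slice
    fractions and tracked frames.
    """
    n_t, n_theta, n_z = dims
    if tracked.n_frames < 3:
        raise GeometryError("insufficient temporal sampling: need >= 3 frames")
    tracked.validate()
    _check_simple_polygons(tracked)
    angles = tracked.angles()
    fracs = tracked.slice_fractions()
    tf = tracked.time_fractions

    times = np.arange(n_t) / n_t
    theta = np.arange(n_theta) * 360.0 / n_theta
    zf = np.linspace(fracs[0], fracs[-1], n_z)

    surfaces = {}
    ctrl = {}
    for b in ("endo", "epi"):
        arr = tracked.control_array(b)  # (F, S, 12, 3)
        ctrl[b] = arr
        on_theta = _periodic_theta_spline(arr, angles)(theta)  # (F, S, TH, 3)
        on_z = CubicSpline(fracs, on_theta, axis=1)(zf)        # (F, Z, TH, 3)
        surfaces[b] = _periodic_time_spline(on_z, tf)(times)   # (T, Z, TH, 3)

    return DynamicMesh(endo=surfaces["endo"], epi=surfaces["epi"],
                       time_fractions=times, theta_deg=theta, z_fractions=zf,
                       subject_id=tracked.subject_id, _ctrl=ctrl,
                       _ctrl_angles=np.asarray(angles, dtype=float),
                       _ctrl_fracs=np.asarray(fracs, dtype=float),
                       _ctrl_times=np.asarray(tf, dtype=float))


def mesh_to_table(mesh: DynamicMesh):
    """Flatten mesh node coordinates to a long-format DataFrame."""
    import pandas as pd

    n_t, n_z, n_th = mesh.shape
    rows = []
    for surf in ("endo", "epi"):
        arr = mesh.surface(surf)
        ti, zi, hi = np.meshgrid(np.arange(n_t), np.arange(n_z),
                                 np.arange(n_th), indexing="ij")
        rows.append(pd.DataFrame({
            "t_index": ti.ravel(), "theta_index": hi.ravel(),
            "z_index": zi.ravel(), "surface": surf,
            "x": arr[..., 0].ravel(), "y": arr[..., 1].ravel(),
            "z": arr[..., 2].ravel()}))
    return pd.concat(rows, ignore_index=True)
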