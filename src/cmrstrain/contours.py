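"""Tracked left-ventricular contour point sets.

The carrier of a feature-tracking result: for every cine frame, endocardial
and epicardial control points sampled at fixed rotational angles on a small
number of short-axis slices, together with the tracked apex/base positions
along the longitudinal axis.  The canonical layout is 12 angular positions
(30 deg apart) on 4 slices per boundary -- 48 control points per boundary
per frame.

Coordinates are millimetres.  ``apex_z``/``base_z`` are the projections of
the tracked apex/base onto the longitudinal-axis direction; in an aligned
point set that direction is +z and the apex sits at z = 0 at end-diastole.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

CANONICAL_ANGLES_DEG = tuple(float(a) for a in range(0, 360, 30))
CANONICAL_SLICE_FRACTIONS = (0.25, 0.50, 0.75, 1.00)
N_ANGLES = 12


class ContourError(ValueError):
    """Raised for structurally invalid tracked point sets."""


@dataclass
class SliceContour:
    """Endo/epi control points of one short-axis slice at one frame."""

    slice_fraction: float
    angles_deg: np.ndarray  # (12,) strictly increasing, in [0, 360)
    endo: np.ndarray        # (12, 3) mm
    epi: np.ndarray         # (12, 3) mm

    def __post_init__(self) -> None:
        self.angles_deg = np.asarray(self.angles_deg, dtype=float)
        self.endo = np.asarray(self.endo, dtype=float)
        self.epi = np.asarray(self.epi, dtype=float)

    def copy(self) -> "SliceContour":
        return SliceContour(self.slice_fraction, self.angles_deg.copy(),
                            self.endo.copy(), self.epi.copy())


@dataclass
class Frame:
    """One cardiac phase: tracked slices plus apex/base axis positions."""

    time_fraction: float
    apex_z: float
    base_z: float
    slices: list[SliceContour] = field(default_factory=list)

    def copy(self) -> "Frame":
        return Frame(self.time_fraction, self.apex_z, self.base_z,
                     [s.copy() for s in self.slices])


@dataclass
class TrackedPointSet:
    """A full cardiac cycle of tracked endo/epi control points."""

    subject_id: str
    frames: list[Frame] = field(default_factory=list)

    # ------------------------------------------------------------------
    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def time_fractions(self) -> np.ndarray:
        return np.array([f.time_fraction for f in self.frames])

    def copy(self) -> "TrackedPointSet":
        return TrackedPointSet(self.subject_id, [f.copy() for f in self.frames])

    # ------------------------------------------------------------------
    def validate(self) -> None:
        """Check the structural invariants; raise :class:`ContourError`."""
        if self.n_frames < 3:
            raise ContourError("need at least 3 frames, got %d" % self.n_frames)
        tf = self.time_fractions
        if not (np.all(np.diff(tf) > 0) and tf[0] == 0.0 and np.all(tf < 1.0)):
            raise ContourError("time fractions must start at 0, be strictly "
                               "increasing and lie in [0, 1)")
        for i, fr in enumerate(self.frames):
            if not np.isfinite([fr.apex_z, fr.base_z]).all():
                raise ContourError(f"/frames/{i}: non-finite apex/base position")
            if not fr.apex_z < fr.base_z:
                raise ContourError(f"/frames/{i}: apex_z must be below base_z")
            if len(fr.slices) < 3:
                raise ContourError(f"/frames/{i}: need at least 3 slices")
            for j, sl in enumerate(fr.slices):
                loc = f"/frames/{i}/slices/{j}"
                if sl.angles_deg.shape != (N_ANGLES,):
                    raise ContourError(f"{loc}: expected {N_ANGLES} angular "
                                       f"positions, got {sl.angles_deg.shape}")
                a = sl.angles_deg
                if not (np.all(np.diff(a) > 0) and a[0] >= 0 and a[-1] < 360):
                    raise ContourError(f"{loc}: angles must be strictly "
                                       "increasing in [0, 360)")
                for name, pts in (("endo", sl.endo), ("epi", sl.epi)):
                    if pts.shape != (N_ANGLES, 3):
                        raise ContourError(f"{loc}/{name}: expected shape "
                                           f"({N_ANGLES}, 3), got {pts.shape}")
                    if not np.isfinite(pts).all():
                        raise ContourError(f"{loc}/{name}: non-finite coordinate")

    def is_canonical(self) -> bool:
        """True when every frame has the 4 canonical slice fractions."""
        for fr in self.frames:
            fracs = [s.slice_fraction for s in fr.slices]
            if len(fracs) != 4 or not np.allclose(
                    fracs, CANONICAL_SLICE_FRACTIONS, atol=1e-9):
                return False
        return True

    # ------------------------------------------------------------------
    def slice_fractions(self) -> np.ndarray:
        """Common per-frame slice fractions (must agree across frames)."""
        ref = np.array([s.slice_fraction for s in self.frames[0].slices])
        for i, fr in enumerate(self.frames[1:], start=1):
            fracs = np.array([s.slice_fraction for s in fr.slices])
            if fracs.shape != ref.shape or not np.allclose(fracs, ref):
                raise ContourError(f"/frames/{i}: slice fractions differ "
                                   "between frames")
        return ref

    def angles(self) -> np.ndarray:
        """Common angular grid (must agree across slices and frames)."""
        ref = self.frames[0].slices[0].angles_deg
        for i, fr in enumerate(self.frames):
            for j, sl in enumerate(fr.slices):
                if not np.allclose(sl.angles_deg, ref):
                    raise ContourError(f"/frames/{i}/slices/{j}: angular grid "
                                       "differs from frame 0")
        return ref

    def control_array(self, boundary: str) -> np.ndarray:
        """Stack control points to shape (n_frames, n_slices, 12, 3)."""
        if boundary not in ("endo", "epi"):
            raise ValueError("boundary must be 'endo' or 'epi'")
        return np.array([[getattr(s, boundary) for s in fr.slices]
                         for fr in self.frames])


# ----------------------------------------------------------------------
# rigid transforms


def rotation_matrix(axis: Sequence[float], angle_rad: float) -> np.ndarray:
    """Rodrigues rotation about ``axis`` by ``angle_rad``."""
    u = np.asarray(axis, dtype=float)
    u = u / np.linalg.norm(u)
    k = np.array([[0, -u[2], u[1]], [u[2], 0, -u[0]], [-u[1], u[0], 0]])
    return np.eye(3) + np.sin(angle_rad) * k + (1 - np.cos(angle_rad)) * k @ k


def _ed_axis_direction(tracked: TrackedPointSet) -> np.ndarray:
    """Unit apex->base direction from the end-diastolic endo centroids."""
    fr = tracked.frames[0]
    order = np.argsort([s.slice_fraction for s in fr.slices])
    lo = fr.slices[order[0]].endo.mean(axis=0)
    hi = fr.slices[order[-1]].endo.mean(axis=0)
    d = hi - lo
    n = np.linalg.norm(d)
    if n < 1e-9:
        raise ContourError("degenerate geometry: apical and basal slice "
                           "centroids coincide; axis is not orientable")
    return d / n


def transform_rigid(tracked: TrackedPointSet, rotation: np.ndarray,
                    translation: Sequence[float]) -> TrackedPointSet:
    """Apply one global rigid transform x -> R x + t to every frame.

    ``apex_z``/``base_z`` are axis projections, so they shift by the
    translation component along the transformed longitudinal axis.
    """
    rotation = np.asarray(rotation, dtype=float)
    t = np.asarray(translation, dtype=float)
    u_new = rotation @ _ed_axis_direction(tracked)
    dz = float(u_new @ t)
    out = tracked.copy()
    for fr in out.frames:
        fr.apex_z += dz
        fr.base_z += dz
        for sl in fr.slices:
            sl.endo = sl.endo @ rotation.T + t
            sl.epi = sl.epi @ rotation.T + t
    return out
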