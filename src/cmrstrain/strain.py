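"""Localized left-ventricular strain measures on the dynamic mesh.

Four scalar strain measures, all referenced to end-diastole (t = 0) and
reported in percent:

* ``Ecc`` -- circumferential Green-Lagrange strain of a short-axis slice:
  ``0.5 * [(C(z,t)/C_D(z))^2 - 1] * 100`` where C is the arc length of the
  closed contour at slice z and C_D its end-diastolic value.
* ``Ell`` -- longitudinal engineering strain of the apex-to-base meridian
  at rotation theta: ``(L - L_D)/L_D * 100``.
* ``Err`` -- radial engineering strain of the wall thickness, the in-plane
  endo-to-epi distance at a (z, theta) node: ``(R - R_D)/R_D * 100``
  (positive during systolic thickening).
* ``Ea`` -- endocardial surface-area strain of the quad patch between
  adjacent slices and rotations: ``(A - A_D)/A_D * 100``.

Region strain curves are unweighted means over the selected nodes at each
time point; peak strain and systolic / early- and late-diastolic strain
rates are extracted from each curve.  Strain rates are least-squares
slopes in percent per frame, one frame being 1/60 of the cardiac cycle.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline

from .geometry import DynamicMesh
from .regions import LEVELS, SECTORS, RegionSpec

FRAMES_PER_CYCLE = 60  # strain-rate unit: % per 1/60-cycle frame

STRAIN_KINDS = ("ecc", "ell", "err", "ea")

#: Samples per spline interval when measuring arc lengths densely.
_DENSE_PER_INTERVAL = 12

#: Moving-window width (frames of the curve grid) for the early-diastolic
#: strain-rate search.
EARLY_DIASTOLE_WINDOW = 5

#: Minimum admissible end-diastolic wall thickness (mm) before Err flags a
#: tracking/geometry fault.
MIN_WALL_THICKNESS_MM = 0.5


class StrainError(ValueError):
    """Raised for degenerate geometry or corrupt strain curves."""


# ----------------------------------------------------------------------
# geometric primitives


def _closed_arc_lengths(nodes: np.ndarray, theta_deg: np.ndarray) -> np.ndarray:
    """Arc length of the closed theta-spline through grid nodes.

    ``nodes`` has shape (..., Theta, 3); returns shape (...).  The spline
    is sampled densely and summed as a polyline (relative error O(h^2),
    ~1e-6 at the default grid).
    """
    x = np.append(theta_deg, theta_deg[0] + 360.0)
    y = np.concatenate([nodes, nodes[..., :1, :]], axis=-2)
    spl = CubicSpline(x, y, axis=nodes.ndim - 2, bc_type="periodic")
    dense = np.linspace(x[0], x[-1], len(theta_deg) * _DENSE_PER_INTERVAL + 1)
    pts = spl(dense)  # (..., dense, 3)
    return np.sqrt(((np.diff(pts, axis=-2)) ** 2).sum(-1)).sum(-1)


def _meridian_arc_lengths(nodes: np.ndarray, z_fractions: np.ndarray) -> np.ndarray:
    """Arc length of the open z-spline through grid nodes (..., Z, 3)."""
    spl = CubicSpline(z_fractions, nodes, axis=nodes.ndim - 2)
    dense = np.linspace(z_fractions[0], z_fractions[-1],
                        len(z_fractions) * _DENSE_PER_INTERVAL + 1)
    pts = spl(dense)  # (..., dense, 3)
    return np.sqrt(((np.diff(pts, axis=-2)) ** 2).sum(-1)).sum(-1)


def _patch_areas(endo: np.ndarray) -> np.ndarray:
    """Endocardial quad-patch areas, shape (T, Z-1, Theta) with theta wrap.

    Each quad (z, theta)-(z+1, theta)-(z+1, theta+1)-(z, theta+1) is split
    into two triangles along the (z, theta)-(z+1, theta+1) diagonal.
    """
    p00 = endo[:, :-1, :, :]
    p10 = endo[:, 1:, :, :]
    p01 = np.roll(endo, -1, axis=2)[:, :-1, :, :]
    p11 = np.roll(endo, -1, axis=2)[:, 1:, :, :]

    def tri(a, b, c):
        return 0.5 * np.linalg.norm(np.cross(b - a, c - a), axis=-1)

    return tri(p00, p10, p11) + tri(p00, p11, p01)


# ----------------------------------------------------------------------
# strain fields


@dataclass
class StrainField:
    """One strain measure evaluated over time and location.

    ``values`` (%) has shape (T, Z) for Ecc, (T, Theta) for Ell,
    (T, Z, Theta) for Err and (T, Z-1, Theta) for Ea; ``reference`` holds
    the end-diastolic geometric quantity (C_D, L_D, R_D or A_D) on the
    spatial grid.  Ea patches are indexed by the lower of the two slice
    indices they span.
    """

    kind: str
    values: np.ndarray
    reference: np.ndarray
    time_fractions: np.ndarray
    theta_deg: np.ndarray
    z_fractions: np.ndarray
    boundary: str = "endo"

    @property
    def n_z(self) -> int:
        """Extent of the z axis of the field (Z, or Z-1 for Ea)."""
        if self.kind == "ell":
            return 0
        return self.values.shape[1]

    def region_mask(self, spec: RegionSpec, scheme: str, label) -> np.ndarray:
        """Boolean mask over the field's spatial axes for one region."""
        if scheme == "level":
            sel = spec.level_index == LEVELS.index(label)
            if self.kind == "ecc":
                return sel
            if self.kind == "ell":
                raise StrainError("Ell is localized by sector, not level")
            sel = sel[: self.values.shape[1]]  # Ea: lower-edge index
            return np.repeat(sel[:, None], len(self.theta_deg), axis=1)
        if scheme == "sector":
            sel = spec.sector_index == SECTORS.index(label)
            if self.kind == "ell":
                return sel
            if self.kind == "ecc":
                raise StrainError("Ecc is localized by level, not sector")
            return np.repeat(sel[None, :], self.values.shape[1], axis=0)
        if scheme == "aha":
            if self.kind in ("ecc", "ell"):
                raise StrainError(f"{self.kind} is not a nodal (z, theta) field")
            return spec.aha_mask(label)[: self.values.shape[1]]
        raise ValueError(f"unknown region scheme {scheme!r}")

    def node_values(self, t_index: int) -> np.ndarray:
        return self.values[t_index]


def compute_strain_field(mesh: DynamicMesh, kind: str,
                         boundary: str = "endo") -> StrainField:
    """Evaluate one strain measure over the whole mesh grid."""
    kind = kind.lower()
    if kind not in STRAIN_KINDS:
        raise ValueError(f"unknown strain kind {kind!r}")
    common = dict(time_fractions=mesh.time_fractions, theta_deg=mesh.theta_deg,
                  z_fractions=mesh.z_fractions, boundary=boundary)

    if kind == "ecc":
        circ = _closed_arc_lengths(
            np.moveaxis(mesh.surface(boundary), 2, -2), mesh.theta_deg)
        ref = circ[0]
        if np.any(ref <= 0):
            raise StrainError("degenerate slice: non-positive end-diastolic "
                              "circumference")
        values = 0.5 * ((circ / ref) ** 2 - 1.0) * 100.0
    elif kind == "ell":
        nodes = np.moveaxis(mesh.surface(boundary), 1, 2)  # (T, TH, Z, 3)
        length = _meridian_arc_lengths(nodes, mesh.z_fractions)
        ref = length[0]
        if np.any(ref <= 0):
            raise StrainError("degenerate meridian: zero end-diastolic length")
        values = (length - ref) / ref * 100.0
    elif kind == "err":
        d = mesh.endo[..., :2] - mesh.epi[..., :2]  # in-plane distance
        r = np.sqrt((d ** 2).sum(-1))
        ref = r[0]
        if np.any(ref < MIN_WALL_THICKNESS_MM):
            raise StrainError("end-diastolic wall thickness below "
                              f"{MIN_WALL_THICKNESS_MM} mm: tracking or "
                              "geometry fault")
        values = (r - ref) / ref * 100.0
    else:  # ea
        area = _patch_areas(mesh.endo)
        ref = area[0]
        if np.any(ref <= 0):
            raise StrainError("degenerate mesh: zero-area reference patch")
        values = (area - ref) / ref * 100.0

    return StrainField(kind=kind, values=values, reference=ref, **common)


# single-location accessors --------------------------------------------


def circumferential_strain(mesh: DynamicMesh, boundary: str, z_index: int,
                           t_index: int) -> float:
    """Ecc (%) of one slice at one time point."""
    return float(compute_strain_field(mesh, "ecc", boundary)
                 .values[t_index, z_index])


def longitudinal_strain(mesh: DynamicMesh, boundary: str, theta_index: int,
                        t_index: int) -> float:
    """Ell (%) of one meridian at one time point."""
    return float(compute_strain_field(mesh, "ell", boundary)
                 .values[t_index, theta_index])


def radial_strain(mesh: DynamicMesh, z_index: int, theta_index: int,
                  t_index: int) -> float:
    """Err (%) of one wall column at one time point."""
    return float(compute_strain_field(mesh, "err")
                 .values[t_index, z_index, theta_index])


def surface_area_strain(mesh: DynamicMesh, z_index: int, theta_index: int,
                        t_index: int) -> float:
    """Ea (%) of one endocardial patch at one time point."""
    return float(compute_strain_field(mesh, "ea")
                 .values[t_index, z_index, theta_index])


# ----------------------------------------------------------------------
# strain curves and metrics


@dataclass
class StrainCurve:
    """Region-aggregated strain versus normalized cycle time."""

    region_label: str
    time_fractions: np.ndarray
    values: np.ndarray  # (%)
    kind: str = ""
    metrics: dict = field(default_factory=dict)


def strain_curve(strain_field: StrainField, mask: np.ndarray,
                 region_label: str = "") -> StrainCurve:
    """Average a strain field over a region at every time point."""
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != strain_field.values.shape[1:]:
        raise StrainError(f"region mask shape {mask.shape} does not match "
                          f"field grid {strain_field.values.shape[1:]}")
    if not mask.any():
        raise StrainError("empty region selector")
    values = strain_field.values[:, mask].mean(axis=1)
    curve = StrainCurve(region_label=region_label,
                        time_fractions=strain_field.time_fractions,
                        values=values, kind=strain_field.kind)
    curve.metrics = curve_metrics(curve)
    return curve


def _lsq_slope(x: np.ndarray, y: np.ndarray) -> float:
    x = x - x.mean()
    return float((x @ (y - y.mean())) / (x @ x))


def curve_metrics(curve: StrainCurve) -> dict:
    """Peak strain and strain rates of one region strain curve.

    * ``peak_strain``: signed extremum of largest magnitude (first frame
      on ties); a flat curve has peak 0 at frame 0 and all rates 0.
    * ``systolic_strain_rate``: least-squares slope from frame 0 to the
      peak frame.
    * ``early_diastolic_strain_rate``: steepest opposite-sign slope over a
      moving window of :data:`EARLY_DIASTOLE_WINDOW` frames located after
      the peak and within the first three quarters of the cycle.
    * ``late_diastolic_strain_rate``: least-squares slope over the final
      quarter of the cycle.

    Rates are % per frame where one frame is 1/60 of the cardiac cycle,
    independent of the curve's own sampling.
    """
    v = np.asarray(curve.values, dtype=float)
    if not np.isfinite(v).all():
        raise StrainError("corrupt strain curve: non-finite values")
    n = len(v)
    if n < 8:
        raise StrainError("strain curve too short: need >= 8 samples")
    frames = curve.time_fractions * FRAMES_PER_CYCLE

    peak_idx = int(np.argmax(np.abs(v)))
    peak = float(v[peak_idx])
    out = {"peak_strain": peak,
           "peak_time_fraction": float(curve.time_fractions[peak_idx]),
           "systolic_strain_rate": 0.0,
           "early_diastolic_strain_rate": 0.0,
           "late_diastolic_strain_rate": 0.0}
    if peak_idx == 0:
        return out

    out["systolic_strain_rate"] = _lsq_slope(frames[:peak_idx + 1],
                                             v[:peak_idx + 1])

    w = EARLY_DIASTOLE_WINDOW
    last = int(np.floor(0.75 * n))
    sign = np.sign(peak)
    best = 0.0
    for s in range(peak_idx + 1, last - w + 2):
        slope = _lsq_slope(frames[s:s + w], v[s:s + w])
        if slope * sign < 0 and abs(slope) > abs(best):
            best = slope
    out["early_diastolic_strain_rate"] = best

    n_late = int(round(0.25 * n))
    if n_late >= 2:
        out["late_diastolic_strain_rate"] = _lsq_slope(frames[-n_late:],
                                                       v[-n_late:])
    return out


def global_metric(regional_values=None, mode: str = "region-mean",
                  strain_field: StrainField | None = None,
                  metric: str = "peak_strain") -> float:
    """Global strain metric, by region averaging or node averaging.

    ``region-mean``: arithmetic mean of the supplied regional metric
    values.  ``node-mean-at-peak``: mean over all nodes of the field at
    the time its all-node mean curve peaks (the convention used for
    global Ea).
    """
    if mode == "region-mean":
        vals = np.asarray(list(regional_values), dtype=float)
        if vals.size == 0:
            raise ValueError("no regional values supplied")
        return float(vals.mean())
    if mode == "node-mean-at-peak":
        if strain_field is None:
            raise ValueError("node-mean-at-peak requires a strain field")
        mean_curve = strain_field.values.reshape(
            len(strain_field.time_fractions), -1).mean(axis=1)
        return float(mean_curve[int(np.argmax(np.abs(mean_curve)))])
    raise ValueError(f"unknown mode {mode!r}")


# ----------------------------------------------------------------------
# per-subject regional analysis


def regional_curves(strain_field: StrainField, spec: RegionSpec) -> dict[str, StrainCurve]:
    """Strain curves for the natural regions of one strain kind.

    Ecc, Err and Ea are localized by slice level, Ell by wall sector
    (the localization each measure's spatial domain supports).
    """
    labels = SECTORS if strain_field.kind == "ell" else LEVELS
    scheme = "sector" if strain_field.kind == "ell" else "level"
    return {lab: strain_curve(strain_field,
                              strain_field.region_mask(spec, scheme, lab), lab)
            for lab in labels}


def analyze_mesh(mesh: DynamicMesh, kinds=STRAIN_KINDS,
                 boundary: str = "endo",
                 apex_cap_fraction: float | None = None) -> dict:
    """Strain fields, regional curves and metrics for one subject.

    Returns ``{kind: {"field": StrainField, "curves": {region: curve},
    "global": {...}}}``; the global record carries the region-mean peak
    and strain rates plus the node-mean-at-peak value for nodal fields.
    """
    kwargs = {} if apex_cap_fraction is None else {
        "apex_cap_fraction": apex_cap_fraction}
    spec = RegionSpec(len(mesh.z_fractions), mesh.theta_deg, **kwargs)
    out = {}
    for kind in kinds:
        f = compute_strain_field(mesh, kind, boundary=boundary)
        curves = regional_curves(f, spec)
        glob = {m: global_metric([c.metrics[m] for c in curves.values()])
                for m in ("peak_strain", "systolic_strain_rate",
                          "early_diastolic_strain_rate",
                          "late_diastolic_strain_rate")}
        if kind in ("err", "ea"):
            glob["node_mean_at_peak"] = global_metric(
                mode="node-mean-at-peak", strain_field=f)
        out[kind] = {"field": f, "curves": curves, "global": glob,
                     "region_spec": spec}
    return out
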