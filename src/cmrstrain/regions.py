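"""Slice-level, rotational-sector and AHA 17-segment assignment.

Conventions (fixed throughout the package):

* z index 0 is the most apical mesh slice, index Z-1 the most basal;
  slice levels are equal thirds of the z grid (apical / mid / basal).
* theta = 0 deg is the anterior reference direction, increasing
  counterclockwise viewed from apex toward base.  The six 60-deg wall
  sectors, in increasing theta from 0: anterior, anterior septum,
  posterior septum, posterior, posterior free wall, anterior free wall.
* AHA segments: basal 1-6 and mid 7-12 follow the sector order above
  (1 = basal anterior at theta in [0, 60)); the apical level splits into
  four 90-deg segments 13-16 anchored at theta = 0 (anterior, septal,
  inferior, lateral); the apical cap (most apical 5 % of the z grid by
  default) is segment 17.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

LEVELS = ("apical", "mid", "basal")

SECTORS = ("anterior", "anterior_septum", "posterior_septum",
           "posterior", "posterior_free_wall", "anterior_free_wall")

AHA_SEGMENT_NAMES = {
    1: "basal anterior", 2: "basal anteroseptal", 3: "basal inferoseptal",
    4: "basal inferior", 5: "basal inferolateral", 6: "basal anterolateral",
    7: "mid anterior", 8: "mid anteroseptal", 9: "mid inferoseptal",
    10: "mid inferior", 11: "mid inferolateral", 12: "mid anterolateral",
    13: "apical anterior", 14: "apical septal", 15: "apical inferior",
    16: "apical lateral", 17: "apex",
}

DEFAULT_APEX_CAP_FRACTION = 0.05


def slice_level(z_index: int, n_z: int) -> str:
    """Level label for a z grid index (0 = apex ... n_z-1 = base)."""
    if not 0 <= z_index < n_z:
        raise IndexError(f"z_index {z_index} out of range for Z={n_z}")
    return LEVELS[min(2, 3 * z_index // n_z)]


def rotational_sector(theta_deg: float) -> str:
    """Wall-sector label for an angular position (normalized mod 360)."""
    return SECTORS[int((theta_deg % 360.0) // 60.0)]


def aha17_segment(z_index: int, theta_deg: float, n_z: int,
                  apex_cap_fraction: float = DEFAULT_APEX_CAP_FRACTION) -> int:
    """AHA 17-segment id for a mesh node."""
    if not 0 <= z_index < n_z:
        raise IndexError(f"z_index {z_index} out of range for Z={n_z}")
    n_cap = max(1, int(np.ceil(apex_cap_fraction * n_z)))
    if z_index < n_cap:
        return 17
    level = slice_level(z_index, n_z)
    theta = theta_deg % 360.0
    if level == "basal":
        return 1 + int(theta // 60.0)
    if level == "mid":
        return 7 + int(theta // 60.0)
    return 13 + int(theta // 90.0)


@dataclass
class RegionSpec:
    """Precomputed region assignments for a (Z, Theta) mesh grid."""

    n_z: int
    theta_deg: np.ndarray
    apex_cap_fraction: float = DEFAULT_APEX_CAP_FRACTION
    level_index: np.ndarray = field(init=False)   # (Z,) 0..2
    sector_index: np.ndarray = field(init=False)  # (Theta,) 0..5
    aha: np.ndarray = field(init=False)           # (Z, Theta) 1..17

    def __post_init__(self) -> None:
        self.theta_deg = np.asarray(self.theta_deg, dtype=float)
        self.level_index = np.array(
            [LEVELS.index(slice_level(z, self.n_z)) for z in range(self.n_z)])
        self.sector_index = np.array(
            [SECTORS.index(rotational_sector(t)) for t in self.theta_deg])
        self.aha = np.array(
            [[aha17_segment(z, t, self.n_z, self.apex_cap_fraction)
              for t in self.theta_deg] for z in range(self.n_z)])

    # boolean masks over the (Z, Theta) grid ---------------------------
    def level_mask(self, level: str) -> np.ndarray:
        sel = self.level_index == LEVELS.index(level)
        return np.repeat(sel[:, None], len(self.theta_deg), axis=1)

    def sector_mask(self, sector: str) -> np.ndarray:
        sel = self.sector_index == SECTORS.index(sector)
        return np.repeat(sel[None, :], self.n_z, axis=0)

    def aha_mask(self, segment_id: int) -> np.ndarray:
        return self.aha == segment_id


def bullseye_table(values: np.ndarray, spec: RegionSpec) -> pd.DataFrame:
    """Per-AHA-segment unweighted means of a nodal (Z, Theta) field."""
    values = np.asarray(values, dtype=float)
    if values.shape != spec.aha.shape:
        raise ValueError(f"field shape {values.shape} does not match the "
                         f"region grid {spec.aha.shape}")
    rows = []
    for seg in range(1, 18):
        mask = spec.aha_mask(seg)
        if not mask.any():
            raise ValueError(f"AHA segment {seg} is empty on this grid")
        rows.append({"segment_id": seg,
                     "segment_name": AHA_SEGMENT_NAMES[seg],
                     "value": float(values[mask].mean())})
    return pd.DataFrame(rows)


def bullseye_plot(table: pd.DataFrame, path, title: str = "",
                  cmap: str = "RdBu_r") -> None:
    """Render a standard 17-segment polar map to an image file."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    vals = table.set_index("segment_id")["value"]
    fig, ax = plt.subplots(subplot_kw={"projection": "polar"},
                           figsize=(5, 5))
    norm = plt.Normalize(vals.min(), vals.max())
    sm = plt.cm.ScalarMappable(norm=norm, cmap=cmap)
    rings = [  # (segment ids, inner radius, outer radius, sector span deg)
        (range(1, 7), 0.75, 1.0, 60),
        (range(7, 13), 0.5, 0.75, 60),
        (range(13, 17), 0.25, 0.5, 90),
    ]
    for segs, r0, r1, span in rings:
        for i, seg in enumerate(segs):
            th = np.deg2rad(np.linspace(i * span, (i + 1) * span, 32))
            ax.fill_between(th, r0, r1, color=sm.to_rgba(vals[seg]))
    th = np.linspace(0, 2 * np.pi, 64)
    ax.fill_between(th, 0.0, 0.25, color=sm.to_rgba(vals[17]))
    ax.set_xticks([])
    ax.set_yticks([])
    ax.set_title(title)
    fig.colorbar(sm, ax=ax, shrink=0.7)
    fig.savefig(path, dpi=120)
    plt.close(fig)
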