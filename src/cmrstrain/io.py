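"""Exchange formats: contour JSON, cine-stack metadata, result reports.

The contour exchange format (versioned, units mm)::

    {
      "format": "cmrstrain-contours",
      "version": "1.0",
      "subject_id": "...",
      "frames": [
        {"time_fraction": 0.0, "apex_z": 0.0, "base_z": 80.0,
         "slices": [
           {"slice_fraction": 0.25,
            "angles_deg": [... 12 ...],
            "endo": [[x, y, z] x 12],
            "epi":  [[x, y, z] x 12]}, ...]}, ...]
    }

Validation errors carry JSON-pointer-style paths.  Numeric fields
round-trip bit-exactly (shortest-repr JSON floats).
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .contours import ContourError, Frame, SliceContour, TrackedPointSet

FORMAT_NAME = "cmrstrain-contours"
SCHEMA_VERSION = "1.0"

log = logging.getLogger("cmrstrain")


# ----------------------------------------------------------------------
# contour JSON


def write_contours(tracked: TrackedPointSet, path) -> None:
    doc = {
        "format": FORMAT_NAME,
        "version": SCHEMA_VERSION,
        "subject_id": tracked.subject_id,
        "frames": [
            {"time_fraction": fr.time_fraction,
             "apex_z": fr.apex_z, "base_z": fr.base_z,
             "slices": [
                 {"slice_fraction": sl.slice_fraction,
                  "angles_deg": sl.angles_deg.tolist(),
                  "endo": sl.endo.tolist(),
                  "epi": sl.epi.tolist()}
                 for sl in fr.slices]}
            for fr in tracked.frames],
    }
    Path(path).write_text(json.dumps(doc, indent=1))


def _require(doc: dict, key: str, where: str):
    if key not in doc:
        raise ContourError(f"{where}/{key}: missing required field")
    return doc[key]


def read_contours(path) -> TrackedPointSet:
    """Read and validate a contour JSON file."""
    try:
        doc = json.loads(Path(path).read_text())
    except json.JSONDecodeError as e:
        raise ContourError(f"malformed JSON in {path}: {e}") from e
    if doc.get("format") != FORMAT_NAME:
        raise ContourError(f"/format: expected {FORMAT_NAME!r}, "
                           f"got {doc.get('format')!r}")
    if doc.get("version") != SCHEMA_VERSION:
        raise ContourError(f"/version: unsupported version "
                           f"{doc.get('version')!r}")
    tracked = TrackedPointSet(str(_require(doc, "subject_id", "")), [])
    for i, fdoc in enumerate(_require(doc, "frames", "")):
        where = f"/frames/{i}"
        fr = Frame(float(_require(fdoc, "time_fraction", where)),
                   float(_require(fdoc, "apex_z", where)),
                   float(_require(fdoc, "base_z", where)), [])
        for j, sdoc in enumerate(_require(fdoc, "slices", where)):
            sw = f"{where}/slices/{j}"
            sl = SliceContour(
                float(_require(sdoc, "slice_fraction", sw)),
                np.asarray(_require(sdoc, "angles_deg", sw), dtype=float),
                np.asarray(_require(sdoc, "endo", sw), dtype=float),
                np.asarray(_require(sdoc, "epi", sw), dtype=float))
            fr.slices.append(sl)
        tracked.frames.append(fr)
    tracked.validate()  # raises ContourError with pointer paths
    return tracked


# ----------------------------------------------------------------------
# cine-stack geometry metadata


@dataclass
class CineGeometry:
    """Geometry metadata of a short-axis cine stack."""

    slice_positions_mm: np.ndarray  # sorted, one per slice
    pixel_spacing_mm: tuple         # (row, col)
    time_fractions: np.ndarray      # per-frame, uniform or trigger-derived
    n_frames_per_slice: int


def _read_dicom_dir(directory: Path) -> CineGeometry:
    import pydicom

    records = []
    orientations = set()
    for f in sorted(directory.iterdir()):
        if f.suffix.lower() not in (".dcm", ".ima"):
            continue
        ds = pydicom.dcmread(f, stop_before_pixels=True)
        if "ImageOrientationPatient" in ds:
            orientations.add(tuple(round(float(v), 4)
                                   for v in ds.ImageOrientationPatient))
        if "SliceLocation" in ds:
            z = float(ds.SliceLocation)
        elif "ImagePositionPatient" in ds:
            z = float(ds.ImagePositionPatient[2])
        else:
            raise ValueError(f"{f.name}: no slice position tag")
        if "TriggerTime" not in ds:
            raise ValueError(f"{f.name}: missing TriggerTime tag")
        spacing = tuple(float(v) for v in ds.PixelSpacing)
        records.append((z, float(ds.TriggerTime), spacing))
    if not records:
        raise ValueError(f"no DICOM files found in {directory}")
    if len(orientations) > 1:
        raise ValueError("mixed image orientations in cine stack")

    df = pd.DataFrame(records, columns=["z", "trigger", "spacing"])
    df = df.sort_values(["z", "trigger"]).reset_index(drop=True)
    counts = df.groupby("z").size()
    if counts.nunique() != 1:
        bad = counts[counts != counts.mode()[0]]
        raise ValueError("inconsistent frame count: slice at z="
                         f"{bad.index[0]} has {bad.iloc[0]} frames, "
                         f"expected {counts.mode()[0]}")
    n_frames = int(counts.iloc[0])
    triggers = np.sort(df["trigger"].unique())
    rr = triggers[-1] + (triggers[1] - triggers[0] if len(triggers) > 1 else 1.0)
    return CineGeometry(
        slice_positions_mm=np.sort(df["z"].unique()),
        pixel_spacing_mm=df["spacing"].iloc[0],
        time_fractions=triggers / rr,
        n_frames_per_slice=n_frames)


def _read_sidecar(path: Path) -> CineGeometry:
    doc = json.loads(path.read_text())
    for key in ("slice_positions_mm", "pixel_spacing_mm", "time_fractions"):
        if key not in doc:
            raise ValueError(f"sidecar {path}: missing {key!r}")
    tf = np.asarray(doc["time_fractions"], dtype=float)
    return CineGeometry(
        slice_positions_mm=np.sort(np.asarray(doc["slice_positions_mm"],
                                              dtype=float)),
        pixel_spacing_mm=tuple(np.atleast_1d(doc["pixel_spacing_mm"])[:2])
        if np.ndim(doc["pixel_spacing_mm"]) else
        (float(doc["pixel_spacing_mm"]),) * 2,
        time_fractions=tf,
        n_frames_per_slice=len(tf))


def read_cine_metadata(path) -> CineGeometry:
    """Read stack geometry from a DICOM directory or a mask-stack sidecar.

    Slices are ordered by position, frames by trigger time; time
    fractions are trigger time over the RR interval (uniform spacing when
    only one frame or no RR is derivable).
    """
    path = Path(path)
    if path.is_file() and path.suffix == ".json":
        return _read_sidecar(path)
    if path.is_dir():
        sidecar = path / "sidecar.json"
        if sidecar.exists():
            return _read_sidecar(sidecar)
        return _read_dicom_dir(path)
    raise ValueError(f"{path}: not a DICOM directory or sidecar JSON")


def write_mask_stack(stack, outdir) -> None:
    """Write a rasterized mask stack as .npz + JSON sidecar."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    np.savez(outdir / "masks.npz", myocardium=stack.myocardium,
             cavity=stack.cavity)
    sidecar = {
        "pixel_spacing_mm": stack.pixel_spacing_mm,
        "origin_xy_mm": list(stack.origin_xy_mm),
        "slice_positions_mm": stack.slice_positions_mm[0].tolist(),
        "slice_thickness_mm": stack.slice_thickness_mm,
        "time_fractions": stack.time_fractions.tolist(),
    }
    (outdir / "sidecar.json").write_text(json.dumps(sidecar, indent=1))


# ----------------------------------------------------------------------
# run configuration and reports


@dataclass
class RunConfig:
    """Serializable configuration of one analysis run."""

    input_path: str = ""
    outdir: str = "results"
    grid: tuple = (60, 60, 60)
    boundary: str = "endo"
    kinds: tuple = ("ecc", "ell", "err", "ea")
    apex_cap_fraction: float = 0.05
    seed: int = 0
    log_level: str = "INFO"

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        doc = json.loads(text)
        cfg = cls(**doc)
        cfg.grid = tuple(cfg.grid)
        cfg.kinds = tuple(cfg.kinds)
        return cfg


def curves_table(results: dict, subject_id: str) -> pd.DataFrame:
    """Long-format strain curves (subject, kind, region, time, value)."""
    rows = []
    for kind, res in results.items():
        for region, curve in res["curves"].items():
            for tf, val in zip(curve.time_fractions, curve.values):
                rows.append({"subject": subject_id, "kind": kind,
                             "region": region, "time_fraction": float(tf),
                             "value_pct": float(val)})
    return pd.DataFrame(rows)


def metrics_table(results: dict, subject_id: str) -> pd.DataFrame:
    """Per-region metric table (peak and strain rates, plus global row)."""
    rows = []
    for kind, res in results.items():
        for region, curve in res["curves"].items():
            m = curve.metrics
            rows.append({"subject": subject_id, "kind": kind, "region": region,
                         "peak_pct": m["peak_strain"],
                         "sr_sys": m["systolic_strain_rate"],
                         "sr_early": m["early_diastolic_strain_rate"],
                         "sr_late": m["late_diastolic_strain_rate"]})
        g = res["global"]
        rows.append({"subject": subject_id, "kind": kind, "region": "global",
                     "peak_pct": g["peak_strain"],
                     "sr_sys": g["systolic_strain_rate"],
                     "sr_early": g["early_diastolic_strain_rate"],
                     "sr_late": g["late_diastolic_strain_rate"]})
    return pd.DataFrame(rows)


def write_report(outdir, config: RunConfig, curves: pd.DataFrame | None = None,
                 metrics: pd.DataFrame | None = None,
                 bullseyes: dict | None = None,
                 stats_tables: dict | None = None) -> list[Path]:
    """Write result CSVs, a JSON run manifest and a log file.

    File contents are deterministic for fixed inputs (no timestamps).
    Empty inputs still produce header-only CSVs.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []

    def _csv(name: str, df: pd.DataFrame | None, columns):
        p = outdir / name
        if df is None:
            df = pd.DataFrame(columns=columns)
        df.to_csv(p, index=False)
        written.append(p)

    _csv("strain_curves.csv", curves,
         ["subject", "kind", "region", "time_fraction", "value_pct"])
    _csv("strain_metrics.csv", metrics,
         ["subject", "kind", "region", "peak_pct", "sr_sys", "sr_early",
          "sr_late"])
    for name, table in (bullseyes or {}).items():
        _csv(f"bullseye_{name}.csv", table,
             ["segment_id", "segment_name", "value"])
    for name, table in (stats_tables or {}).items():
        _csv(f"stats_{name}.csv", table, list(table.columns))

    from . import __version__
    manifest = {"config": json.loads(config.to_json()),
                "seed": config.seed,
                "package": "cmrstrain",
                "version": __version__,
                "outputs": sorted(p.name for p in written)}
    mpath = outdir / "manifest.json"
    mpath.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    written.append(mpath)

    logpath = outdir / "run.log"
    logpath.write_text("".join(f"wrote {p.name}\n" for p in written))
    written.append(logpath)
    return written
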