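"""Volume / landmark / mesh I/O, PII stripping, ROI cropping, export bundles.

Volumes are read through SimpleITK (NIfTI, MHA, or DICOM series) and
reoriented to a single internal axis convention on load, so every geometric
module works in one world frame.  DICOM metadata is stripped of personally
identifiable information with a whitelist: only geometry and modality
fields survive.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from pathlib import Path

import numpy as np
import SimpleITK as sitk

from . import __version__
from .volume import INVALID_HU, Volume, from_sitk, to_sitk

#: DICOM tags retained by strip_pii (geometry + modality only).
_DICOM_WHITELIST = {
    "0008|0060",  # Modality
    "0008|0070",  # Manufacturer
    "0018|0050",  # SliceThickness
    "0018|0060",  # KVP
    "0018|5100",  # PatientPosition (gantry geometry, not identity)
    "0020|0032",  # ImagePositionPatient
    "0020|0037",  # ImageOrientationPatient
    "0028|0002",  # SamplesPerPixel
    "0028|0010", "0028|0011",  # Rows, Columns
    "0028|0030",  # PixelSpacing
    "0028|0100", "0028|0101", "0028|0102", "0028|0103",  # bit depth
    "0028|1052", "0028|1053",  # RescaleIntercept / Slope
}

_WHITELIST_KEYWORDS = (
    "spacing", "origin", "direction", "orientation", "position",
    "modality", "rows", "columns", "bits", "rescale", "slice", "pixel",
    "dim", "manufacturer", "kvp",
)


def strip_pii(metadata) -> dict:
    """Remove all personally identifiable information from header metadata.

    Works on plain dicts (including SimpleITK "GGGG|EEEE" keyed metadata)
    and on pydicom Datasets.  A whitelist approach is used: anything that
    is not recognisably geometry or modality is dropped, so names, IDs,
    dates, institutions, physicians, addresses etc. can never leak through
    an unanticipated field.
    """
    try:
        import pydicom
        if isinstance(metadata, pydicom.Dataset):
            out = {}
            for elem in metadata:
                tag = f"{elem.tag.group:04x}|{elem.tag.element:04x}"
                if tag in _DICOM_WHITELIST:
                    out[tag] = str(elem.value)
            return out
    except ImportError:
        pass

    out = {}
    for key, value in dict(metadata).items():
        k = str(key).lower()
        if k in _DICOM_WHITELIST or key in _DICOM_WHITELIST:
            out[key] = value
        elif "|" not in str(key) and any(w in k for w in _WHITELIST_KEYWORDS):
            out[key] = value
    return out


def read_volume(path: str | Path) -> Volume:
    """Read a NIfTI / MHA file or a DICOM series directory, in HU.

    The volume is reoriented to the internal LPS-aligned axis convention;
    metadata is PII-stripped on ingest.
    """
    path = Path(path)
    try:
        if path.is_dir():
            reader = sitk.ImageSeriesReader()
            files = reader.GetGDCMSeriesFileNames(str(path))
            if not files:
                raise RuntimeError("no DICOM series found")
            reader.SetFileNames(files)
            img = reader.Execute()
        else:
            img = sitk.ReadImage(str(path))
    except RuntimeError as err:
        raise IOError(f"cannot read volume {path}: {err}") from err

    if img.GetDimension() != 3:
        raise IOError(f"{path}: expected a 3D volume, got {img.GetDimension()}D")
    direction = np.array(img.GetDirection()).reshape(3, 3)
    if abs(abs(np.linalg.det(direction)) - 1.0) > 1e-3:
        raise IOError(f"{path}: ambiguous orientation matrix")
    img = sitk.DICOMOrient(img, "LPS")

    meta = {k: img.GetMetaData(k) for k in img.GetMetaDataKeys()}
    vol = from_sitk(img, metadata=strip_pii(meta))
    vol.data = np.asarray(vol.data, dtype=np.float32)
    return vol


def write_volume(volume: Volume, path: str | Path):
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    sitk.WriteImage(to_sitk(volume), str(path))


def crop_roi(volume: Volume, center, side_mm: float = 10.0,
             invalid_value: float = INVALID_HU) -> Volume:
    """Cubic physical ROI of ``side_mm`` centered on a world point.

    Out-of-bounds voxels are padded with ``invalid_value`` (excluded later
    by the registration similarity mask).  Cropping an identical crop again
    returns the same volume.
    """
    center = np.asarray(center, dtype=float)
    if not volume.contains(center):
        raise ValueError(f"ROI center {center} outside the volume")
    half = side_mm / (2.0 * volume.spacing)
    c_idx = volume.world_to_index(center)
    start = np.round(c_idx - half).astype(int)
    size = np.round(side_mm / volume.spacing).astype(int)

    out = np.full(tuple(size), invalid_value, dtype=volume.data.dtype)
    src_lo = np.maximum(start, 0)
    src_hi = np.minimum(start + size, volume.shape)
    dst_lo = src_lo - start
    dst_hi = dst_lo + (src_hi - src_lo)
    if np.all(src_hi > src_lo):
        out[dst_lo[0]:dst_hi[0], dst_lo[1]:dst_hi[1], dst_lo[2]:dst_hi[2]] = \
            volume.data[src_lo[0]:src_hi[0], src_lo[1]:src_hi[1], src_lo[2]:src_hi[2]]
    origin = volume.index_to_world(start)
    return Volume(out, volume.spacing.copy(), origin, dict(volume.metadata))


# -- export bundle --------------------------------------------------------

def _checksum(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def export_bundle(results: dict, outdir: str | Path, formats=("json", "csv"),
                  input_files=None) -> list[Path]:
    """Write an analysis bundle directory.

    ``results`` may contain: "metrics" (MetricReport), "sections" (list of
    CrossSection), "contacts" (ElectrodeArray), "transform"
    (RigidTransform), "flags" (FlagReport), "meshes" (name -> trimesh),
    "coverage" (DataFrame).  Missing stages are marked as skipped in the
    manifest.  Every table is written as JSON and CSV (Parquet and Excel
    when those optional writers are available).
    """
    import pandas as pd

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    stages = {}

    def write_table(df: pd.DataFrame, name: str):
        if "csv" in formats:
            p = outdir / f"{name}.csv"
            df.to_csv(p, index=False)
            written.append(p)
        if "json" in formats:
            p = outdir / f"{name}.json"
            df.to_json(p, orient="records", indent=1)
            written.append(p)
        if "parquet" in formats:
            try:
                p = outdir / f"{name}.parquet"
                df.to_parquet(p)
                written.append(p)
            except ImportError:
                warnings.warn("parquet writer unavailable; skipped")
        if "xlsx" in formats:
            try:
                p = outdir / f"{name}.xlsx"
                df.to_excel(p, index=False)
                written.append(p)
            except ImportError:
                warnings.warn("excel writer unavailable; skipped")

    metrics = results.get("metrics")
    if metrics is not None:
        p = outdir / "metrics.json"
        p.write_text(json.dumps(metrics.to_dict(), indent=1))
        written.append(p)
        stages["metrics"] = "complete"
    else:
        stages["metrics"] = "skipped"

    sections = results.get("sections")
    if sections:
        from .metrics import local_metrics
        rows = []
        for s in sections:
            row = local_metrics(s)
            for name, pt in s.landmarks.items():
                row[f"{name}_x_mm"], row[f"{name}_y_mm"], row[f"{name}_z_mm"] = pt
            rows.append(row)
        write_table(pd.DataFrame(rows), "sections")
        stages["sections"] = "complete"
    else:
        stages["sections"] = "skipped"

    contacts = results.get("contacts")
    if contacts is not None:
        write_table(contacts.to_table(), "contacts")
        stages["contacts"] = "complete"
    else:
        stages["contacts"] = "skipped"

    transform = results.get("transform")
    if transform is not None:
        p = outdir / "transform.json"
        p.write_text(json.dumps({"matrix": transform.matrix.tolist(),
                                 "fixed_frame": transform.fixed_frame,
                                 "moving_frame": transform.moving_frame}, indent=1))
        written.append(p)
        stages["registration"] = "complete"
    else:
        stages["registration"] = "skipped"

    flags = results.get("flags")
    if flags is not None:
        p = outdir / "flags.json"
        p.write_text(json.dumps(flags.to_dict(), indent=1))
        written.append(p)
        stages["flags"] = "complete"
    else:
        stages["flags"] = "skipped"

    meshes = results.get("meshes") or {}
    for name, mesh in meshes.items():
        if mesh is None or len(getattr(mesh, "vertices", [])) == 0:
            continue
        p = outdir / f"{name}.stl"
        mesh.export(p)
        written.append(p)
    stages["meshes"] = "complete" if meshes else "skipped"

    coverage = results.get("coverage")
    if coverage is not None:
        write_table(coverage, "coverage")
        stages["coverage"] = "complete"
    else:
        stages["coverage"] = "skipped"

    manifest = {
        "pipeline_version": __version__,
        "stages": stages,
        "inputs": {str(p): _checksum(Path(p)) for p in (input_files or [])},
    }
    p = outdir / "manifest.json"
    p.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    written.append(p)
    return written


def read_landmarks(path: str | Path):
    from .pose import LandmarkSet
    return LandmarkSet.from_json(Path(path).read_text())


def write_landmarks(landmarks, path: str | Path):
    Path(path).write_text(landmarks.to_json())
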