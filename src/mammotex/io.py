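"""File formats: images + manifest CSV, feature tables, reports.

Images are written as 16-bit grayscale TIFF with binary PNG masks and a
manifest CSV (one row per image: path, subject_id, laterality, view,
thickness_mm, kV_proxy, mAs_proxy, pixel_spacing_mm, mask_path).
Tabular artifacts are CSV with a one-line schema header comment
(``# mammotex-csv v1 kind=...``); readers reject unknown schema versions
and name the offending column on schema mismatch.
"""

from __future__ import annotations

import hashlib
import json
import os
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .records import ImageRecord

__all__ = [
    "write_image_records",
    "read_manifest",
    "write_table",
    "read_table",
    "write_provenance",
]

SCHEMA_VERSION = 1

MANIFEST_COLUMNS = [
    "path",
    "subject_id",
    "laterality",
    "view",
    "thickness_mm",
    "kV_proxy",
    "mAs_proxy",
    "pixel_spacing_mm",
    "mask_path",
]


def write_image_records(
    records: list[ImageRecord], out_dir: str | Path, prefix: str = "img"
) -> Path:
    """Write images as 16-bit TIFF plus masks and a manifest CSV.

    Returns the manifest path.  Intensities are rounded to integers and
    clipped to the 16-bit range.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, rec in enumerate(records):
        stem = f"{prefix}_{i:04d}"
        img_path = out_dir / f"{stem}.tif"
        mask_path = out_dir / f"{stem}_mask.png"
        pixels = np.clip(np.rint(rec.pixels), 0, 65535).astype(np.uint16)
        tifffile.imwrite(img_path, pixels)
        import imageio.v3 as iio

        iio.imwrite(mask_path, (rec.mask.astype(np.uint8) * 255))
        rows.append(
            {
                "path": img_path.name,
                "subject_id": rec.subject_id,
                "laterality": rec.laterality,
                "view": rec.view,
                "thickness_mm": rec.thickness_mm,
                "kV_proxy": rec.kv,
                "mAs_proxy": rec.mas,
                "pixel_spacing_mm": rec.pixel_spacing_mm,
                "mask_path": mask_path.name,
            }
        )
    manifest = pd.DataFrame(rows, columns=MANIFEST_COLUMNS)
    manifest_path = out_dir / f"{prefix}_manifest.csv"
    write_table(manifest, manifest_path, kind="manifest")
    return manifest_path


def _read_image(path: Path) -> tuple[np.ndarray, float | None]:
    """Read TIFF/PNG (or DICOM when pydicom is available)."""
    suffix = path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        return np.asarray(tifffile.imread(path), dtype=float), None
    if suffix == ".dcm":
        import pydicom

        ds = pydicom.dcmread(path)
        spacing = None
        if getattr(ds, "PixelSpacing", None):
            spacing = float(ds.PixelSpacing[0])
        elif getattr(ds, "ImagerPixelSpacing", None):
            spacing = float(ds.ImagerPixelSpacing[0])
        return np.asarray(ds.pixel_array, dtype=float), spacing
    import imageio.v3 as iio

    return np.asarray(iio.imread(path), dtype=float), None


def read_manifest(manifest_path: str | Path) -> list[ImageRecord]:
    """Load the image records described by a manifest CSV."""
    manifest_path = Path(manifest_path)
    manifest = read_table(manifest_path, kind="manifest",
                          required=MANIFEST_COLUMNS)
    base = manifest_path.parent
    records = []
    for row in manifest.itertuples(index=False):
        pixels, dicom_spacing = _read_image(base / row.path)
        spacing = (
            dicom_spacing
            if dicom_spacing is not None and pd.isna(row.pixel_spacing_mm)
            else float(row.pixel_spacing_mm)
        )
        mask = None
        if isinstance(row.mask_path, str) and row.mask_path:
            mask_arr, _ = _read_image(base / row.mask_path)
            mask = mask_arr > 0
        records.append(
            ImageRecord(
                pixels=pixels,
                pixel_spacing_mm=spacing,
                mask=mask,
                subject_id=str(row.subject_id),
                laterality=str(row.laterality) if pd.notna(row.laterality) else "",
                view=str(row.view),
                thickness_mm=float(row.thickness_mm),
                kv=float(row.kV_proxy),
                mas=float(row.mAs_proxy),
            )
        )
    return records


def write_table(df: pd.DataFrame, path: str | Path, kind: str) -> None:
    """CSV with a one-line schema header; byte-deterministic for equal input."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", newline="") as fh:
        fh.write(f"# mammotex-csv v{SCHEMA_VERSION} kind={kind}\n")
        df.to_csv(fh, index=False, lineterminator="\n")


def read_table(
    path: str | Path, kind: str | None = None, required: list[str] | None = None
) -> pd.DataFrame:
    """Read a schema-tagged (or plain) CSV, validating version and columns."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(
            f"missing artifact {path}; run the producing command first"
        )
    with open(path) as fh:
        first = fh.readline()
    skip = 0
    if first.startswith("# mammotex-csv"):
        version = first.split()[2]
        if version != f"v{SCHEMA_VERSION}":
            raise ValueError(
                f"{path}: unsupported schema version {version!r} "
                f"(reader supports v{SCHEMA_VERSION})"
            )
        skip = 1
    df = pd.read_csv(path, skiprows=skip)
    if required:
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise ValueError(
                f"{path}: schema mismatch, missing column(s) {missing}"
            )
    return df


def write_provenance(out_dir: str | Path, config: dict, seed: int) -> Path:
    """Record the exact configuration and seed used to produce artifacts."""
    from . import __version__

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    blob = json.dumps(config, sort_keys=True, default=str)
    payload = {
        "config": config,
        "config_sha256": hashlib.sha256(blob.encode()).hexdigest(),
        "seed": seed,
        "mammotex_version": __version__,
    }
    path = out_dir / "provenance.json"
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True, default=str)
    return path
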