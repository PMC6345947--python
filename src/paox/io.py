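"""On-disk formats.

Scans travel as multi-page TIFF (one page per wavelength, in wavelength
order) with a JSON sidecar carrying the acquisition metadata; ROI masks as
single-page binary TIFF or PNG; cohort tables as plain CSV.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Union

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

from .errors import FormatError
from .phantom import MultispectralScan

__all__ = [
    "write_scan", "read_scan", "write_mask", "read_mask",
    "write_cohort_table", "read_cohort_table",
]

PathLike = Union[str, Path]


def write_scan(scan: MultispectralScan, tiff_path: PathLike,
               json_path: Optional[PathLike] = None) -> None:
    """Write frames (+ structural image as the final page) and the sidecar."""
    tiff_path = Path(tiff_path)
    json_path = Path(json_path) if json_path else tiff_path.with_suffix(".json")
    pages = np.concatenate(
        [scan.frames.astype(np.float32), scan.structural[None].astype(np.float32)]
    )
    tifffile.imwrite(tiff_path, pages, photometric="minisblack")
    meta = {
        "wavelengths_nm": list(scan.wavelengths_nm),
        "surface_fluence_mj_cm2": list(scan.surface_fluence_mj_cm2),
        "pixel_spacing_mm": scan.pixel_spacing_mm,
        "seed": scan.seed,
        "corrected": scan.corrected,
        "scan_id": scan.scan_id,
        "structural_page": len(scan.wavelengths_nm),
    }
    json_path.write_text(json.dumps(meta, indent=1))


def read_scan(tiff_path: PathLike, json_path: Optional[PathLike] = None) -> MultispectralScan:
    tiff_path = Path(tiff_path)
    json_path = Path(json_path) if json_path else tiff_path.with_suffix(".json")
    try:
        meta = json.loads(json_path.read_text())
    except (OSError, json.JSONDecodeError) as exc:
        raise FormatError(f"cannot read scan sidecar {json_path}: {exc}") from exc
    pages = tifffile.imread(tiff_path)
    if pages.ndim == 2:
        pages = pages[None]
    n_wl = len(meta["wavelengths_nm"])
    if pages.shape[0] < n_wl:
        raise FormatError(
            f"scan TIFF has {pages.shape[0]} pages but sidecar lists {n_wl} wavelengths"
        )
    frames = pages[:n_wl].astype(float)
    structural = (pages[n_wl].astype(float) if pages.shape[0] > n_wl
                  else np.zeros(frames.shape[1:]))
    return MultispectralScan(
        frames=frames,
        wavelengths_nm=tuple(meta["wavelengths_nm"]),
        surface_fluence_mj_cm2=tuple(meta["surface_fluence_mj_cm2"]),
        structural=structural,
        pixel_spacing_mm=float(meta["pixel_spacing_mm"]),
        seed=meta.get("seed"),
        corrected=bool(meta.get("corrected", False)),
        scan_id=meta.get("scan_id", ""),
    )


def write_mask(mask: np.ndarray, path: PathLike) -> None:
    """Binary mask as 0/255 single-page TIFF or PNG (by extension)."""
    path = Path(path)
    img = (np.asarray(mask).astype(bool) * np.uint8(255))
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, img)
    else:
        iio.imwrite(path, img)


def read_mask(path: PathLike) -> np.ndarray:
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        img = tifffile.imread(path)
    else:
        img = iio.imread(path)
    if img.ndim == 3:  # RGB(A) mask export: any nonzero channel counts
        img = img[..., :3].max(axis=-1)
    return np.asarray(img) > 0


def write_cohort_table(table: pd.DataFrame, path: PathLike) -> None:
    table.to_csv(path, index=False)


def read_cohort_table(path: PathLike) -> pd.DataFrame:
    df = pd.read_csv(path)
    if "group" not in df.columns:
        raise FormatError("cohort CSV must have a 'group' column")
    return df
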