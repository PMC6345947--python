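"""Oxygenation overlays.

Display convention: a 255-entry blue-to-red colormap (entry 0 = fully
deoxygenated = pure blue, entry 254 = fully oxygenated = pure red) drawn
over the grayscale structural image, with per-pixel transparency scaled to
the fluence-corrected photoacoustic amplitude so that strongly absorbing
(blood-rich) pixels dominate the figure and signal-free pixels vanish.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Union

import imageio.v3 as iio
import numpy as np

from .errors import ValidationError

__all__ = ["OxygenationColormap", "build_so2_colormap", "render_overlay",
           "side_by_side_panel", "save_png"]


@dataclass(frozen=True)
class OxygenationColormap:
    """Ordered list of exactly 255 RGB triplets mapping sO2 0 -> 1."""

    entries: np.ndarray  # (255, 3) uint8

    def __post_init__(self) -> None:
        e = np.asarray(self.entries)
        if e.shape != (255, 3):
            raise ValidationError("oxygenation colormap must have exactly 255 RGB entries")
        object.__setattr__(self, "entries", e.astype(np.uint8))

    def lookup(self, so2: np.ndarray) -> np.ndarray:
        """Map saturation fractions to RGB; NaN maps to entry 0 (callers are
        expected to zero the alpha of undefined pixels)."""
        s = np.nan_to_num(np.asarray(so2, float), nan=0.0)
        idx = np.clip(np.round(s * 254.0), 0, 254).astype(np.intp)
        return self.entries[idx]


def build_so2_colormap() -> OxygenationColormap:
    """Linear 255-step RGB ramp from blue (0,0,255) to red (255,0,0).

    Intermediate hues pass through dark purple; only the endpoints are part
    of the display convention, the ramp in between is this package's choice.
    """
    i = np.arange(255)
    red = (255 * i) // 254
    entries = np.stack([red, np.zeros(255, dtype=np.intp), 255 - red], axis=1)
    return OxygenationColormap(entries.astype(np.uint8))


def _as_gray_uint8(img: np.ndarray) -> np.ndarray:
    img = np.asarray(img, float)
    if img.max() > 1.0:
        img = img / 255.0
    return np.clip(np.round(img * 255.0), 0, 255).astype(np.uint8)


def render_overlay(
    structural: np.ndarray,
    so2_map: np.ndarray,
    alpha_source: np.ndarray,
    mask: np.ndarray,
    alpha_percentile: float = 99.0,
    cmap: Optional[OxygenationColormap] = None,
) -> np.ndarray:
    """Composite the sO2 colormap over the structural image.

    Per-pixel overlay opacity inside the mask is the fluence-corrected
    amplitude clipped to ``[0, P]`` and divided by ``P``, where ``P`` is the
    ``alpha_percentile``-th percentile of in-mask amplitude (a robust "full
    opacity" reference that ignores hot pixels).  Outside the mask — and at
    pixels whose sO2 is undefined — the overlay is fully transparent and the
    structural image shows through unchanged.

    Returns an (H, W, 4) uint8 array: RGB is the composited image, the
    alpha channel stores the overlay opacity (0 where only anatomy shows).
    """
    structural = np.asarray(structural, float)
    so2_map = np.asarray(so2_map, float)
    alpha_source = np.asarray(alpha_source, float)
    mask = np.asarray(mask).astype(bool)
    if not (structural.shape == so2_map.shape == alpha_source.shape == mask.shape):
        raise ValidationError("structural, so2, alpha and mask images must share a shape")
    if not 0.0 < alpha_percentile <= 100.0:
        raise ValidationError("alpha_percentile must be in (0, 100]")
    cmap = cmap or build_so2_colormap()

    alpha = np.zeros(mask.shape)
    if mask.any():
        ref = np.percentile(alpha_source[mask], alpha_percentile)
        if ref > 0:
            alpha[mask] = np.clip(alpha_source[mask], 0.0, ref) / ref
    alpha[~np.isfinite(so2_map)] = 0.0
    alpha[~mask] = 0.0

    gray = _as_gray_uint8(structural).astype(float)
    color = cmap.lookup(so2_map).astype(float)
    rgb = (1.0 - alpha[..., None]) * gray[..., None] + alpha[..., None] * color
    out = np.empty(mask.shape + (4,), dtype=np.uint8)
    out[..., :3] = np.clip(np.round(rgb), 0, 255).astype(np.uint8)
    out[..., 3] = np.clip(np.round(alpha * 255.0), 0, 255).astype(np.uint8)
    return out


def side_by_side_panel(*images: np.ndarray, gap_px: int = 4) -> np.ndarray:
    """Horizontal panel of equally sized images (grayscale or RGB(A)),
    e.g. structural | isosbestic amplitude | oxygenation overlay."""
    if not images:
        raise ValidationError("panel needs at least one image")
    rgb = []
    for img in images:
        arr = np.asarray(img)
        if arr.ndim == 2:
            g = _as_gray_uint8(arr)
            arr = np.stack([g, g, g], axis=-1)
        elif arr.shape[-1] == 4:
            arr = arr[..., :3]
        rgb.append(arr.astype(np.uint8))
    h = rgb[0].shape[0]
    if any(r.shape[0] != h for r in rgb):
        raise ValidationError("panel images must share height")
    spacer = np.full((h, gap_px, 3), 255, dtype=np.uint8)
    parts = []
    for i, r in enumerate(rgb):
        if i:
            parts.append(spacer)
        parts.append(r)
    return np.concatenate(parts, axis=1)


def save_png(image: np.ndarray, path: Union[str, Path]) -> None:
    """Write an 8-bit PNG; identical arrays produce identical bytes."""
    iio.imwrite(Path(path), np.asarray(image, dtype=np.uint8), extension=".png")
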