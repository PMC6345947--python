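"""Immunohistochemistry quantification by color deconvolution.

Brightfield histology obeys Beer-Lambert absorption in each RGB channel, so
a stained slide is linear in optical density (OD): the OD of a pixel is the
stain amounts weighted by per-stain unit OD vectors.  Inverting that 3x3
system ("color deconvolution", Ruifrok & Johnston's method) separates DAB
(the brown hypoxia-marker chromogen) from the hematoxylin counterstain, and
the hypoxia readout is the percent of placental-section pixels whose DAB
amount exceeds a threshold.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .errors import ConditioningError, FormatError, ValidationError

__all__ = [
    "StainVectors",
    "IHCQuantResult",
    "rgb_to_od",
    "od_to_rgb",
    "compose_od",
    "color_deconvolve",
    "dab_area_fraction",
    "DEFAULT_DAB_THRESHOLD_OD",
]

#: Default DAB positivity threshold, in OD units along the DAB stain vector.
DEFAULT_DAB_THRESHOLD_OD = 0.15


@dataclass(frozen=True)
class StainVectors:
    """Unit stain vectors in RGB optical-density space (rows = stains).

    Row order is (hematoxylin, DAB, residual).  Rows are normalized to unit
    Euclidean norm and must be nonnegative; the matrix must be invertible.
    """

    matrix: np.ndarray
    names: tuple[str, str, str] = ("hematoxylin", "dab", "residual")

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, float)
        if m.shape != (3, 3):
            raise ValidationError("stain matrix must be 3x3 (rows = stains)")
        if np.any(m < 0):
            raise ValidationError("stain vector components must be nonnegative")
        norms = np.linalg.norm(m, axis=1)
        if np.any(norms == 0):
            raise ConditioningError("zero stain vector")
        m = m / norms[:, None]
        cond = np.linalg.cond(m)
        if not np.isfinite(cond) or cond > 1e8:
            raise ConditioningError(f"stain matrix is singular (cond={cond:.3g})")
        object.__setattr__(self, "matrix", m)
        object.__setattr__(self, "condition_number", float(cond))

    condition_number: float = 0.0

    @classmethod
    def hdab(cls) -> "StainVectors":
        """The standard hematoxylin + DAB pair (Ruifrok & Johnston values)
        with the conventional nonnegative residual third vector
        (componentwise sqrt of the unexplained channel energy)."""
        h = np.array([0.650, 0.704, 0.286])
        d = np.array([0.268, 0.570, 0.776])
        h = h / np.linalg.norm(h)
        d = d / np.linalg.norm(d)
        r = np.sqrt(np.clip(1.0 - h**2 - d**2, 0.0, None))
        return cls(np.stack([h, d, r]))

    @property
    def inverse(self) -> np.ndarray:
        return np.linalg.inv(self.matrix)


@dataclass(frozen=True)
class IHCQuantResult:
    """DAB-positivity quantification within a placental section mask."""

    dab_od_map: np.ndarray
    positive_mask: np.ndarray
    area_fraction_percent: float
    threshold_used: float
    n_mask_pixels: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.area_fraction_percent <= 100.0:
            raise ValidationError("area fraction must be a percentage in [0, 100]")


def rgb_to_od(rgb: np.ndarray, background_intensity: float = 255.0) -> np.ndarray:
    """Transmitted-light image to optical density, per channel:
    ``OD_c = -log10(max(I_c, 1) / background)``.  The 1-count floor keeps
    fully dark pixels finite."""
    rgb = np.asarray(rgb)
    if rgb.ndim != 3 or rgb.shape[-1] != 3:
        raise FormatError("expected an (H, W, 3) RGB image")
    if rgb.dtype != np.uint8 and (rgb.min() < 0 or rgb.max() > 255):
        raise FormatError("expected 8-bit RGB intensities in [0, 255]")
    i = np.maximum(rgb.astype(float), 1.0)
    return -np.log10(i / float(background_intensity))


def od_to_rgb(od: np.ndarray, background_intensity: float = 255.0,
              quantize: bool = True) -> np.ndarray:
    """Inverse of :func:`rgb_to_od`: OD back to transmitted intensities."""
    i = float(background_intensity) * np.power(10.0, -np.asarray(od, float))
    if quantize:
        return np.clip(np.round(i), 0, 255).astype(np.uint8)
    return i


def compose_od(amounts: np.ndarray, vectors: StainVectors) -> np.ndarray:
    """Forward stain mixing: per-pixel stain amounts (H, W, 3) to OD."""
    return np.asarray(amounts, float) @ vectors.matrix


def color_deconvolve(od: np.ndarray, vectors: Optional[StainVectors] = None) -> np.ndarray:
    """Separate an OD image into per-stain amount maps.

    Solves the 3x3 linear system per pixel (amounts @ matrix = OD) and clips
    negative amounts to zero.  Returns an (H, W, 3) array in the row order
    of ``vectors`` (hematoxylin, DAB, residual by default).
    """
    vectors = vectors or StainVectors.hdab()
    od = np.asarray(od, float)
    if od.ndim != 3 or od.shape[-1] != 3:
        raise FormatError("expected an (H, W, 3) OD image")
    amounts = od @ vectors.inverse
    return np.clip(amounts, 0.0, None)


def dab_area_fraction(
    dab_map: np.ndarray,
    placenta_mask: np.ndarray,
    threshold: float = DEFAULT_DAB_THRESHOLD_OD,
) -> IHCQuantResult:
    """Percent of mask pixels whose DAB amount exceeds ``threshold``."""
    dab_map = np.asarray(dab_map, float)
    mask = np.asarray(placenta_mask).astype(bool)
    if mask.shape != dab_map.shape:
        raise ValidationError("mask shape must match the DAB map")
    n = int(mask.sum())
    if n == 0:
        raise ValidationError("placenta mask is empty")
    positive = (dab_map > threshold) & mask
    return IHCQuantResult(
        dab_od_map=dab_map,
        positive_mask=positive,
        area_fraction_percent=100.0 * int(positive.sum()) / n,
        threshold_used=float(threshold),
        n_mask_pixels=n,
    )


def quantify_slide(
    rgb: np.ndarray,
    placenta_mask: np.ndarray,
    vectors: Optional[StainVectors] = None,
    threshold: float = DEFAULT_DAB_THRESHOLD_OD,
    background_intensity: float = 255.0,
) -> IHCQuantResult:
    """Full slide pipeline: RGB -> OD -> deconvolution -> DAB area fraction."""
    amounts = color_deconvolve(rgb_to_od(rgb, background_intensity), vectors)
    return dab_area_fraction(amounts[..., 1], placenta_mask, threshold)
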