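"""Spectral unmixing of multispectral photoacoustic scans to sO2.

Pipeline: divide each frame by its surface laser fluence, solve the per-pixel
overdetermined linear system

    p(lambda) = ln(10) * [eps_hbo2(lambda), eps_hb(lambda)] @ [c_hbo2, c_hb]

in the least-squares sense, handle negative solutions per the chosen clip
policy, average concentrations over the region of interest, and form

    sO2 = C[HbO2] / (C[HbO2] + C[Hb])

from the ROI-mean concentrations.  Concentrations are relative (arbitrary
units): the Grueneisen parameter and system gain are not calibrated, which
cancels in the saturation ratio.

Unmixing is done per pixel first and concentrations are averaged afterwards
(not the other way around): saturation is a ratio, so averaging spectra
before inversion would weight pixels by amplitude rather than by area.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Literal, Sequence

import numpy as np
from scipy.optimize import nnls as _scipy_nnls

from .errors import ConditioningError, DegenerateInputError, ValidationError
from .optics import ExtinctionTable, epsilon_at
from .phantom import LN10, MultispectralScan

__all__ = [
    "ChromophoreConcentrations",
    "SO2Result",
    "fluence_correct",
    "design_matrix",
    "unmix_pixel",
    "unmix_frames",
    "unmix_roi",
]

ClipPolicy = Literal["clip_negative", "nnls"]

#: Condition-number ceiling above which the spectral system is rejected.
MAX_CONDITION_NUMBER = 1e8


@dataclass(frozen=True)
class ChromophoreConcentrations:
    """Raw (possibly negative) least-squares solution for one pixel."""

    c_hbo2: float
    c_hb: float


@dataclass(frozen=True)
class SO2Result:
    """Concentration/saturation maps plus the ROI-level summary.

    ``so2_map`` is NaN outside the ROI and at degenerate pixels (total
    concentration ≤ 0 after clipping); such pixels stay counted in
    ``n_roi_pixels``.  ``n_clipped_pixels`` counts clipped chromophore
    components (≤ 2 per pixel).  ``roi_so2`` is exactly
    ``roi_mean_c_hbo2 / (roi_mean_c_hbo2 + roi_mean_c_hb)``.
    """

    c_hb_map: np.ndarray
    c_hbo2_map: np.ndarray
    so2_map: np.ndarray
    residual_map: np.ndarray
    roi_mean_c_hb: float
    roi_mean_c_hbo2: float
    roi_so2: float
    n_roi_pixels: int
    n_clipped_pixels: int
    scan_id: str = ""

    def summary_row(self) -> dict:
        return {
            "scan_id": self.scan_id,
            "roi_so2": self.roi_so2,
            "roi_mean_c_hbo2": self.roi_mean_c_hbo2,
            "roi_mean_c_hb": self.roi_mean_c_hb,
            "n_roi_pixels": self.n_roi_pixels,
            "n_clipped_pixels": self.n_clipped_pixels,
        }


def fluence_correct(scan: MultispectralScan) -> MultispectralScan:
    """Normalize each frame by its surface fluence (mJ/cm^2).

    Returns a scan whose frames are in amplitude per unit fluence with the
    ``corrected`` flag set; correcting an already corrected scan is a no-op,
    so the operation is idempotent.
    """
    if scan.corrected:
        return scan
    fluences = np.asarray(scan.surface_fluence_mj_cm2, float)
    if np.any(fluences <= 0):
        raise ValidationError("surface fluences must be positive for correction")
    return replace(scan, frames=scan.frames / fluences[:, None, None], corrected=True)


def design_matrix(table: ExtinctionTable, wavelengths: Sequence[float]) -> np.ndarray:
    """Spectral system matrix, rows = wavelengths, columns = (eps_hbo2, eps_hb),
    scaled by ln(10) to match the absorption-coefficient convention of the
    forward model.  Raises :class:`ConditioningError` when the wavelength set
    cannot separate the two species (e.g. all wavelengths isosbestic)."""
    wavelengths = tuple(float(w) for w in wavelengths)
    if len(wavelengths) < 2:
        raise ValidationError("need at least two wavelengths to unmix two chromophores")
    A = LN10 * np.column_stack([
        np.asarray(epsilon_at(table, np.asarray(wavelengths), "hbo2"), float),
        np.asarray(epsilon_at(table, np.asarray(wavelengths), "hb"), float),
    ])
    cond = np.linalg.cond(A)
    if not np.isfinite(cond) or cond > MAX_CONDITION_NUMBER:
        raise ConditioningError(
            f"wavelength set {wavelengths} nm yields a rank-deficient or "
            f"ill-conditioned spectral system (cond={cond:.3g}); the Hb and "
            "HbO2 spectra are not separable at these wavelengths"
        )
    return A


def unmix_pixel(
    amplitudes: Sequence[float], A: np.ndarray
) -> tuple[ChromophoreConcentrations, float]:
    """Least-squares inversion of one pixel's per-wavelength amplitudes.

    Returns the raw solution (components may be negative) and the Euclidean
    residual norm.  Clipping is applied downstream per policy.
    """
    y = np.asarray(amplitudes, float)
    if y.shape != (A.shape[0],):
        raise ValidationError("one amplitude per design-matrix wavelength required")
    sol, *_ = np.linalg.lstsq(A, y, rcond=None)
    residual = float(np.linalg.norm(A @ sol - y))
    return ChromophoreConcentrations(c_hbo2=float(sol[0]), c_hb=float(sol[1])), residual


def unmix_frames(frames: np.ndarray, A: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized per-pixel least squares over a (n_wl, H, W) stack.

    Returns raw ``(c_hbo2, c_hb, residual_norm)`` maps.
    """
    n_wl = A.shape[0]
    y = frames.reshape(n_wl, -1)
    sol = np.linalg.pinv(A) @ y  # (2, N)
    res = np.linalg.norm(A @ sol - y, axis=0)
    shape = frames.shape[1:]
    return sol[0].reshape(shape), sol[1].reshape(shape), res.reshape(shape)


def _apply_clip_policy(
    c_hbo2: np.ndarray,
    c_hb: np.ndarray,
    frames: np.ndarray,
    A: np.ndarray,
    mask: np.ndarray,
    policy: ClipPolicy,
) -> tuple[np.ndarray, np.ndarray, int]:
    neg = (c_hbo2 < 0) | (c_hb < 0)
    n_clipped = int((c_hbo2[mask] < 0).sum() + (c_hb[mask] < 0).sum())
    if policy == "clip_negative":
        return np.clip(c_hbo2, 0, None), np.clip(c_hb, 0, None), n_clipped
    if policy == "nnls":
        c_hbo2 = c_hbo2.copy()
        c_hb = c_hb.copy()
        redo = np.flatnonzero((neg & mask).ravel())
        y = frames.reshape(A.shape[0], -1)
        for idx in redo:
            sol, _ = _scipy_nnls(A, y[:, idx])
            c_hbo2.ravel()[idx], c_hb.ravel()[idx] = sol
        # pixels with an already-nonnegative unconstrained solution keep it
        return np.clip(c_hbo2, 0, None), np.clip(c_hb, 0, None), n_clipped
    raise ValidationError(f"unknown clip policy {policy!r}")


def unmix_roi(
    scan: MultispectralScan,
    table: ExtinctionTable,
    mask: np.ndarray,
    clip_policy: ClipPolicy = "clip_negative",
) -> SO2Result:
    """Fluence-correct, unmix every ROI pixel, and compute ROI sO2.

    ``mask`` is a boolean (or 0/1) array matching the frame shape; the ROI
    is typically the manually drawn placental border.  Degenerate pixels
    (total concentration ≤ 0 after clipping) are excluded from ``so2_map``
    but remain in ``n_roi_pixels``.  Raises :class:`ValidationError` for an
    empty mask and :class:`DegenerateInputError` when the ROI-mean total
    concentration is not positive (saturation undefined).
    """
    mask = np.asarray(mask).astype(bool)
    if mask.shape != scan.shape:
        raise ValidationError("mask shape must match the scan frames")
    if not mask.any():
        raise ValidationError("ROI mask is empty")

    corrected = fluence_correct(scan)
    A = design_matrix(table, corrected.wavelengths_nm)
    c_hbo2_raw, c_hb_raw, residual = unmix_frames(corrected.frames, A)
    c_hbo2, c_hb, n_clipped = _apply_clip_policy(
        c_hbo2_raw, c_hb_raw, corrected.frames, A, mask, clip_policy
    )

    c_hbo2 = np.where(mask, c_hbo2, np.nan)
    c_hb = np.where(mask, c_hb, np.nan)
    total = c_hbo2 + c_hb
    with np.errstate(invalid="ignore", divide="ignore"):
        so2_map = np.where(total > 0, c_hbo2 / np.where(total > 0, total, 1.0), np.nan)

    mean_hbo2 = float(np.nanmean(c_hbo2[mask]))
    mean_hb = float(np.nanmean(c_hb[mask]))
    if mean_hbo2 + mean_hb <= 0:
        raise DegenerateInputError(
            "ROI-mean total hemoglobin concentration is not positive; sO2 undefined"
        )
    return SO2Result(
        c_hb_map=c_hb,
        c_hbo2_map=c_hbo2,
        so2_map=so2_map,
        residual_map=np.where(mask, residual, np.nan),
        roi_mean_c_hb=mean_hb,
        roi_mean_c_hbo2=mean_hbo2,
        roi_so2=mean_hbo2 / (mean_hbo2 + mean_hb),
        n_roi_pixels=int(mask.sum()),
        n_clipped_pixels=n_clipped,
        scan_id=scan.scan_id,
    )
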