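"""Synthetic placental phantoms and forward photoacoustic simulation.

Every downstream stage (unmixing, rendering, histology quantification,
cohort statistics) is exercised against data produced here, so the module
carries explicit ground truth alongside every image it emits.

The forward model is the usual linearized photoacoustic generation model:

    p(x, lambda) = gamma * mu_a(x, lambda) * Phi(lambda, depth(x)) + noise

with the absorption coefficient assembled from the two hemoglobin species,

    mu_a = ln(10) * (eps_hbo2(lambda) * c_hbo2(x) + eps_hb(lambda) * c_hb(x)).

gamma lumps the Grueneisen parameter and system gain and defaults to 1 in
arbitrary units: oxygen saturation is a concentration ratio and therefore
insensitive to any global scale, so no absolute calibration is attempted.

The cohort simulator emulates a two-group longitudinal design: normal
pregnant (NP) controls versus a reduced-uterine-perfusion-pressure (RUPP)
model of preeclampsia, imaged on gestational days 14, 16 and 18 with ten
animals per group and five placentas per animal.  NP placental sO2 averages
60%; RUPP shows a 12% relative deficit two days after surgery (GD16) with a
slight recovery (9% deficit) by GD18.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Literal, Optional, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import ndimage

from .errors import GeometryError, RangeError, ValidationError
from .optics import ExtinctionTable, epsilon_at

__all__ = [
    "PhantomTruth",
    "FluenceModel",
    "MultispectralScan",
    "CohortDesign",
    "IHCImageTruth",
    "CohortRecord",
    "LN10",
    "DEFAULT_WAVELENGTHS_NM",
    "make_placenta_phantom",
    "forward_pa",
    "draw_cohort_truths",
    "simulate_cohort",
    "make_ihc_image",
]

LN10 = float(np.log(10.0))

#: Imaging wavelengths: deoxy-Hb peak, near-isosbestic, oxy-Hb dominant.
DEFAULT_WAVELENGTHS_NM: tuple[float, ...] = (690.0, 808.0, 950.0)

#: Default field of view ~30 x 22 mm at 128 x 96 pixels.
DEFAULT_SHAPE: tuple[int, int] = (96, 128)
DEFAULT_PIXEL_SPACING_MM: float = 30.0 / 128.0

LABEL_BACKGROUND, LABEL_TISSUE, LABEL_PLACENTA = 0, 1, 2

# Structural (B-mode-like) rendering: mean intensity per label, in [0, 1].
_STRUCTURAL_MEANS = {LABEL_BACKGROUND: 0.08, LABEL_TISSUE: 0.45, LABEL_PLACENTA: 0.72}


@dataclass(frozen=True)
class PhantomTruth:
    """Per-pixel ground-truth chromophore maps plus tissue geometry.

    ``depth_axis`` is the image axis pointing away from the transducer
    (always 0 here: depth grows with the row index; pixel (0, 0) top-left).
    """

    c_hb: np.ndarray
    c_hbo2: np.ndarray
    labels: np.ndarray
    pixel_spacing_mm: float
    depth_axis: int = 0

    def __post_init__(self) -> None:
        if self.c_hb.shape != self.labels.shape or self.c_hbo2.shape != self.labels.shape:
            raise ValidationError("concentration maps and labels must share a shape")
        if np.any(self.c_hb < 0) or np.any(self.c_hbo2 < 0):
            raise ValidationError("concentration maps must be nonnegative")

    @property
    def so2(self) -> np.ndarray:
        """Ground-truth per-pixel saturation; NaN where total hemoglobin is 0."""
        total = self.c_hb + self.c_hbo2
        with np.errstate(invalid="ignore", divide="ignore"):
            s = np.where(total > 0, self.c_hbo2 / np.where(total > 0, total, 1.0), np.nan)
        return s

    @property
    def depth_mm(self) -> np.ndarray:
        """Per-pixel depth below the transducer face."""
        rows = np.arange(self.labels.shape[self.depth_axis], dtype=float)
        depth = rows * self.pixel_spacing_mm
        return np.broadcast_to(depth[:, None], self.labels.shape).copy()


@dataclass(frozen=True)
class FluenceModel:
    """Optical fluence delivered to tissue, per wavelength.

    ``surface_only`` uses the surface pulse energy density alone (the
    default, matching plain laser-energy normalization); ``beer_lambert_depth``
    additionally attenuates exponentially with depth using ``mu_eff_per_mm``,
    which is useful to study the bias of an uncompensated depth term.
    The instrument delivers 10-20 mJ/cm^2 at the surface; ``default()``
    stays inside that range, but the constructor only requires positivity so
    that unit-fluence simulations remain expressible.
    """

    wavelengths_nm: tuple[float, ...]
    surface_fluence_mj_cm2: tuple[float, ...]
    mu_eff_per_mm: tuple[float, ...] = ()
    model: Literal["surface_only", "beer_lambert_depth"] = "surface_only"

    def __post_init__(self) -> None:
        wl = tuple(float(w) for w in self.wavelengths_nm)
        f = tuple(float(v) for v in self.surface_fluence_mj_cm2)
        mu = tuple(float(v) for v in self.mu_eff_per_mm) or (0.0,) * len(wl)
        if len(f) != len(wl) or len(mu) != len(wl):
            raise ValidationError("per-wavelength fluence fields must align with wavelengths")
        if any(v <= 0 for v in f):
            raise ValidationError("surface fluence must be positive")
        if any(v < 0 for v in mu):
            raise ValidationError("mu_eff must be nonnegative")
        if self.model not in ("surface_only", "beer_lambert_depth"):
            raise ValidationError(f"unknown fluence model {self.model!r}")
        object.__setattr__(self, "wavelengths_nm", wl)
        object.__setattr__(self, "surface_fluence_mj_cm2", f)
        object.__setattr__(self, "mu_eff_per_mm", mu)

    @classmethod
    def default(cls, wavelengths_nm: Sequence[float] = DEFAULT_WAVELENGTHS_NM) -> "FluenceModel":
        """Surface-only fluence inside the 10-20 mJ/cm^2 instrument range,
        decreasing with wavelength as pulse energy typically does."""
        wl = np.asarray(wavelengths_nm, float)
        f = np.interp(wl, [650.0, 1000.0], [18.0, 11.0])
        return cls(tuple(wl), tuple(f))

    @classmethod
    def unit(cls, wavelengths_nm: Sequence[float] = DEFAULT_WAVELENGTHS_NM) -> "FluenceModel":
        return cls(tuple(float(w) for w in wavelengths_nm), (1.0,) * len(tuple(wavelengths_nm)))

    @property
    def in_instrument_range(self) -> bool:
        return all(10.0 <= v <= 20.0 for v in self.surface_fluence_mj_cm2)

    def surface(self, wavelength_nm: float) -> float:
        try:
            i = self.wavelengths_nm.index(float(wavelength_nm))
        except ValueError:
            raise RangeError(f"no fluence tabulated at {wavelength_nm} nm") from None
        return self.surface_fluence_mj_cm2[i]

    def at(self, wavelength_nm: float, depth_mm: np.ndarray) -> np.ndarray:
        """Phi(lambda, depth) on an array of depths (mm)."""
        i = self.wavelengths_nm.index(float(wavelength_nm))
        phi0 = self.surface_fluence_mj_cm2[i]
        if self.model == "surface_only":
            return np.full_like(np.asarray(depth_mm, float), phi0)
        return phi0 * np.exp(-self.mu_eff_per_mm[i] * np.asarray(depth_mm, float))


@dataclass(frozen=True)
class MultispectralScan:
    """Co-registered per-wavelength photoacoustic frames plus metadata.

    ``frames`` has shape (n_wavelengths, H, W); ``structural`` is the
    co-registered grayscale anatomy image (B-mode-like, in [0, 1]).
    ``corrected`` records whether frames are already fluence-normalized.
    """

    frames: np.ndarray
    wavelengths_nm: tuple[float, ...]
    surface_fluence_mj_cm2: tuple[float, ...]
    structural: np.ndarray
    pixel_spacing_mm: float
    seed: Optional[int] = None
    corrected: bool = False
    scan_id: str = ""

    def __post_init__(self) -> None:
        frames = np.asarray(self.frames, float)
        wl = tuple(float(w) for w in self.wavelengths_nm)
        fl = tuple(float(v) for v in self.surface_fluence_mj_cm2)
        if frames.ndim != 3 or frames.shape[0] != len(wl):
            raise ValidationError("frames must be (n_wavelengths, H, W), one per wavelength")
        if len(fl) != len(wl):
            raise ValidationError("one surface fluence per wavelength required")
        if self.structural.shape != frames.shape[1:]:
            raise ValidationError("structural image must share the frame shape")
        if not all(b > a for a, b in zip(wl, wl[1:])):
            raise ValidationError("wavelengths must be strictly increasing")
        object.__setattr__(self, "frames", frames)
        object.__setattr__(self, "wavelengths_nm", wl)
        object.__setattr__(self, "surface_fluence_mj_cm2", fl)

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]

    def frame_at(self, wavelength_nm: float) -> np.ndarray:
        return self.frames[self.wavelengths_nm.index(float(wavelength_nm))]


@dataclass(frozen=True)
class CohortDesign:
    """Parameters of the simulated two-group longitudinal imaging study.

    sO2 quantities are fractions in [0, 1].  ``noise_sd=None`` selects the
    default noise level: per scan, the standard deviation giving ~20 dB
    amplitude SNR in the placenta at the wavelength nearest the isosbestic
    point (808 nm).
    """

    groups: tuple[str, str] = ("NP", "RUPP")
    gestational_days: tuple[int, ...] = (14, 16, 18)
    n_animals_per_group: int = 10
    n_placentas_per_animal: int = 5
    np_mean_so2: float = 0.60
    rupp_gd16_relative_decrease: float = 0.12
    rupp_gd18_relative_decrease: float = 0.09
    between_animal_sd: float = 0.03
    within_animal_sd: float = 0.03
    total_hb: float = 1.0
    noise_sd: Optional[float] = None
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("np_mean_so2", "rupp_gd16_relative_decrease",
                     "rupp_gd18_relative_decrease", "between_animal_sd",
                     "within_animal_sd"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must be a fraction in [0, 1], got {v}")
        if self.n_animals_per_group < 1 or self.n_placentas_per_animal < 1:
            raise ValidationError("need at least one animal and one placenta")
        if self.noise_sd is not None and self.noise_sd < 0:
            raise ValidationError("noise_sd must be nonnegative")

    def group_mean_so2(self, group: str, gd: int) -> float:
        """Design mean sO2 for a (group, gestational day) cell.

        RUPP equals NP at GD14 (surgery happens after the first imaging
        session); the deficit appears at GD16 and partially recovers at GD18.
        """
        if group == "NP" or gd <= 14:
            return self.np_mean_so2
        if gd == 16:
            return self.np_mean_so2 * (1.0 - self.rupp_gd16_relative_decrease)
        return self.np_mean_so2 * (1.0 - self.rupp_gd18_relative_decrease)

    @classmethod
    def from_yaml(cls, path) -> "CohortDesign":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("groups", "gestational_days"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        d = self.__dict__.copy()
        d["groups"] = list(d["groups"])
        d["gestational_days"] = list(d["gestational_days"])
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)


@dataclass(frozen=True)
class IHCImageTruth:
    """A synthetic H-DAB histology image with known DAB-positive fraction."""

    rgb: np.ndarray
    placenta_mask: np.ndarray
    true_dab_fraction: float
    dab_amount: np.ndarray = field(repr=False, default=None)  # type: ignore[assignment]
    hematoxylin_amount: np.ndarray = field(repr=False, default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if not 0.0 <= self.true_dab_fraction <= 100.0:
            raise ValidationError("true_dab_fraction must be in [0, 100]")


# ---------------------------------------------------------------------------
# phantom construction


def _ellipse_mask(shape: tuple[int, int], center_mm: tuple[float, float],
                  axes_mm: tuple[float, float], spacing: float) -> np.ndarray:
    rows, cols = np.ogrid[: shape[0], : shape[1]]
    cy, cx = (center_mm[0] / spacing, center_mm[1] / spacing)
    ay, ax = (axes_mm[0] / spacing, axes_mm[1] / spacing)
    return ((rows - cy) / ay) ** 2 + ((cols - cx) / ax) ** 2 <= 1.0


def make_placenta_phantom(
    shape: tuple[int, int] = DEFAULT_SHAPE,
    center_mm: tuple[float, float] = (7.0, 15.0),
    axes_mm: tuple[float, float] = (2.0, 4.0),
    so2: float = 0.60,
    total_hb: float = 1.0,
    background_hb_fraction: float = 0.2,
    background_so2: Optional[float] = None,
    surface_mm: float = 1.0,
    pixel_spacing_mm: float = DEFAULT_PIXEL_SPACING_MM,
    texture: bool = False,
    texture_amplitude: float = 0.1,
    seed: int = 0,
) -> tuple[PhantomTruth, np.ndarray]:
    """Build a placenta-like ground-truth phantom and its ROI mask.

    The placenta is an ellipse (``center_mm`` = (depth, lateral) of the
    center, ``axes_mm`` = semi-axes) embedded in tissue below a thin
    coupling layer (``surface_mm``).  Placental pixels carry
    ``c_hbo2 = so2 * total_hb`` and ``c_hb = (1 - so2) * total_hb``;
    surrounding tissue carries ``background_hb_fraction`` of the placental
    total (same sO2 unless ``background_so2`` is given).  With ``texture``,
    a smooth seed-driven field modulates total hemoglobin by at most
    ``texture_amplitude`` (both species equally, so per-pixel sO2 is
    untouched).

    Returns ``(truth, mask)`` where ``mask`` is the placental label region.
    """
    if not 0.0 <= so2 <= 1.0:
        raise ValidationError("so2 must be in [0, 1]")
    h, w = shape
    spacing = float(pixel_spacing_mm)
    cy, cx = center_mm
    ay, ax = axes_mm
    if (cy - ay < surface_mm or cy + ay > h * spacing
            or cx - ax < 0 or cx + ax > w * spacing):
        raise GeometryError(
            f"ellipse (center {center_mm} mm, semi-axes {axes_mm} mm) does not "
            f"fit inside the {h * spacing:.1f} x {w * spacing:.1f} mm field "
            f"below the {surface_mm:g} mm surface layer"
        )

    labels = np.full(shape, LABEL_TISSUE, dtype=np.int8)
    labels[: max(1, int(round(surface_mm / spacing)))] = LABEL_BACKGROUND
    mask = _ellipse_mask(shape, center_mm, axes_mm, spacing)
    labels[mask] = LABEL_PLACENTA

    bg_so2 = so2 if background_so2 is None else background_so2
    total = np.zeros(shape)
    total[labels == LABEL_TISSUE] = background_hb_fraction * total_hb
    total[mask] = total_hb
    sat = np.where(mask, so2, bg_so2)

    if texture:
        rng = np.random.default_rng(np.random.SeedSequence(seed))
        rough = rng.standard_normal(shape)
        smooth = ndimage.gaussian_filter(rough, sigma=3.0)
        peak = np.max(np.abs(smooth)) or 1.0
        total = total * (1.0 + texture_amplitude * smooth / peak)

    truth = PhantomTruth(
        c_hb=(1.0 - sat) * total,
        c_hbo2=sat * total,
        labels=labels,
        pixel_spacing_mm=spacing,
    )
    return truth, mask


# ---------------------------------------------------------------------------
# forward simulation


def _structural_image(labels: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """B-mode-like anatomy: per-label mean intensity with multiplicative
    speckle-like noise (gamma distributed, unit mean)."""
    base = np.zeros(labels.shape)
    for lab, mean in _STRUCTURAL_MEANS.items():
        base[labels == lab] = mean
    speckle = rng.gamma(shape=16.0, scale=1.0 / 16.0, size=labels.shape)
    return np.clip(base * speckle, 0.0, 1.0)


def default_noise_sd(
    truth: PhantomTruth,
    table: ExtinctionTable,
    wavelengths: Sequence[float],
    fluence: FluenceModel,
    gamma: float = 1.0,
    snr_db: float = 20.0,
    reference_nm: float = 808.0,
) -> float:
    """Noise sd giving ``snr_db`` amplitude SNR in the placenta at the
    wavelength nearest ``reference_nm``."""
    wl = min(wavelengths, key=lambda w: abs(w - reference_nm))
    mu = LN10 * (epsilon_at(table, wl, "hbo2") * truth.c_hbo2
                 + epsilon_at(table, wl, "hb") * truth.c_hb)
    p = gamma * mu * fluence.at(wl, truth.depth_mm)
    placenta = truth.labels == LABEL_PLACENTA
    signal = float(np.mean(p[placenta])) if placenta.any() else float(np.mean(p))
    return signal / (10.0 ** (snr_db / 20.0))


def forward_pa(
    truth: PhantomTruth,
    table: ExtinctionTable,
    wavelengths: Sequence[float] = DEFAULT_WAVELENGTHS_NM,
    fluence: Optional[FluenceModel] = None,
    gamma: float = 1.0,
    noise_sd: Optional[float] = 0.0,
    seed: int = 0,
    scan_id: str = "",
) -> MultispectralScan:
    """Simulate a multispectral photoacoustic scan of ``truth``.

    ``noise_sd`` is the sd of additive zero-mean Gaussian amplitude noise;
    ``None`` selects the default 20 dB-SNR level (see
    :func:`default_noise_sd`).  Raises :class:`RangeError` if a wavelength
    falls outside the extinction table.
    """
    wavelengths = tuple(float(w) for w in wavelengths)
    if fluence is None:
        fluence = FluenceModel.default(wavelengths)
    if noise_sd is None:
        noise_sd = default_noise_sd(truth, table, wavelengths, fluence, gamma)
    if noise_sd < 0:
        raise ValidationError("noise_sd must be nonnegative")

    rng = np.random.default_rng(np.random.SeedSequence(seed))
    depth = truth.depth_mm
    frames = np.empty((len(wavelengths),) + truth.labels.shape)
    for i, wl in enumerate(wavelengths):
        mu_a = LN10 * (epsilon_at(table, wl, "hbo2") * truth.c_hbo2
                       + epsilon_at(table, wl, "hb") * truth.c_hb)
        frames[i] = gamma * mu_a * fluence.at(wl, depth)
    if noise_sd > 0:
        frames = frames + rng.normal(0.0, noise_sd, size=frames.shape)

    return MultispectralScan(
        frames=frames,
        wavelengths_nm=wavelengths,
        surface_fluence_mj_cm2=tuple(fluence.surface(w) for w in wavelengths),
        structural=_structural_image(truth.labels, rng),
        pixel_spacing_mm=truth.pixel_spacing_mm,
        seed=seed,
        scan_id=scan_id,
    )


# ---------------------------------------------------------------------------
# cohort simulation


@dataclass(frozen=True)
class CohortRecord:
    """One simulated placenta: identity, ground truth, scan and ROI mask."""

    group: str
    animal: str
    gd: int
    placenta: int
    true_so2: float
    scan: MultispectralScan
    mask: np.ndarray


def _cell_rng(design: CohortDesign, *key: int) -> np.random.Generator:
    """Independent, reproducible stream for one design cell."""
    return np.random.default_rng(np.random.SeedSequence(design.seed, spawn_key=key))


def _cell_seed(design: CohortDesign, *key: int) -> int:
    return int(
        np.random.SeedSequence(design.seed, spawn_key=key).generate_state(1)[0] % (2**31)
    )


def draw_cohort_truths(design: CohortDesign) -> pd.DataFrame:
    """Draw per-placenta ground-truth sO2 for the whole design.

    Hierarchy: animal-by-day mean ~ Normal(group/day mean, between_animal_sd),
    placenta ~ Normal(animal mean, within_animal_sd); truths clipped to
    [0.02, 0.98].  Returns a tidy frame with columns
    ``group, animal, gd, placenta, true_so2``.
    """
    rows = []
    for gi, group in enumerate(design.groups):
        for ai in range(design.n_animals_per_group):
            animal = f"{group}{ai + 1:02d}"
            for di, gd in enumerate(design.gestational_days):
                rng = _cell_rng(design, gi, ai, di)
                animal_mean = rng.normal(design.group_mean_so2(group, gd),
                                         design.between_animal_sd)
                truths = np.clip(
                    rng.normal(animal_mean, design.within_animal_sd,
                               size=design.n_placentas_per_animal),
                    0.02, 0.98,
                )
                for pi, s in enumerate(truths):
                    rows.append((group, animal, gd, pi + 1, float(s)))
    return pd.DataFrame(rows, columns=["group", "animal", "gd", "placenta", "true_so2"])


def simulate_cohort(
    design: CohortDesign,
    table: ExtinctionTable,
    fluence: Optional[FluenceModel] = None,
    shape: tuple[int, int] = DEFAULT_SHAPE,
    wavelengths: Sequence[float] = DEFAULT_WAVELENGTHS_NM,
    texture: bool = True,
) -> Iterator[CohortRecord]:
    """Yield one simulated scan per placenta of the design.

    Placental geometry is jittered per placenta (ellipse semi-axes ~8 x 4 mm
    at 5-9 mm depth within the ~30 x 22 mm field); all randomness derives
    deterministically from ``design.seed`` via per-cell spawn keys, so the
    same design reproduces byte-identical scans.  Use
    :func:`draw_cohort_truths` for the matching truth table.
    """
    truths = draw_cohort_truths(design)
    if fluence is None:
        fluence = FluenceModel.default(wavelengths)
    group_index = {g: i for i, g in enumerate(design.groups)}
    day_index = {g: i for i, g in enumerate(design.gestational_days)}

    for row in truths.itertuples(index=False):
        gi = group_index[row.group]
        ai = int(row.animal[len(row.group):]) - 1
        di = day_index[row.gd]
        pi = row.placenta - 1
        geo_rng = _cell_rng(design, gi, ai, di, pi, 0)
        # jittered ~8 x 4 mm ellipse at mid-depth, scaled down if the field
        # of view is smaller than the default 30 x 22 mm
        field_h = shape[0] * DEFAULT_PIXEL_SPACING_MM
        field_w = shape[1] * DEFAULT_PIXEL_SPACING_MM
        surface, margin = 1.0, 0.3
        ay = min(float(geo_rng.uniform(1.8, 2.4)), 0.3 * (field_h - surface))
        ax = min(float(geo_rng.uniform(3.4, 4.6)), 0.3 * field_w)
        cy_lo = surface + ay + margin
        cy_hi = min(field_h - ay - margin, cy_lo + 3.0)
        cx_lo = ax + margin
        cx_hi = field_w - ax - margin
        center = (
            float(geo_rng.uniform(cy_lo, cy_hi)),
            float(geo_rng.uniform(cx_lo, cx_hi)),
        )
        axes = (ay, ax)
        sub_seed = _cell_seed(design, gi, ai, di, pi, 1)
        truth, mask = make_placenta_phantom(
            shape=shape,
            center_mm=center,
            axes_mm=axes,
            so2=row.true_so2,
            total_hb=design.total_hb,
            texture=texture,
            seed=sub_seed,
        )
        scan = forward_pa(
            truth,
            table,
            wavelengths=wavelengths,
            fluence=fluence,
            noise_sd=design.noise_sd,
            seed=sub_seed,
            scan_id=f"{row.group}{ai + 1:02d}_gd{row.gd}_p{row.placenta}",
        )
        yield CohortRecord(row.group, row.animal, int(row.gd), int(row.placenta),
                           float(row.true_so2), scan, mask)


# ---------------------------------------------------------------------------
# synthetic histology


def make_ihc_image(
    shape: tuple[int, int] = (256, 256),
    placenta_mask: Optional[np.ndarray] = None,
    dab_fraction: float = 25.0,
    stain_vectors=None,
    blob_scale: float = 12.0,
    seed: int = 0,
    hematoxylin_od: float = 0.6,
    dab_od: float = 0.9,
    background_intensity: int = 255,
    quantize: bool = True,
) -> IHCImageTruth:
    """Synthesize an H-DAB-stained section with a known DAB-positive area.

    Composition happens in optical-density space: hematoxylin everywhere in
    the mask (with mild smooth texture), DAB on seed-placed smooth blobs
    covering exactly ``round(dab_fraction/100 * mask_pixels)`` pixels, then
    conversion back to transmitted RGB (8-bit if ``quantize``).  The blob
    footprint is the upper level set of a Gaussian-smoothed random field
    (correlation length ``blob_scale`` px), so positives cluster like real
    nuclear staining rather than salt-and-pepper noise.
    """
    from .ihc import StainVectors, od_to_rgb  # local import to avoid a cycle

    if not 0.0 <= dab_fraction <= 100.0:
        raise ValidationError("dab_fraction must be in [0, 100] percent")
    if placenta_mask is None:
        placenta_mask = _ellipse_mask(shape, (shape[0] / 2.0, shape[1] / 2.0),
                                      (shape[0] * 0.38, shape[1] * 0.38), 1.0)
    placenta_mask = placenta_mask.astype(bool)
    if placenta_mask.shape != tuple(shape):
        raise ValidationError("mask shape must match the image shape")
    n_mask = int(placenta_mask.sum())
    if n_mask == 0:
        raise GeometryError("placenta mask is empty")
    vectors = stain_vectors if stain_vectors is not None else StainVectors.hdab()

    rng = np.random.default_rng(np.random.SeedSequence(seed))
    k = int(round(dab_fraction / 100.0 * n_mask))
    field_ = ndimage.gaussian_filter(rng.standard_normal(shape), sigma=blob_scale)
    inside = field_[placenta_mask]
    dab_positive = np.zeros(shape, dtype=bool)
    if k > 0:
        order = np.argsort(inside, kind="stable")[::-1][:k]
        sel = np.zeros(n_mask, dtype=bool)
        sel[order] = True
        dab_positive[placenta_mask] = sel

    hema = np.zeros(shape)
    tex = ndimage.gaussian_filter(rng.standard_normal(shape), sigma=4.0)
    peak = np.max(np.abs(tex)) or 1.0
    hema[placenta_mask] = hematoxylin_od * (1.0 + 0.1 * tex[placenta_mask] / peak)
    hema = np.clip(hema, 0.0, None)
    dab = np.where(dab_positive, dab_od, 0.0)

    amounts = np.stack([hema, dab, np.zeros(shape)], axis=-1)
    od = amounts @ vectors.matrix
    rgb = od_to_rgb(od, background_intensity=background_intensity, quantize=quantize)

    return IHCImageTruth(
        rgb=rgb,
        placenta_mask=placenta_mask,
        true_dab_fraction=100.0 * k / n_mask,
        dab_amount=dab,
        hematoxylin_amount=hema,
    )
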