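"""Quantitative backscatter-SEM analysis of bone cross-sections.

Backscatter gray level is a proxy for local mineral content.  Raw images
are calibrated linearly so that pure-carbon and pure-aluminum standards
(scanned before and after each specimen, means averaged) map to gray
levels 25 and 225.  From the calibrated bone histogram (unit bins) the
mode gives the typical degree of mineralization and the FWHM its
heterogeneity.  Matrix porosity segments below-threshold pixels into
8-connected pores classified by equivalent diameter: > 15 um vascular,
otherwise lacunar.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from skimage import measure

logger = logging.getLogger("micage")

CARBON_TARGET = 25.0
ALUMINUM_TARGET = 225.0
VASCULAR_DIAMETER_UM = 15.0


@dataclass
class BseImage:
    """Raw 16-bit backscatter raster with standards and bone mask."""

    raster: np.ndarray             # 2-D, raw gray levels
    pixel_size_um: float
    bone_mask: np.ndarray          # boolean, same shape
    carbon_means: tuple[float, float]     # patch means (before, after scan)
    aluminum_means: tuple[float, float]

    def __post_init__(self) -> None:
        self.raster = np.asarray(self.raster)
        self.bone_mask = np.asarray(self.bone_mask, dtype=bool)
        if self.pixel_size_um <= 0:
            raise ValueError("pixel size must be positive")
        if self.bone_mask.shape != self.raster.shape:
            raise ValueError("mask shape differs from raster")


@dataclass
class Calibration:
    slope: float
    intercept: float
    carbon_mean: float             # before/after-averaged raw means
    aluminum_mean: float

    def apply(self, raster: np.ndarray) -> np.ndarray:
        return np.clip(self.slope * raster.astype(float) + self.intercept,
                       0.0, 255.0)


@dataclass
class MineralizationProfile:
    histogram: np.ndarray          # counts over 256 unit-width bins
    mode: float                    # calibrated gray level
    fwhm: float                    # gray levels
    degenerate: bool = False
    multimodal: bool = False


@dataclass
class PoreRecord:
    area_um2: float
    equivalent_diameter_um: float
    kind: str                      # 'vascular' | 'lacunar'


@dataclass
class PorosityResult:
    total_pct: float
    lacunar_pct: float
    vascular_pct: float
    pores: list[PoreRecord] = field(default_factory=list)
    threshold: float = float("nan")


# ---------------------------------------------------------------------------
# calibration
# ---------------------------------------------------------------------------

def calibrate(image: BseImage) -> tuple[Calibration, np.ndarray]:
    """Two-point linear calibration sending carbon -> 25, aluminum -> 225.

    Each standard's raw mean is the average of its before- and after-scan
    patch means (compensating beam drift); calibrated values are clipped to
    [0, 255].
    """
    c = float(np.mean(image.carbon_means))
    a = float(np.mean(image.aluminum_means))
    if c >= a:
        raise ValueError("carbon mean >= aluminum mean: inverted contrast")
    slope = (ALUMINUM_TARGET - CARBON_TARGET) / (a - c)
    intercept = CARBON_TARGET - slope * c
    cal = Calibration(slope, intercept, c, a)
    return cal, cal.apply(image.raster)


# ---------------------------------------------------------------------------
# mineralization histogram
# ---------------------------------------------------------------------------

def mineralization_profile(calibrated: np.ndarray,
                           mask: np.ndarray) -> MineralizationProfile:
    """Histogram mode and FWHM of calibrated bone pixels (unit bins).

    The mode is the maximal bin (lowest gray on ties; non-adjacent equal
    maxima raise a multimodality warning); FWHM interpolates the half-max
    crossings flanking the mode linearly between bin centers.  A histogram
    concentrated in one bin is flagged degenerate with FWHM = 1.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask")
    vals = np.asarray(calibrated, dtype=float)[mask]
    hist, _ = np.histogram(vals, bins=np.arange(257) - 0.5)
    peaks = np.flatnonzero(hist == hist.max())
    multimodal = bool(np.any(np.diff(peaks) > 1))
    if multimodal:
        warnings.warn("multimodal mineralization histogram; reporting the "
                      "lowest-gray mode", stacklevel=2)
    mode_bin = int(peaks[0])
    half = hist.max() / 2.0

    # left crossing
    left = float(mode_bin)
    for i in range(mode_bin, -1, -1):
        if hist[i] < half:
            left = i + (half - hist[i]) / (hist[i + 1] - hist[i])
            break
    else:
        i = -1
    found_left = i >= 0
    right = float(mode_bin)
    for j in range(mode_bin, 256):
        if hist[j] < half:
            right = j - (half - hist[j]) / (hist[j - 1] - hist[j])
            break
    else:
        j = 256
    found_right = j < 256
    single_bin = hist.max() == hist.sum()
    degenerate = single_bin or not (found_left and found_right)
    fwhm = (right - left) if not degenerate else 1.0
    if degenerate:
        logger.info("mineralization_profile: degenerate histogram, "
                    "FWHM reported as 1 bin")
    return MineralizationProfile(hist, float(mode_bin), float(fwhm),
                                 degenerate=degenerate, multimodal=multimodal)


# ---------------------------------------------------------------------------
# porosity
# ---------------------------------------------------------------------------

def porosity(calibrated: np.ndarray, mask: np.ndarray, pixel_size_um: float,
             pore_threshold: float | None = None) -> PorosityResult:
    """Matrix porosity from below-threshold pixels within the bone mask.

    Pores are 8-connected components; equivalent diameter
    d = 2 sqrt(area/pi) classifies them (> 15 um vascular, else lacunar).
    Percentages are relative to the full mask area (matrix plus pores).
    ``pore_threshold`` defaults to Otsu's threshold over the masked pixels
    and must stay below the matrix mode.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask")
    cal = np.asarray(calibrated, dtype=float)
    profile = mineralization_profile(cal, mask)
    if pore_threshold is None:
        # pores (void/resin) backscatter like the carbon standard while
        # matrix sits at the histogram mode, so the midpoint separates the
        # classes robustly even on nearly pore-free sections where
        # histogram-splitting rules (e.g. Otsu) land inside one class
        pore_threshold = (CARBON_TARGET + profile.mode) / 2.0
        logger.info("porosity: default carbon/mode midpoint threshold %.1f",
                    pore_threshold)
    if pore_threshold >= profile.mode:
        raise ValueError(
            f"pore threshold {pore_threshold} >= matrix mode {profile.mode}; "
            "would classify matrix as pore")
    pore_px = (cal < pore_threshold) & mask
    labeled = measure.label(pore_px, connectivity=2)
    px_area = pixel_size_um ** 2
    pores = []
    lac_area = vas_area = 0.0
    for region in measure.regionprops(labeled):
        area = region.area * px_area
        d = 2.0 * np.sqrt(area / np.pi)
        kind = "vascular" if d > VASCULAR_DIAMETER_UM else "lacunar"
        pores.append(PoreRecord(area, d, kind))
        if kind == "vascular":
            vas_area += area
        else:
            lac_area += area
    mask_area = mask.sum() * px_area
    return PorosityResult(
        total_pct=100.0 * (lac_area + vas_area) / mask_area,
        lacunar_pct=100.0 * lac_area / mask_area,
        vascular_pct=100.0 * vas_area / mask_area,
        pores=pores,
        threshold=float(pore_threshold),
    )
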