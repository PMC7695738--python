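"""Color-based pH-front segmentation for dye-stained tissue cross-sections.

Electrolysis of saline-tumesced adipose tissue generates an acid front at the
anode and a base front at the cathode. After sectioning and application of a
halochromic dye the fronts appear as an orange and a blue band on the cut
surface. This module quantifies the lateral extent of each band in millimetres:
the user supplies one region of interest (ROI) inside each colored band, the
band's color statistics are estimated in CIE 1976 L*a*b* space, every pixel of
the image is classified by its Euclidean color distance to the ROI mean, the
resulting boolean mask is cleaned morphologically, and the band width is the
mean number of mask pixels per occupied row, converted to mm with the image
scale.

Re-estimating the ROI color statistics per image makes the segmentation robust
to moderate shifts in ambient lighting and dye intensity, which is why no fixed
reference colors are used.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy import ndimage as ndi
from skimage import morphology

#: IEC 61966-2-1 sRGB (linear) → CIE XYZ matrix, D65 white.
_XYZ_FROM_RGB = np.array([
    [0.4124564, 0.3575761, 0.1804375],
    [0.2126729, 0.7151522, 0.0721750],
    [0.0193339, 0.1191920, 0.9503041],
])
#: Reference white = XYZ of sRGB (1,1,1), so white maps exactly to L*=100,
#: a*=b*=0 under this matrix (self-consistent convention).
_WHITE_XYZ = _XYZ_FROM_RGB.sum(axis=1)


@dataclass
class CalibratedImage:
    """An RGB (H×W×3) or single-channel (H×W) raster with a physical scale.

    Pixel values must be finite and lie in [0, 1]; ``scale_mm_per_px`` is the
    side length of one pixel in millimetres.
    """

    pixels: np.ndarray
    scale_mm_per_px: float
    origin_note: str = "insertion surface on top"

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim not in (2, 3):
            raise ValueError(f"expected H×W or H×W×3 raster, got shape {self.pixels.shape}")
        if self.pixels.ndim == 3 and self.pixels.shape[2] != 3:
            raise ValueError(f"color image must have 3 channels, got {self.pixels.shape[2]}")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("pixel values must be finite")
        if self.pixels.min() < 0 or self.pixels.max() > 1:
            raise ValueError("pixel values must lie in [0, 1]")
        if not self.scale_mm_per_px > 0:
            raise ValueError("scale_mm_per_px must be positive")

    @property
    def shape(self) -> tuple:
        return self.pixels.shape


@dataclass(frozen=True)
class RegionOfInterest:
    """Half-open pixel bounds [row_start, row_end) × [col_start, col_end)."""

    row_start: int
    row_end: int
    col_start: int
    col_end: int

    def __post_init__(self) -> None:
        if self.row_end <= self.row_start or self.col_end <= self.col_start:
            raise ValueError("ROI must contain at least one pixel")
        if self.row_start < 0 or self.col_start < 0:
            raise ValueError("ROI bounds must be nonnegative")

    def validate_within(self, shape: tuple) -> None:
        if self.row_end > shape[0] or self.col_end > shape[1]:
            raise ValueError(f"ROI {self} exceeds image of shape {shape[:2]}")

    def slices(self) -> tuple[slice, slice]:
        return slice(self.row_start, self.row_end), slice(self.col_start, self.col_end)

    @property
    def n_pixels(self) -> int:
        return (self.row_end - self.row_start) * (self.col_end - self.col_start)


@dataclass(frozen=True)
class ColorStats:
    """Mean L*a*b* color of an ROI and its internal color-distance statistics.

    ``mean_distance`` / ``sd_distance`` are the mean and population standard
    deviation of the Euclidean LAB distances from each ROI pixel to the ROI
    mean color.
    """

    mean_lab: tuple[float, float, float]
    mean_distance: float
    sd_distance: float
    n_pixels: int


@dataclass
class FrontMask:
    """Boolean raster marking the pH-altered band at one electrode site."""

    mask: np.ndarray
    site: Literal["anode", "cathode"]


@dataclass
class PhSegmentationSettings:
    """Tunable parameters of the width measurement.

    sd_multiplier
        A pixel is kept when its LAB distance to the ROI mean is at most
        ``mean_distance + sd_multiplier * sd_distance``; 1 reproduces the
        one-SD rule.
    min_component_px
        Connected components smaller than this are treated as debris.
    """

    sd_multiplier: float = 1.0
    min_component_px: int = 25

    def __post_init__(self) -> None:
        if self.sd_multiplier < 0:
            raise ValueError("sd_multiplier must be nonnegative")
        if self.min_component_px < 1:
            raise ValueError("min_component_px must be positive")


@dataclass
class PHWidthResult:
    """Mean anode/cathode pH-front widths in mm plus the intermediate masks."""

    anode_width_mm: float
    cathode_width_mm: float
    anode_mask: FrontMask
    cathode_mask: FrontMask
    params: dict = field(default_factory=dict)


def _srgb_eotf(s: np.ndarray) -> np.ndarray:
    """sRGB companding curve: encoded [0,1] → linear light."""
    return np.where(s <= 0.04045, s / 12.92, ((s + 0.055) / 1.055) ** 2.4)


def _srgb_oetf(lin: np.ndarray) -> np.ndarray:
    lin = np.clip(lin, 0.0, 1.0)
    return np.where(lin <= 0.0031308, lin * 12.92, 1.055 * lin ** (1 / 2.4) - 0.055)


def _lab_f(t: np.ndarray) -> np.ndarray:
    delta = 6.0 / 29.0
    return np.where(t > delta**3, np.cbrt(t), t / (3 * delta**2) + 4.0 / 29.0)


def _lab_f_inv(u: np.ndarray) -> np.ndarray:
    delta = 6.0 / 29.0
    return np.where(u > delta, u**3, 3 * delta**2 * (u - 4.0 / 29.0))


def rgb_to_lab(rgb: np.ndarray) -> np.ndarray:
    """sRGB in [0,1] → CIE 1976 L*a*b* under the D65 sRGB white.

    Convention: sRGB companding, the IEC 61966-2-1 linear-RGB→XYZ matrix, and
    the reference white taken as the XYZ of sRGB (1,1,1) so that pure white
    maps exactly to (100, 0, 0).
    """
    xyz = _srgb_eotf(np.asarray(rgb, dtype=float)) @ _XYZ_FROM_RGB.T
    fxyz = _lab_f(xyz / _WHITE_XYZ)
    lab = np.empty_like(fxyz)
    lab[..., 0] = 116.0 * fxyz[..., 1] - 16.0
    lab[..., 1] = 500.0 * (fxyz[..., 0] - fxyz[..., 1])
    lab[..., 2] = 200.0 * (fxyz[..., 1] - fxyz[..., 2])
    return lab


def lab_to_rgb(lab: np.ndarray) -> np.ndarray:
    """Inverse of :func:`rgb_to_lab`; out-of-gamut values are clipped."""
    lab = np.asarray(lab, dtype=float)
    fy = (lab[..., 0] + 16.0) / 116.0
    fx = fy + lab[..., 1] / 500.0
    fz = fy - lab[..., 2] / 200.0
    xyz = _lab_f_inv(np.stack([fx, fy, fz], axis=-1)) * _WHITE_XYZ
    lin = xyz @ np.linalg.inv(_XYZ_FROM_RGB).T
    return _srgb_oetf(lin)


def convert_rgb_to_lab(image: CalibratedImage) -> np.ndarray:
    """Convert a calibrated sRGB image to CIE 1976 L*a*b* (L* in [0, 100])."""
    if image.pixels.ndim != 3:
        raise ValueError("convert_rgb_to_lab requires an RGB image")
    return rgb_to_lab(image.pixels)


def roi_color_stats(lab: np.ndarray, roi: RegionOfInterest) -> ColorStats:
    """Mean LAB color of the ROI and the distance statistics within it."""
    roi.validate_within(lab.shape)
    patch = lab[roi.slices()].reshape(-1, 3)
    mean_lab = patch.mean(axis=0)
    dists = np.linalg.norm(patch - mean_lab, axis=1)
    return ColorStats(
        mean_lab=tuple(float(v) for v in mean_lab),
        mean_distance=float(dists.mean()),
        sd_distance=float(dists.std()),  # population SD, ddof=0
        n_pixels=patch.shape[0],
    )


def distance_map(lab: np.ndarray, reference: tuple[float, float, float]) -> np.ndarray:
    """Per-pixel Euclidean LAB distance to a reference color."""
    ref = np.asarray(reference, dtype=float)
    return np.linalg.norm(lab - ref, axis=-1)


def segment_by_distance(dmap: np.ndarray, stats: ColorStats, sd_multiplier: float = 1.0) -> np.ndarray:
    """Keep pixels whose color distance is within the ROI's own spread.

    Retains pixels with ``dmap <= mean_distance + sd_multiplier * sd_distance``,
    i.e. pixels no further from the ROI mean color than the ROI's own pixels
    are (up to the multiplier). Returns a boolean raster.
    """
    if sd_multiplier < 0:
        raise ValueError("sd_multiplier must be nonnegative")
    return dmap <= stats.mean_distance + sd_multiplier * stats.sd_distance


def clean_mask(raw: np.ndarray, min_component_px: int = 25) -> np.ndarray:
    """Fill interior holes and drop small disconnected components.

    Holes are filled with a 4-connected background fill; components are
    8-connected and removed when smaller than ``min_component_px``. The
    operation is idempotent.
    """
    filled = ndi.binary_fill_holes(raw)  # default structure = 4-connectivity
    if min_component_px <= 1:
        return filled
    # max_size semantics: removes components with area <= max_size
    return morphology.remove_small_objects(filled, max_size=min_component_px - 1,
                                           connectivity=2)


def mean_row_width(mask: np.ndarray, scale_mm_per_px: float) -> float:
    """Mean mask-pixel count per occupied row, in mm.

    Rows with no mask pixels are excluded from the mean so the result does not
    depend on image padding. An empty mask yields width 0.
    """
    if not scale_mm_per_px > 0:
        raise ValueError("scale must be positive")
    counts = mask.sum(axis=1)
    occupied = counts[counts > 0]
    if occupied.size == 0:
        return 0.0
    return float(occupied.mean() * scale_mm_per_px)


def calibrate_scale(ruler_px_distance: float, ruler_known_mm: float) -> float:
    """mm-per-pixel scale from a ruler of known physical length in the image."""
    if not (ruler_px_distance > 0 and ruler_known_mm > 0):
        raise ValueError("ruler distances must be positive")
    return ruler_known_mm / ruler_px_distance


def _measure_site(
    lab: np.ndarray,
    roi: RegionOfInterest,
    site: Literal["anode", "cathode"],
    scale: float,
    settings: PhSegmentationSettings,
) -> tuple[float, FrontMask]:
    stats = roi_color_stats(lab, roi)
    dmap = distance_map(lab, stats.mean_lab)
    raw = segment_by_distance(dmap, stats, settings.sd_multiplier)
    cleaned = clean_mask(raw, settings.min_component_px)
    width = mean_row_width(cleaned, scale)
    return width, FrontMask(mask=cleaned, site=site)


def measure_ph_widths(
    image: CalibratedImage,
    roi_anode: RegionOfInterest,
    roi_cathode: RegionOfInterest,
    settings: PhSegmentationSettings | None = None,
) -> PHWidthResult:
    """Full pipeline: LAB conversion, per-site segmentation, width in mm.

    The two ROIs must be disjoint; each site is processed independently with
    color statistics re-estimated from its own ROI.
    """
    settings = settings or PhSegmentationSettings()
    if _rois_overlap(roi_anode, roi_cathode):
        raise ValueError("anode and cathode ROIs must be disjoint")
    lab = convert_rgb_to_lab(image)
    anode_w, anode_m = _measure_site(lab, roi_anode, "anode", image.scale_mm_per_px, settings)
    cath_w, cath_m = _measure_site(lab, roi_cathode, "cathode", image.scale_mm_per_px, settings)
    return PHWidthResult(
        anode_width_mm=anode_w,
        cathode_width_mm=cath_w,
        anode_mask=anode_m,
        cathode_mask=cath_m,
        params={
            "sd_multiplier": settings.sd_multiplier,
            "min_component_px": settings.min_component_px,
            "scale_mm_per_px": image.scale_mm_per_px,
        },
    )


def _rois_overlap(a: RegionOfInterest, b: RegionOfInterest) -> bool:
    return (
        a.row_start < b.row_end
        and b.row_start < a.row_end
        and a.col_start < b.col_end
        and b.col_start < a.col_end
    )
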