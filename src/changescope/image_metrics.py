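"""Local contrast-energy and subjective-importance change measures.

The central quantity is the per-pixel local contrast energy: a
Gaussian-window-weighted RMS luminance contrast. For a window centred on a
pixel, with weights ``w_i = exp(-((dx_i^2 + dy_i^2) / (2 sigma^2)))``, the
value is the weighted standard deviation of luminance relative to the
weighted mean::

    ce = sqrt( sum_i w_i (L_i - Lbar)^2 / sum_i w_i ) / Lbar

The ``squared`` variant omits the square root (weighted variance over squared
mean). At image borders the weights are renormalised over the in-bounds
support, so border pixels use a partial window rather than zero-padding.

Change scores for an image pair are computed over an explicit changed-pixel
mask: contrast-energy change is the absolute difference of the region means
of the two contrast-energy maps; subjective-importance change is the sum of
the (0..1) importance-map values over the region.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .errors import (
    DimensionError,
    InvalidParameterError,
    NoChangeError,
    UndefinedContrastError,
)

logger = logging.getLogger(__name__)

__all__ = [
    "ImageGeometry",
    "LuminanceImage",
    "WindowSpec",
    "ChangeRegion",
    "ImportanceMap",
    "ContrastEnergyMap",
    "RegionChangeStats",
    "gaussian_window",
    "contrast_energy_map",
    "contrast_energy_change",
    "subjective_importance_change",
    "diff_region",
    "region_covariates",
    "pixels_to_degrees",
]


@dataclass(frozen=True)
class ImageGeometry:
    """Pixel grid with a pixel-to-degrees-of-visual-angle mapping.

    ``deg_per_px`` is derived from the horizontal extent; the vertical
    mapping is assumed identical (isotropic pixels).
    """

    width_px: int
    height_px: int
    deg_per_px: float

    def __post_init__(self):
        if self.width_px <= 0 or self.height_px <= 0:
            raise InvalidParameterError("image dimensions must be positive")
        if self.deg_per_px <= 0:
            raise InvalidParameterError("deg_per_px must be positive")

    @classmethod
    def from_extent(cls, width_px: int, height_px: int, extent_deg_x: float) -> "ImageGeometry":
        return cls(width_px, height_px, extent_deg_x / width_px)

    @property
    def center_px(self) -> tuple[float, float]:
        """(x, y) of the image centre under 0-based pixel-centre coordinates."""
        return ((self.width_px - 1) / 2.0, (self.height_px - 1) / 2.0)

    @property
    def shape(self) -> tuple[int, int]:
        """(rows, cols) = (height, width)."""
        return (self.height_px, self.width_px)


def pixels_to_degrees(px: float, geom: ImageGeometry) -> float:
    """Convert a pixel distance to degrees of visual angle."""
    return px * geom.deg_per_px


@dataclass
class LuminanceImage:
    """Non-negative 2D luminance values (arbitrary linear units) plus geometry."""

    values: np.ndarray
    geometry: ImageGeometry

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise DimensionError("luminance values must be a 2D array")
        if self.values.shape != self.geometry.shape:
            raise DimensionError(
                f"image shape {self.values.shape} does not match geometry {self.geometry.shape}"
            )
        if np.any(self.values < 0):
            raise InvalidParameterError("luminance values must be non-negative")


@dataclass(frozen=True)
class WindowSpec:
    """Gaussian spatial window: standard deviation and truncated support."""

    sigma_px: float
    truncation_radius_px: int | None = None

    def __post_init__(self):
        if self.sigma_px <= 0:
            raise InvalidParameterError("sigma_px must be positive")
        if self.truncation_radius_px is None:
            object.__setattr__(
                self, "truncation_radius_px", int(math.ceil(3 * self.sigma_px))
            )
        if self.truncation_radius_px < math.ceil(3 * self.sigma_px):
            raise InvalidParameterError(
                "truncation_radius_px must be at least ceil(3*sigma_px)"
            )


@dataclass
class ChangeRegion:
    """Boolean mask of altered pixels for one image pair."""

    mask: np.ndarray
    n_px: int = field(init=False)
    centroid_px: tuple[float, float] = field(init=False)

    def __post_init__(self):
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise DimensionError("mask must be 2D")
        self.n_px = int(self.mask.sum())
        if self.n_px < 1:
            raise InvalidParameterError("change region must contain at least one pixel")
        rows, cols = np.nonzero(self.mask)
        self.centroid_px = (float(cols.mean()), float(rows.mean()))


@dataclass
class ImportanceMap:
    """Average of per-observer binary label maps; values in [0, 1]."""

    values: np.ndarray
    n_observers: int = 5

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise DimensionError("importance map must be 2D")
        if np.any(self.values < 0) or np.any(self.values > 1):
            raise InvalidParameterError("importance values must lie in [0, 1]")
        if self.n_observers < 1:
            raise InvalidParameterError("n_observers must be >= 1")


@dataclass
class ContrastEnergyMap:
    """Per-pixel local contrast energy for one image."""

    values: np.ndarray
    window: WindowSpec
    variant: str = "rms"


def gaussian_window(spec: WindowSpec) -> np.ndarray:
    """Unnormalised Gaussian weight grid of side ``2r+1`` with unit peak."""
    r = spec.truncation_radius_px
    d = np.arange(-r, r + 1, dtype=float)
    dx, dy = np.meshgrid(d, d)
    return np.exp(-(dx**2 + dy**2) / (2.0 * spec.sigma_px**2))


def _gaussian_1d(spec: WindowSpec) -> np.ndarray:
    r = spec.truncation_radius_px
    d = np.arange(-r, r + 1, dtype=float)
    return np.exp(-(d**2) / (2.0 * spec.sigma_px**2))


def contrast_energy_map(
    img: LuminanceImage, spec: WindowSpec, variant: str = "rms"
) -> ContrastEnergyMap:
    """Per-pixel Gaussian-weighted relative luminance contrast.

    ``variant="rms"`` (default) returns the weighted standard deviation over
    the weighted mean; ``variant="squared"`` the weighted variance over the
    squared mean. Border windows are renormalised over in-bounds pixels.

    Raises :class:`UndefinedContrastError` if any window has zero mean
    luminance (contrast is a relative measure and undefined there).
    """
    if variant not in ("rms", "squared"):
        raise InvalidParameterError(f"unknown variant {variant!r}")
    g = _gaussian_1d(spec)
    L = img.values
    # Separable correlation; constant-0 padding plus division by the
    # in-bounds weight sum implements border renormalisation.
    def smooth(a):
        out = ndimage.correlate1d(a, g, axis=0, mode="constant", cval=0.0)
        return ndimage.correlate1d(out, g, axis=1, mode="constant", cval=0.0)

    wsum = smooth(np.ones_like(L))
    # Work on globally centred values: keeps constant images exactly zero.
    offset = L.mean()
    D = L - offset
    m1 = smooth(D) / wsum
    m2 = smooth(D * D) / wsum
    var = np.clip(m2 - m1 * m1, 0.0, None)
    mean = m1 + offset
    if np.any(mean <= 0):
        n_bad = int(np.count_nonzero(mean <= 0))
        raise UndefinedContrastError(
            f"windowed mean luminance is zero at {n_bad} pixel(s); "
            "relative contrast undefined"
        )
    if variant == "rms":
        values = np.sqrt(var) / mean
    else:
        values = var / (mean * mean)
    return ContrastEnergyMap(values=values, window=spec, variant=variant)


def _check_same_geometry(a: LuminanceImage, b: LuminanceImage) -> None:
    if a.geometry != b.geometry:
        raise DimensionError("images do not share a geometry")


def contrast_energy_change(
    orig: LuminanceImage,
    manip: LuminanceImage,
    region: ChangeRegion,
    spec: WindowSpec,
    variant: str = "rms",
    *,
    ce_orig: ContrastEnergyMap | None = None,
    ce_manip: ContrastEnergyMap | None = None,
) -> float:
    """Absolute difference of region-mean local contrast energy of a pair.

    Precomputed maps may be passed to avoid recomputation in batch scoring.
    """
    _check_same_geometry(orig, manip)
    if region.mask.shape != orig.geometry.shape:
        raise DimensionError("region mask does not match image geometry")
    if ce_orig is None:
        ce_orig = contrast_energy_map(orig, spec, variant)
    if ce_manip is None:
        ce_manip = contrast_energy_map(manip, spec, variant)
    m = region.mask
    return float(abs(ce_orig.values[m].mean() - ce_manip.values[m].mean()))


def subjective_importance_change(imap: ImportanceMap, region: ChangeRegion) -> float:
    """Sum of importance-map values over the changed region."""
    if imap.values.shape != region.mask.shape:
        raise DimensionError("importance map and region mask differ in shape")
    return float(imap.values[region.mask].sum())


def diff_region(
    orig: LuminanceImage, manip: LuminanceImage, tol: float | None = None
) -> ChangeRegion:
    """Mask of pixels where the pair differs by more than ``tol``.

    Default tolerance is 0 for integer-valued inputs and 1e-6 otherwise.
    """
    _check_same_geometry(orig, manip)
    if tol is None:
        both_int = np.allclose(orig.values, np.round(orig.values)) and np.allclose(
            manip.values, np.round(manip.values)
        )
        tol = 0.0 if both_int else 1e-6
    mask = np.abs(orig.values - manip.values) > tol
    if not mask.any():
        raise NoChangeError("images are identical within tolerance")
    return ChangeRegion(mask=mask)


@dataclass
class RegionChangeStats:
    """Change scores and balancing covariates for one image pair."""

    ce_change: float
    si_change: float
    size_px: int
    eccentricity_deg: float
    mean_contrast: float
    max_contrast: float
    min_contrast: float
    luminance_change: float
    sf_change: float

    def covariate_dict(self) -> dict[str, float]:
        """Covariates used for condition balancing (change scores excluded)."""
        return {
            "size_px": float(self.size_px),
            "eccentricity_deg": self.eccentricity_deg,
            "mean_contrast": self.mean_contrast,
            "max_contrast": self.max_contrast,
            "min_contrast": self.min_contrast,
            "luminance_change": self.luminance_change,
            "sf_change": self.sf_change,
        }


def _radial_amplitude(patch: np.ndarray) -> np.ndarray:
    """Radially binned 2D Fourier amplitude of a Hann-tapered patch."""
    h, w = patch.shape
    taper = np.outer(np.hanning(h), np.hanning(w))
    amp = np.abs(np.fft.fft2(patch * taper))
    ky = np.fft.fftfreq(h) * h
    kx = np.fft.fftfreq(w) * w
    r = np.rint(np.hypot(*np.meshgrid(kx, ky))).astype(int)
    return np.bincount(r.ravel(), weights=amp.ravel())


def _sf_change(orig: np.ndarray, manip: np.ndarray, mask: np.ndarray) -> float:
    rows, cols = np.nonzero(mask)
    r0, r1 = rows.min(), rows.max() + 1
    c0, c1 = cols.min(), cols.max() + 1
    a = _radial_amplitude(orig[r0:r1, c0:c1])
    b = _radial_amplitude(manip[r0:r1, c0:c1])
    n = max(len(a), len(b))
    a = np.pad(a, (0, n - len(a)))
    b = np.pad(b, (0, n - len(b)))
    return float(np.median(a - b))


def region_covariates(
    orig: LuminanceImage,
    manip: LuminanceImage,
    region: ChangeRegion,
    spec: WindowSpec,
    *,
    imap: ImportanceMap | None = None,
    variant: str = "rms",
    ce_orig: ContrastEnergyMap | None = None,
    ce_manip: ContrastEnergyMap | None = None,
) -> RegionChangeStats:
    """Change scores plus the covariates used to balance the 2x2 design.

    Covariates: region size in pixels; eccentricity of the region centroid
    in degrees; mean/max/min local contrast over the region pooled across
    both images; absolute mean-luminance change; and the median of the
    difference of radially binned Fourier amplitude spectra of the region's
    bounding-box patch (spatial-frequency change).
    """
    _check_same_geometry(orig, manip)
    geom = orig.geometry
    if region.mask.shape != geom.shape:
        raise DimensionError("region mask does not match image geometry")
    if ce_orig is None:
        ce_orig = contrast_energy_map(orig, spec, variant)
    if ce_manip is None:
        ce_manip = contrast_energy_map(manip, spec, variant)
    m = region.mask
    rows, cols = np.nonzero(m)
    if rows.min() == 0 or cols.min() == 0 or rows.max() == geom.height_px - 1 or (
        cols.max() == geom.width_px - 1
    ):
        logger.warning("change region touches the image border; bounding box clipped")
    cx, cy = geom.center_px
    ecc_px = math.hypot(region.centroid_px[0] - cx, region.centroid_px[1] - cy)
    co, cm = ce_orig.values[m], ce_manip.values[m]
    si = subjective_importance_change(imap, region) if imap is not None else float("nan")
    return RegionChangeStats(
        ce_change=float(abs(co.mean() - cm.mean())),
        si_change=si,
        size_px=region.n_px,
        eccentricity_deg=pixels_to_degrees(ecc_px, geom),
        mean_contrast=float((co.mean() + cm.mean()) / 2.0),
        max_contrast=float(max(co.max(), cm.max())),
        min_contrast=float(min(co.min(), cm.min())),
        luminance_change=float(abs(orig.values[m].mean() - manip.values[m].mean())),
        sf_change=_sf_change(orig.values, manip.values, m),
    )
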