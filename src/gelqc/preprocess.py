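"""Image loading, cropping, and cleanup for gel densitometry.

The processing chain mirrors standard gel-image practice: normalize
polarity so bands are bright on a dark background, fill small dark hole
artifacts by grayscale morphological reconstruction, suppress shot noise
with a median filter, then apply a locally adaptive Wiener filter that
smooths aggressively in flat regions and lightly near edges.  A separate
CLAHE step produces a contrast-enhanced image for *display only*: every
quantitative measurement downstream runs on the denoised image.
"""
from __future__ import annotations

import dataclasses

import imageio.v3 as iio
import numpy as np
from scipy import ndimage
from skimage import exposure, morphology

from .errors import InputError, ValidationError

#: Minimum rows/columns accepted when loading a full gel image.
MIN_IMAGE_DIM = 16

_POLARITIES = ("bands_bright", "bands_dark")
_STAGES = ("raw", "denoised", "display")

# ITU-R BT.709 luminance weights, as used by skimage.color.rgb2gray.
_LUMA = np.array([0.2125, 0.7154, 0.0721])


@dataclasses.dataclass
class GelImage:
    """A 2-D gel intensity matrix with polarity and provenance metadata.

    Rows are indexed top to bottom: row 0 is the well end and migration
    distance increases with the row index.  Intensities live in [0, 1].
    From stage ``denoised`` onward the polarity is always
    ``bands_bright`` (the denoiser inverts dark-band images).
    """

    pixels: np.ndarray
    polarity: str = "bands_bright"
    stage: str = "raw"
    source: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2 or self.pixels.size == 0:
            raise ValidationError("GelImage requires a non-empty 2-D matrix")
        lo, hi = float(self.pixels.min()), float(self.pixels.max())
        if lo < 0.0 or hi > 1.0:
            raise ValidationError(
                f"intensities must lie in [0, 1]; got range [{lo:g}, {hi:g}]"
            )
        if self.polarity not in _POLARITIES:
            raise ValidationError(f"unknown polarity {self.polarity!r}")
        if self.stage not in _STAGES:
            raise ValidationError(f"unknown stage {self.stage!r}")
        if self.stage != "raw" and self.polarity != "bands_bright":
            raise ValidationError(
                f"stage {self.stage!r} requires polarity 'bands_bright'"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]


@dataclasses.dataclass(frozen=True)
class RegionOfInterest:
    """0-based half-open pixel bounds of a rectangular crop."""

    row_start: int
    row_stop: int
    col_start: int
    col_stop: int

    def __post_init__(self) -> None:
        if self.row_start < 0 or self.col_start < 0:
            raise ValidationError("ROI bounds must be non-negative")
        if self.row_stop <= self.row_start:
            raise ValidationError(
                f"row_stop ({self.row_stop}) must exceed row_start ({self.row_start})"
            )
        if self.col_stop <= self.col_start:
            raise ValidationError(
                f"col_stop ({self.col_stop}) must exceed col_start ({self.col_start})"
            )

    def validate_within(self, shape: tuple[int, int]) -> None:
        n_rows, n_cols = shape
        if self.row_stop > n_rows:
            raise ValidationError(f"row_stop {self.row_stop} exceeds image rows {n_rows}")
        if self.col_stop > n_cols:
            raise ValidationError(f"col_stop {self.col_stop} exceeds image cols {n_cols}")


def _require_stage(img: GelImage, *stages: str) -> None:
    if img.stage not in stages:
        raise ValidationError(
            f"operation requires image stage in {stages}; got {img.stage!r}"
        )


def load_image(path) -> GelImage:
    """Load a PNG/TIFF/JPEG gel image as a raw :class:`GelImage`.

    Color inputs are collapsed to luminance; integer dtypes are rescaled
    to [0, 1] by their full dtype range.  Polarity is auto-detected
    (``bands_bright`` when the median pixel is darker than the mean, i.e.
    a mostly dark field with few bright features) and recorded but not
    applied — :func:`denoise` performs the inversion.
    """
    try:
        arr = iio.imread(path)
    except (FileNotFoundError, OSError, ValueError) as exc:
        raise InputError(f"cannot read image file {str(path)!r}: {exc}") from exc
    arr = np.asarray(arr)
    if arr.size == 0:
        raise ValidationError(f"image {str(path)!r} is empty")
    if arr.ndim == 3:  # RGB(A) -> luminance, ignoring alpha
        arr = arr[..., :3].astype(float) @ _LUMA
    elif arr.ndim != 2:
        raise ValidationError(f"image {str(path)!r} is not 2-D (shape {arr.shape})")

    if np.issubdtype(arr.dtype, np.integer):
        pixels = arr.astype(float) / float(np.iinfo(arr.dtype).max)
    else:
        pixels = arr.astype(float)
        hi = pixels.max()
        if hi > 1.0:  # float image on an integer-like scale
            pixels = pixels / hi
    pixels = np.clip(pixels, 0.0, 1.0)

    if min(pixels.shape) < MIN_IMAGE_DIM:
        raise ValidationError(
            f"image {str(path)!r} smaller than {MIN_IMAGE_DIM} px in one dimension"
        )
    polarity = "bands_bright" if np.median(pixels) < pixels.mean() else "bands_dark"
    return GelImage(pixels, polarity=polarity, stage="raw", source=str(path))


def crop(img: GelImage, roi: RegionOfInterest) -> GelImage:
    """Return the exact sub-block of ``img`` delimited by ``roi``."""
    roi.validate_within(img.shape)
    block = img.pixels[roi.row_start : roi.row_stop, roi.col_start : roi.col_stop].copy()
    return GelImage(block, polarity=img.polarity, stage=img.stage,
                    source=f"{img.source}|crop{dataclasses.astuple(roi)}")


def fill_holes(pixels: np.ndarray) -> np.ndarray:
    """Fill regional minima not connected to the border.

    Grayscale fill by morphological reconstruction of the complement: the
    output never decreases any pixel, and dark spots enclosed by brighter
    surroundings are raised to the level of their enclosing rim.
    """
    p = np.asarray(pixels, dtype=float)
    seed = p.copy()
    seed[1:-1, 1:-1] = p.max()
    return morphology.reconstruction(seed, p, method="erosion")


def adaptive_wiener(pixels: np.ndarray, size: int = 5) -> np.ndarray:
    """Pixel-wise adaptive Wiener filter.

    Local mean and variance are estimated over a ``size``-square window;
    the noise power is taken as the mean local variance.  Smoothing is
    inversely proportional to the local variance, so flat regions collapse
    to their local mean while strong edges pass nearly untouched.
    Constant images are preserved.
    """
    a = np.asarray(pixels, dtype=float)
    mean = ndimage.uniform_filter(a, size, mode="reflect")
    sq_mean = ndimage.uniform_filter(a * a, size, mode="reflect")
    var = np.maximum(sq_mean - mean * mean, 0.0)
    noise = float(var.mean())
    gain = np.where(var > noise,
                    np.maximum(var - noise, 0.0) / np.maximum(var, 1e-12), 0.0)
    return np.clip(mean + gain * (a - mean), 0.0, 1.0)


def _validate_odd(name: str, value: int) -> None:
    if not isinstance(value, (int, np.integer)) or value < 3 or value % 2 == 0:
        raise ValidationError(f"{name} must be an odd integer >= 3; got {value!r}")


def denoise(img: GelImage, median_size: int = 3, wiener_size: int = 5) -> GelImage:
    """Polarity-normalize and clean a gel image for quantification.

    Applies, in order: inversion when bands are dark, grayscale hole
    filling, median filtering, adaptive Wiener filtering.  Calling it on
    an already denoised image never re-inverts.
    """
    _require_stage(img, "raw", "denoised")
    _validate_odd("median_size", median_size)
    _validate_odd("wiener_size", wiener_size)
    p = img.pixels
    if img.polarity == "bands_dark":
        p = 1.0 - p
    p = fill_holes(p)
    p = ndimage.median_filter(p, size=median_size, mode="reflect")
    p = adaptive_wiener(p, wiener_size)
    return GelImage(np.clip(p, 0.0, 1.0), polarity="bands_bright",
                    stage="denoised", source=f"{img.source}|denoise")


def enhance_contrast(img: GelImage, tiles: int = 8, clip_limit: float = 0.01) -> GelImage:
    """CLAHE contrast enhancement, for visualization/QC overlays only.

    Quantification always runs on the denoised image; this output exists
    so faint bands are visible when reviewing detections.
    """
    _require_stage(img, "denoised")
    if not 0.0 < clip_limit <= 1.0:
        raise ValidationError(f"clip_limit must be in (0, 1]; got {clip_limit!r}")
    if not isinstance(tiles, (int, np.integer)) or tiles < 1:
        raise ValidationError(f"tiles must be a positive integer; got {tiles!r}")
    p = img.pixels
    if p.max() - p.min() <= 0.0:  # nothing to stretch
        out = p.copy()
    else:
        n_rows, n_cols = p.shape
        kernel = (max(1, n_rows // tiles), max(1, n_cols // tiles))
        out = exposure.equalize_adapthist(p, kernel_size=kernel, clip_limit=clip_limit)
    return GelImage(np.clip(out, 0.0, 1.0), polarity="bands_bright",
                    stage="display", source=f"{img.source}|clahe")
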