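"""Automatic lane-boundary detection.

Lanes are assumed vertical.  A Canny edge map (thresholds derived from
Otsu's method on the gradient magnitude) is filtered with a Sobel
operator selective for vertical structure; the per-column response is
summed and the 2·k strongest columns under non-maximum suppression become
the k (left, right) lane boundary pairs.  When detection fails or is
inaccurate, :func:`override_lanes` replaces the boundaries
programmatically — the non-interactive equivalent of adjusting them by
hand.
"""
from __future__ import annotations

import dataclasses

import numpy as np
from scipy import ndimage
from skimage import feature, filters

from .errors import LaneDetectionError, ValidationError
from .preprocess import GelImage, _require_stage

#: Ratio of the Canny low threshold to the Otsu-derived high threshold.
LOW_HIGH_RATIO = 0.4
#: Gaussian smoothing scale (px) used inside the Canny detector.
CANNY_SIGMA = 1.0


@dataclasses.dataclass
class LaneSet:
    """Ordered column boundaries of k vertical lanes.

    ``boundaries`` holds 2·k strictly ascending column indices; consecutive
    pairs (1st–2nd, 3rd–4th, ...) delimit the lanes inclusively.
    """

    boundaries: np.ndarray
    k: int
    ladder_index: int

    def __post_init__(self) -> None:
        self.boundaries = np.asarray(self.boundaries, dtype=int)
        if self.k < 1:
            raise ValidationError(f"lane count k must be >= 1; got {self.k}")
        if self.boundaries.ndim != 1 or len(self.boundaries) != 2 * self.k:
            raise ValidationError(
                f"expected {2 * self.k} boundaries for k={self.k}; "
                f"got {len(np.atleast_1d(self.boundaries))}"
            )
        if np.any(np.diff(self.boundaries) <= 0):
            raise ValidationError("boundaries must be strictly ascending")
        if np.any(self.boundaries < 0):
            raise ValidationError("boundaries must be non-negative column indices")
        widths = self.boundaries[1::2] - self.boundaries[0::2] + 1
        if np.any(widths < 3):
            raise ValidationError(
                f"each lane must span >= 3 columns; widths {widths.tolist()}"
            )
        if not 0 <= self.ladder_index < self.k:
            raise ValidationError(
                f"ladder_index {self.ladder_index} outside [0, {self.k})"
            )

    @property
    def lanes(self) -> list[tuple[int, int]]:
        b = self.boundaries
        return [(int(b[2 * i]), int(b[2 * i + 1])) for i in range(self.k)]

    @property
    def ladder_lane(self) -> tuple[int, int]:
        return self.lanes[self.ladder_index]

    def sample_indices(self) -> list[int]:
        return [i for i in range(self.k) if i != self.ladder_index]


def edge_map(img: GelImage) -> np.ndarray:
    """Canny edge map of a denoised gel image.

    The high hysteresis threshold comes from Otsu's method applied to the
    Sobel gradient magnitude of the Gaussian-smoothed image; the low
    threshold is ``LOW_HIGH_RATIO`` times the high one.
    """
    _require_stage(img, "denoised")
    p = img.pixels
    grad = filters.sobel(ndimage.gaussian_filter(p, CANNY_SIGMA))
    if grad.max() <= 0.0:
        return np.zeros(p.shape, dtype=bool)
    high = float(filters.threshold_otsu(grad))
    low = LOW_HIGH_RATIO * high
    return feature.canny(p, sigma=CANNY_SIGMA, low_threshold=low, high_threshold=high)


def vertical_edge_strength(edges: np.ndarray) -> np.ndarray:
    """Per-column vertical-edge score of a binary edge map.

    A horizontal-derivative Sobel operator responds to vertical edge
    lines; its absolute response summed over rows scores each column in
    proportion to the vertical edge length passing through it.
    """
    e = np.asarray(edges, dtype=float)
    gx = ndimage.sobel(e, axis=1, mode="reflect")
    return np.abs(gx).sum(axis=0)


def detect_lanes(img: GelImage, k: int, ladder_index: int = 0,
                 min_lane_width: int | None = None) -> LaneSet:
    """Locate the 2·k strongest vertical-edge columns and pair them into lanes.

    Columns are selected greedily by score under non-maximum suppression
    (no two selections closer than ``min_lane_width``; ties broken toward
    the lower column index), sorted ascending, and paired consecutively.
    """
    _require_stage(img, "denoised")
    if not isinstance(k, (int, np.integer)) or k < 1:
        raise ValidationError(f"k must be a positive integer; got {k!r}")
    if not 0 <= ladder_index < k:
        raise ValidationError(f"ladder_index {ladder_index} outside [0, {k})")
    n_cols = img.shape[1]
    if min_lane_width is None:
        min_lane_width = max(3, n_cols // (4 * k))
    if min_lane_width < 3:
        raise ValidationError(f"min_lane_width must be >= 3; got {min_lane_width}")
    if n_cols < (2 * k - 1) * min_lane_width + 1:
        raise ValidationError(
            f"image width {n_cols} too small for {k} lanes of width {min_lane_width}"
        )

    scores = vertical_edge_strength(edge_map(img))
    order = np.argsort(-scores, kind="stable")  # ties -> lower column first
    selected: list[int] = []
    for col in order:
        if scores[col] <= 0.0:
            break
        if all(abs(int(col) - c) >= min_lane_width for c in selected):
            selected.append(int(col))
        if len(selected) == 2 * k:
            break
    if len(selected) < 2 * k:
        raise LaneDetectionError(
            f"found only {len(selected)} candidate boundary columns but k={k} lanes "
            f"need {2 * k}; adjust min_lane_width or supply boundaries manually "
            "(override_lanes / --boundaries)"
        )
    return LaneSet(np.sort(selected), k=k, ladder_index=ladder_index)


def override_lanes(ls: LaneSet, new_boundaries, image_width: int | None = None) -> LaneSet:
    """Replace the boundaries of ``ls``, re-validating all invariants."""
    nb = np.asarray(new_boundaries, dtype=int)
    if image_width is not None and nb.size and nb.max() >= image_width:
        raise ValidationError(
            f"boundary {nb.max()} out of bounds for image width {image_width}"
        )
    return LaneSet(nb, k=ls.k, ladder_index=ls.ladder_index)
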