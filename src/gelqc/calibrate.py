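"""Ladder marker localization and pixel-row -> base-pair calibration.

The ladder lane's per-row mean intensity is min–max normalized; its local
maxima are the ladder markers.  Markers are matched to the user-supplied
bp values by row order (topmost peak = largest fragment, since smaller
fragments migrate farther).  The calibration map interpolates bp linearly
against pixel row between markers and extrapolates linearly beyond the
outermost markers, flagging those rows.
"""
from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
from scipy import signal

from .errors import CalibrationError, ValidationError
from .lanes import LaneSet
from .preprocess import GelImage, _require_stage

#: Default minimum peak prominence, as a fraction of the normalized range.
DEFAULT_MIN_PROMINENCE = 0.05
#: Default inter-marker distance = profile_length / (DISTANCE_DIVISOR * n_markers).
DISTANCE_DIVISOR = 3


@dataclasses.dataclass(frozen=True)
class LadderSpec:
    """Marker sizes of a DNA ladder, in bp, strictly descending."""

    bp_values: tuple

    def __post_init__(self) -> None:
        vals = tuple(float(v) for v in self.bp_values)
        object.__setattr__(self, "bp_values", vals)
        if len(vals) < 3:
            raise ValidationError(f"a ladder needs >= 3 markers; got {len(vals)}")
        if any(v <= 0 for v in vals):
            raise ValidationError("ladder bp values must be positive")
        if any(nxt >= prev for prev, nxt in zip(vals, vals[1:])):
            raise ValidationError("ladder bp values must be strictly descending")

    def __len__(self) -> int:
        return len(self.bp_values)

    @classmethod
    def from_string(cls, text: str) -> "LadderSpec":
        return cls(tuple(float(t) for t in text.replace(";", ",").split(",") if t.strip()))


@dataclasses.dataclass
class MarkerLocalization:
    """Detected (or overridden) marker rows matched to ladder bp values."""

    rows: np.ndarray
    bp_values: tuple
    prominences: np.ndarray

    def __post_init__(self) -> None:
        self.rows = np.asarray(self.rows, dtype=int)
        self.prominences = np.asarray(self.prominences, dtype=float)
        if self.rows.ndim != 1 or len(self.rows) != len(self.bp_values):
            raise ValidationError(
                f"{len(np.atleast_1d(self.rows))} rows for {len(self.bp_values)} bp values"
            )
        if len(self.prominences) != len(self.rows):
            raise ValidationError("prominences and rows must have equal length")
        if np.any(np.diff(self.rows) <= 0):
            raise ValidationError("marker rows must be strictly ascending")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"row": self.rows, "bp": list(self.bp_values),
                             "prominence": self.prominences})


def ladder_profile(img: GelImage, ls: LaneSet) -> np.ndarray:
    """Min–max-normalized per-row mean intensity of the ladder lane."""
    _require_stage(img, "denoised")
    left, right = ls.ladder_lane
    prof = img.pixels[:, left : right + 1].mean(axis=1)
    rng = prof.max() - prof.min()
    if rng <= 0.0:
        warnings.warn("ladder lane has a zero-variance profile", stacklevel=2)
        return np.zeros_like(prof)
    return (prof - prof.min()) / rng


def detect_markers(profile: np.ndarray, spec: LadderSpec,
                   min_prominence: float = DEFAULT_MIN_PROMINENCE,
                   min_distance: int | None = None) -> MarkerLocalization:
    """Find ladder markers as local maxima of the normalized profile.

    Keeps the ``len(spec)`` most prominent peaks (prominence ties broken
    toward the lower row) and assigns bp values by row order.
    """
    profile = np.asarray(profile, dtype=float)
    n = len(spec)
    if min_distance is None:
        min_distance = max(1, int(round(len(profile) / (DISTANCE_DIVISOR * n))))
    peaks, props = signal.find_peaks(profile, prominence=min_prominence,
                                     distance=min_distance)
    if len(peaks) < n:
        raise CalibrationError(
            f"found {len(peaks)} candidate marker peaks but the ladder defines {n}; "
            "lower min_prominence/min_distance or supply rows via override_markers"
        )
    if len(peaks) > n:
        keep = np.lexsort((peaks, -props["prominences"]))[:n]
        keep.sort()
        peaks, prom = peaks[keep], props["prominences"][keep]
    else:
        prom = props["prominences"]
    return MarkerLocalization(rows=peaks, bp_values=spec.bp_values, prominences=prom)


def override_markers(ml: MarkerLocalization, new_rows) -> MarkerLocalization:
    """Replace marker rows (manual-adjustment equivalent); prominences become NaN."""
    nr = np.asarray(new_rows, dtype=int)
    return MarkerLocalization(rows=nr, bp_values=ml.bp_values,
                              prominences=np.full(len(np.atleast_1d(nr)), np.nan))


def _piecewise_bp(rows, knot_rows: np.ndarray, knot_bp: np.ndarray) -> np.ndarray:
    """bp at (possibly fractional) rows: linear between knots, linear beyond."""
    r = np.asarray(rows, dtype=float)
    bp = np.interp(r, knot_rows, knot_bp)
    slope_lo = (knot_bp[1] - knot_bp[0]) / (knot_rows[1] - knot_rows[0])
    slope_hi = (knot_bp[-1] - knot_bp[-2]) / (knot_rows[-1] - knot_rows[-2])
    bp = np.where(r < knot_rows[0], knot_bp[0] + slope_lo * (r - knot_rows[0]), bp)
    bp = np.where(r > knot_rows[-1], knot_bp[-1] + slope_hi * (r - knot_rows[-1]), bp)
    return bp


@dataclasses.dataclass
class CalibrationMap:
    """Strictly decreasing pixel-row -> bp map built from marker knots."""

    knot_rows: np.ndarray
    knot_bp: np.ndarray
    n_rows: int
    bp_of_rows: np.ndarray = dataclasses.field(init=False)
    extrapolated: np.ndarray = dataclasses.field(init=False)

    def __post_init__(self) -> None:
        self.knot_rows = np.asarray(self.knot_rows, dtype=float)
        self.knot_bp = np.asarray(self.knot_bp, dtype=float)
        if len(self.knot_rows) < 2:
            raise ValidationError("calibration needs >= 2 markers")
        if np.any(np.diff(self.knot_rows) <= 0):
            raise ValidationError("two markers share a pixel row or rows are unsorted")
        if np.any(np.diff(self.knot_bp) >= 0):
            raise ValidationError("marker bp values must strictly decrease with row")
        rows = np.arange(self.n_rows, dtype=float)
        self.bp_of_rows = _piecewise_bp(rows, self.knot_rows, self.knot_bp)
        self.extrapolated = (rows < self.knot_rows[0]) | (rows > self.knot_rows[-1])
        if self.n_rows > 1 and np.any(np.diff(self.bp_of_rows) >= 0):
            raise ValidationError("calibration map is not strictly decreasing")

    def bp_at_row(self, rows):
        """bp at scalar or array (fractional) row positions."""
        out = _piecewise_bp(rows, self.knot_rows, self.knot_bp)
        return float(out) if np.isscalar(rows) else out

    def row_at_bp(self, bp):
        """Inverse map: fractional row at the given bp value(s)."""
        b = np.asarray(bp, dtype=float)
        # knots reversed so xp ascends; extrapolate with the edge slopes
        kb, kr = self.knot_bp[::-1], self.knot_rows[::-1]
        r = np.interp(b, kb, kr)
        slope_lo = (kr[1] - kr[0]) / (kb[1] - kb[0])
        slope_hi = (kr[-1] - kr[-2]) / (kb[-1] - kb[-2])
        r = np.where(b < kb[0], kr[0] + slope_lo * (b - kb[0]), r)
        r = np.where(b > kb[-1], kr[-1] + slope_hi * (b - kb[-1]), r)
        return float(r) if np.isscalar(bp) else r


def build_calibration(ml: MarkerLocalization, roi_rows: int) -> CalibrationMap:
    """Piecewise-linear bp-vs-row map through the marker knots."""
    if roi_rows < 1:
        raise ValidationError("roi_rows must be positive")
    return CalibrationMap(knot_rows=ml.rows, knot_bp=np.asarray(ml.bp_values),
                          n_rows=int(roi_rows))
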