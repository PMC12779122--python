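"""Synthetic gel-electrophoresis images with exact ground truth.

The simulator renders vertical lanes of constant width on a tilted
background.  Fragment migration follows the standard log-size law

    row(bp) = migration_a + migration_b * (log10(bp_max) - log10(bp)),

so ladder bands become Gaussian bumps (point-spread ``band_sigma`` rows)
at their migration rows, and a log-normal smear — pushed through the law
by change of variables — becomes an exactly Gaussian row profile centered
at the row of its median with spread ``migration_b * sigma_log / ln 10``
rows.  Additive Gaussian noise, a horizontal background gradient, and
dark disc "hole" artifacts inside bright bands complete the image.  Every
render is fully determined by the config seed, and the sidecar
:class:`GroundTruth` carries the true lane boundaries, marker rows, and
closed-form per-lane size distributions.
"""
from __future__ import annotations

import dataclasses
import json
import math

import numpy as np
from scipy.stats import norm

from .errors import ValidationError
from .preprocess import GelImage

#: 14-marker 1-kb-plus-style ladder (bp, descending), 100 bp – 10 kb.
DEFAULT_LADDER_BP = (10000.0, 7000.0, 5000.0, 4000.0, 3000.0, 2000.0, 1500.0,
                     1000.0, 700.0, 500.0, 400.0, 300.0, 200.0, 100.0)

_LN10 = math.log(10.0)


@dataclasses.dataclass(frozen=True)
class BandSample:
    """A discrete band of fragments of one size."""

    bp: float
    amplitude: float = 0.6

    def __post_init__(self) -> None:
        if self.bp <= 0:
            raise ValidationError("band bp must be positive")


@dataclasses.dataclass(frozen=True)
class SmearSample:
    """A log-normal fragment-size distribution (sigma_log in ln units)."""

    median_bp: float = 300.0
    sigma_log: float = 0.35
    amplitude: float = 0.6

    def __post_init__(self) -> None:
        if self.median_bp <= 0 or self.sigma_log <= 0:
            raise ValidationError("smear median_bp and sigma_log must be positive")


def _as_components(spec) -> tuple:
    """Normalize a per-lane sample spec to a tuple of components."""
    if isinstance(spec, (BandSample, SmearSample)):
        return (spec,)
    comps = tuple(spec)
    if not comps or not all(isinstance(c, (BandSample, SmearSample)) for c in comps):
        raise ValidationError("sample spec must be BandSample/SmearSample or a sequence of them")
    return comps


@dataclasses.dataclass
class GelSimConfig:
    """Full description of one synthetic gel; the seed is mandatory."""

    seed: int
    image_height: int = 400
    image_width: int = 300
    k: int = 9
    ladder_index: int = 0
    ladder_bp: tuple = DEFAULT_LADDER_BP
    migration_a: float = 30.0
    migration_b: float = 150.0
    band_sigma: float = 2.0
    lane_width: int = 20
    lane_gap: int = 12
    samples: tuple | None = None  # one spec per non-ladder lane, in lane order
    lane_baseline: float = 0.10
    background_level: float = 0.06
    background_gradient: float = 0.08
    noise_sigma: float = 0.03
    hole_rate: float = 5e-4

    def __post_init__(self) -> None:
        if self.image_height < 1 or self.image_width < 1:
            raise ValidationError("image dimensions must be positive")
        if self.migration_b <= 0:
            raise ValidationError("migration_b must be positive (monotone law)")
        if self.k < 1 or not 0 <= self.ladder_index < self.k:
            raise ValidationError("need k >= 1 and ladder_index in [0, k)")
        if self.lane_width < 3 or self.lane_gap < 1:
            raise ValidationError("lane_width >= 3 and lane_gap >= 1 required")
        self.ladder_bp = tuple(float(v) for v in self.ladder_bp)
        if any(nxt >= prev for prev, nxt in zip(self.ladder_bp, self.ladder_bp[1:])):
            raise ValidationError("ladder_bp must be strictly descending")
        span = self.k * self.lane_width + (self.k - 1) * self.lane_gap
        if span + 2 > self.image_width:
            raise ValidationError(
                f"{self.k} lanes of width {self.lane_width} (gap {self.lane_gap}) "
                f"span {span} px, exceeding image width {self.image_width}"
            )
        if self.samples is None:
            self.samples = tuple(SmearSample() for _ in range(self.k - 1))
        else:
            self.samples = tuple(self.samples)
            if len(self.samples) != self.k - 1:
                raise ValidationError(
                    f"samples must list {self.k - 1} specs (one per non-ladder lane); "
                    f"got {len(self.samples)}"
                )

    @property
    def margin(self) -> int:
        span = self.k * self.lane_width + (self.k - 1) * self.lane_gap
        return (self.image_width - span) // 2

    def lane_columns(self) -> list[tuple[int, int]]:
        out = []
        for i in range(self.k):
            left = self.margin + i * (self.lane_width + self.lane_gap)
            out.append((left, left + self.lane_width - 1))
        return out


def migration_row(bp: float, cfg: GelSimConfig) -> float:
    """Fractional migration row of a fragment of size ``bp``."""
    if np.any(np.asarray(bp) <= 0):
        raise ValidationError("bp must be positive")
    bp_max = max(cfg.ladder_bp)
    return cfg.migration_a + cfg.migration_b * (np.log10(bp_max) - np.log10(bp))


def smear_row_sigma(smear: SmearSample, cfg: GelSimConfig) -> float:
    """Row-axis spread of a log-normal smear under the migration law."""
    return cfg.migration_b * smear.sigma_log / _LN10


def _component_row_profile(comp, cfg: GelSimConfig, rows: np.ndarray) -> np.ndarray:
    if isinstance(comp, BandSample):
        mu, sd = migration_row(comp.bp, cfg), cfg.band_sigma
    else:
        mu, sd = migration_row(comp.median_bp, cfg), smear_row_sigma(comp, cfg)
    return comp.amplitude * np.exp(-0.5 * ((rows - mu) / sd) ** 2)


@dataclasses.dataclass
class GroundTruth:
    """Simulator sidecar: everything downstream detections are tested against."""

    boundaries: np.ndarray          # 2k true boundary columns, ascending
    marker_rows: np.ndarray         # rounded ladder marker rows, ascending
    lane_samples: dict              # lane index -> tuple of sample components
    clean_pixels: np.ndarray        # noise-free render (before noise/holes)
    config: GelSimConfig

    def true_peak_bp(self, lane: int) -> tuple:
        """True peak bp value(s) of a sample lane, descending."""
        out = []
        for comp in self.lane_samples[lane]:
            out.append(comp.bp if isinstance(comp, BandSample) else comp.median_bp)
        return tuple(sorted(out, reverse=True))

    def true_profile(self, lane: int) -> np.ndarray:
        """Noise-free per-row mean intensity of a lane (from the clean render)."""
        cols = self.config.lane_columns()[lane]
        return self.clean_pixels[:, cols[0] : cols[1] + 1].mean(axis=1)

    def true_mass(self, lane: int, lo_bp: float, hi_bp: float) -> float:
        """Analytic fraction of the lane's signal with size in [lo_bp, hi_bp]."""
        comps = self.lane_samples[lane]
        cfg = self.config
        weights, masses = [], []
        for comp in comps:
            if isinstance(comp, BandSample):
                weights.append(comp.amplitude * cfg.band_sigma)
                masses.append(1.0 if lo_bp <= comp.bp <= hi_bp else 0.0)
            else:
                weights.append(comp.amplitude * smear_row_sigma(comp, cfg))
                z_lo = (math.log(lo_bp) - math.log(comp.median_bp)) / comp.sigma_log
                z_hi = (math.log(hi_bp) - math.log(comp.median_bp)) / comp.sigma_log
                masses.append(float(norm.cdf(z_hi) - norm.cdf(z_lo)))
        w = np.asarray(weights)
        return float(np.average(masses, weights=w / w.sum()))

    def to_json_dict(self) -> dict:
        def comp_dict(c):
            d = dataclasses.asdict(c)
            d["kind"] = "band" if isinstance(c, BandSample) else "smear"
            return d

        return {
            "boundaries": self.boundaries.tolist(),
            "marker_rows": self.marker_rows.tolist(),
            "lanes": {str(i): [comp_dict(c) for c in comps]
                      for i, comps in self.lane_samples.items()},
            "ladder_bp": list(self.config.ladder_bp),
            "seed": self.config.seed,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_json_dict(), fh, indent=2, sort_keys=True)


def render_gel(cfg: GelSimConfig) -> tuple[GelImage, GroundTruth]:
    """Render a synthetic gel and its ground truth, deterministically by seed."""
    h, w = cfg.image_height, cfg.image_width
    rows = np.arange(h, dtype=float)
    clean = np.empty((h, w))
    clean[:] = cfg.background_level + cfg.background_gradient * (
        np.arange(w) / max(w - 1, 1))[None, :]

    lane_cols = cfg.lane_columns()
    lane_samples: dict = {}
    sample_iter = iter(cfg.samples)
    for i, (left, right) in enumerate(lane_cols):
        profile = np.full(h, cfg.lane_baseline)
        if i == cfg.ladder_index:
            for bp in cfg.ladder_bp:
                profile += _component_row_profile(BandSample(bp), cfg, rows)
        else:
            comps = _as_components(next(sample_iter))
            lane_samples[i] = comps
            for comp in comps:
                profile += _component_row_profile(comp, cfg, rows)
        clean[:, left : right + 1] += profile[:, None]
    clean = np.clip(clean, 0.0, 1.0)

    rng = np.random.default_rng(cfg.seed)
    noisy = clean + rng.normal(0.0, cfg.noise_sigma, clean.shape)

    bright = np.argwhere(clean > 0.45)
    if len(bright) and cfg.hole_rate > 0:
        n_holes = int(rng.poisson(cfg.hole_rate * len(bright)))
        if n_holes:
            centers = bright[rng.choice(len(bright), size=n_holes, replace=False)]
            yy, xx = np.ogrid[:h, :w]
            for cy, cx in centers:
                radius = int(rng.integers(1, 3))
                disc = (yy - cy) ** 2 + (xx - cx) ** 2 <= radius**2
                noisy[disc] *= 0.2

    img = GelImage(np.clip(noisy, 0.0, 1.0), polarity="bands_bright", stage="raw",
                   source=f"gelsim(seed={cfg.seed})")
    boundaries = np.array([c for pair in lane_cols for c in pair])
    marker_rows = np.rint([migration_row(bp, cfg) for bp in cfg.ladder_bp])
    truth = GroundTruth(boundaries=boundaries,
                        marker_rows=np.sort(marker_rows).astype(int),
                        lane_samples=lane_samples, clean_pixels=clean, config=cfg)
    return img, truth


def agarose_scenario(pct: float, seed: int = 0, **overrides) -> GelSimConfig:
    """Phenomenological stress-test config emulating agarose percentage.

    The single-slope log-size law cannot compress one size range
    selectively, so the scenario shrinks the migration slope and widens
    the band point-spread as ``pct`` departs from 1.0 %: at low
    percentages small fragments lose spatial separation, at high
    percentages large fragments do (the other end of the ladder is then
    mostly off the measurable span).  This is a documented fixture for
    stress-testing detection, not a physical gel model.
    """
    if not 0.5 <= pct <= 2.0:
        raise ValidationError(f"agarose percentage must be in [0.5, 2.0]; got {pct}")
    migration_b = 150.0 - 90.0 * abs(pct - 1.0)
    band_sigma = 2.0 + 2.5 * abs(pct - 1.0)
    return GelSimConfig(seed=seed, migration_b=migration_b, band_sigma=band_sigma,
                        **overrides)


def write_png(img: GelImage, path) -> None:
    """Write a GelImage as an 8-bit grayscale PNG."""
    import imageio.v3 as iio

    iio.imwrite(path, np.rint(img.pixels * 255.0).astype(np.uint8))
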