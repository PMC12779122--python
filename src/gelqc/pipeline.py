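"""End-to-end analysis pipeline and file exports.

:func:`analyze` runs preprocess -> lanes -> calibrate -> quantify on an
in-memory :class:`~gelqc.preprocess.GelImage`; :func:`run` wraps it with
image loading, ROI cropping, and the CSV/PNG/JSON exports.  Stage errors
propagate as :class:`~gelqc.errors.StageError` naming the failed stage,
and no output file is written unless the whole analysis succeeded.
"""
from __future__ import annotations

import contextlib
import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import calibrate as _cal
from . import lanes as _lanes
from . import preprocess as _pre
from . import quantify as _q
from .errors import GelQCError, StageError, ValidationError

log = logging.getLogger("gelqc")


@dataclasses.dataclass
class RunConfig:
    """All parameters of one analysis run (the YAML config schema)."""

    image: str
    k: int
    ladder_index: int
    ladder_bp: tuple
    roi: tuple | None = None                 # (row_start, row_stop, col_start, col_stop)
    smoothing_factor: float = 0.5
    target_range_lo: float = 150.0
    target_range_hi: float = 600.0
    min_peak_prominence: float = 0.05
    min_peak_distance_bp: float = 0.0
    min_peak_area_pct: float = 0.0
    median_size: int = 3
    wiener_size: int = 5
    smoothing_window: int | None = None
    min_lane_width: int | None = None
    marker_min_prominence: float = _cal.DEFAULT_MIN_PROMINENCE
    marker_min_distance: int | None = None
    boundaries: tuple | None = None          # manual lane-boundary override
    marker_rows: tuple | None = None         # manual marker-row override
    outdir: str = "gelqc_out"
    sample_names: tuple | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.smoothing_factor <= 1.0:
            raise ValidationError(
                f"smoothing_factor must be in [0, 1]; got {self.smoothing_factor}")
        if not self.target_range_lo < self.target_range_hi:
            raise ValidationError("target_range_lo must be < target_range_hi")
        self.ladder_bp = tuple(float(v) for v in self.ladder_bp)
        _cal.LadderSpec(self.ladder_bp)  # validates

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        if not isinstance(data, dict):
            raise ValidationError(f"config {str(path)!r} must be a YAML mapping")
        return cls.from_dict(data)


@dataclasses.dataclass
class RunResult:
    """Everything one analysis produced, before any file is written."""

    denoised: _pre.GelImage
    display: _pre.GelImage
    laneset: _lanes.LaneSet
    markers: _cal.MarkerLocalization
    calibration: _cal.CalibrationMap
    profiles: dict                       # lane index -> IntensityProfile
    reports: list                        # QCReport per sample lane


@contextlib.contextmanager
def _stage(name: str):
    log.info("stage %s", name)
    try:
        yield
    except StageError:
        raise
    except GelQCError as exc:
        raise StageError(name, exc) from exc


def _sample_name(cfg: RunConfig, ordinal: int, lane: int) -> str:
    if cfg.sample_names is not None and ordinal < len(cfg.sample_names):
        return str(cfg.sample_names[ordinal])
    return f"sample{ordinal + 1:02d}"


def analyze(img: _pre.GelImage, cfg: RunConfig) -> RunResult:
    """Run the full analysis on an in-memory gel image."""
    with _stage("preprocess"):
        den = _pre.denoise(img, cfg.median_size, cfg.wiener_size) \
            if img.stage == "raw" else img
        display = _pre.enhance_contrast(den)

    with _stage("lanes"):
        if cfg.boundaries is not None:
            ls = _lanes.LaneSet(np.asarray(cfg.boundaries, dtype=int),
                                k=cfg.k, ladder_index=cfg.ladder_index)
            if ls.boundaries.max() >= den.shape[1]:
                raise ValidationError("manual boundaries exceed image width")
        else:
            ls = _lanes.detect_lanes(den, cfg.k, cfg.ladder_index, cfg.min_lane_width)

    with _stage("calibrate"):
        spec = _cal.LadderSpec(cfg.ladder_bp)
        prof = _cal.ladder_profile(den, ls)
        if cfg.marker_rows is not None:
            ml = _cal.MarkerLocalization(
                rows=np.asarray(cfg.marker_rows, dtype=int), bp_values=spec.bp_values,
                prominences=np.full(len(cfg.marker_rows), np.nan))
        else:
            ml = _cal.detect_markers(prof, spec, cfg.marker_min_prominence,
                                     cfg.marker_min_distance)
        cal = _cal.build_calibration(ml, roi_rows=den.shape[0])

    with _stage("quantify"):
        profiles: dict = {}
        reports: list = []
        for ordinal, lane in enumerate(ls.sample_indices()):
            p = _q.sample_profile(den, ls, lane, cal)
            p = _q.smooth(p, cfg.smoothing_factor, cfg.smoothing_window)
            profiles[lane] = p
            peaks = _q.call_peaks(p, cfg.min_peak_prominence, cfg.min_peak_distance_bp)
            peaks = _q.peak_areas(p, peaks)
            peaks = _q.filter_peaks_by_area(peaks, cfg.min_peak_area_pct)
            pct = _q.pct_in_range(p, cfg.target_range_lo, cfg.target_range_hi)
            flags = []
            if not peaks:
                flags.append("no-peaks")
            net = np.clip(p.final_intensity - p.baseline, 0.0, None)
            if p.extrapolated is not None and net.sum() > 0 and \
                    net[p.extrapolated].sum() / net.sum() > _q.EXTRAPOLATION_WARN_FRACTION:
                flags.append("extrapolated-signal")
            reports.append(_q.QCReport(
                sample=_sample_name(cfg, ordinal, lane), lane=lane, peaks=peaks,
                pct_in_range=pct, range_lo_bp=cfg.target_range_lo,
                range_hi_bp=cfg.target_range_hi, flags=flags))
    return RunResult(denoised=den, display=display, laneset=ls, markers=ml,
                     calibration=cal, profiles=profiles, reports=reports)


def _qc_table(result: RunResult) -> pd.DataFrame:
    rows = []
    for rep in result.reports:
        if rep.peaks:
            for p in rep.peaks:
                rows.append({"sample": rep.sample, "lane": rep.lane,
                             "peak_bp": p.peak_bp, "peak_intensity": p.peak_intensity,
                             "left_bound_bp": p.left_bound_bp,
                             "right_bound_bp": p.right_bound_bp,
                             "relative_area_pct": p.relative_area_pct,
                             "pct_in_range": rep.pct_in_range,
                             "flags": ";".join(rep.flags)})
        else:
            rows.append({"sample": rep.sample, "lane": rep.lane, "peak_bp": np.nan,
                         "peak_intensity": np.nan, "left_bound_bp": np.nan,
                         "right_bound_bp": np.nan, "relative_area_pct": np.nan,
                         "pct_in_range": rep.pct_in_range,
                         "flags": ";".join(rep.flags)})
    return pd.DataFrame(rows)


def _write_plots(result: RunResult, outdir: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    # annotated detection overlay
    fig, ax = plt.subplots(figsize=(6, 7))
    ax.imshow(result.display.pixels, cmap="gray", aspect="auto")
    for i, (left, right) in enumerate(result.laneset.lanes):
        color = "red" if i == result.laneset.ladder_index else "deepskyblue"
        ax.axvline(left, color=color, lw=0.8)
        ax.axvline(right, color=color, lw=0.8)
    lad_l, lad_r = result.laneset.ladder_lane
    for row, bp in zip(result.markers.rows, result.markers.bp_values):
        ax.plot([lad_l, lad_r], [row, row], color="orange", lw=0.8)
        ax.annotate(f"{bp:g}", (lad_r + 1, row), color="orange", fontsize=5,
                    va="center")
    ax.set_title("lane and ladder-marker detections")
    fig.savefig(outdir / "overlay.png", dpi=150)
    plt.close(fig)

    plots = outdir / "plots"
    plots.mkdir(exist_ok=True)
    for rep in result.reports:
        p = result.profiles[rep.lane]
        fig, ax = plt.subplots(figsize=(6, 3))
        ax.plot(p.bp, p.final_intensity, lw=1.0, label="final")
        ax.plot(p.bp, p.raw_intensity, lw=0.5, alpha=0.5, label="raw")
        for pk in rep.peaks:
            ax.axvline(pk.peak_bp, color="crimson", lw=0.8, ls="--")
            ax.annotate(f"{pk.peak_bp:.0f}", (pk.peak_bp, pk.peak_intensity),
                        fontsize=6, color="crimson")
        ax.set_xscale("log")
        ax.set_xlabel("fragment size (bp)")
        ax.set_ylabel("intensity")
        ax.set_title(rep.sample)
        ax.legend(fontsize=6)
        fig.tight_layout()
        fig.savefig(plots / f"{rep.sample}.png", dpi=150)
        plt.close(fig)

    fig, ax = plt.subplots(figsize=(5, 3))
    names = [r.sample for r in result.reports]
    ax.bar(names, [r.pct_in_range for r in result.reports], color="steelblue")
    lo, hi = result.reports[0].range_lo_bp, result.reports[0].range_hi_bp
    ax.set_ylabel(f"% in [{lo:g}, {hi:g}] bp")
    ax.set_ylim(0, 100)
    ax.tick_params(axis="x", rotation=45, labelsize=7)
    fig.tight_layout()
    fig.savefig(outdir / "pct_in_range.png", dpi=150)
    plt.close(fig)


def write_outputs(result: RunResult, cfg: RunConfig) -> Path:
    """Write per-sample CSVs, the QC table, markers table, plots, and summary."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    samples = outdir / "samples"
    samples.mkdir(exist_ok=True)
    for rep in result.reports:
        p = result.profiles[rep.lane]
        pd.DataFrame({"bp": p.bp, "raw_intensity": p.raw_intensity,
                      "smoothed_intensity": p.smoothed_intensity,
                      "final_intensity": p.final_intensity}).to_csv(
            samples / f"{rep.sample}.csv", index=False)
    _qc_table(result).to_csv(outdir / "qc_table.csv", index=False)
    result.markers.to_frame().to_csv(outdir / "markers.csv", index=False)
    summary = {
        "k": result.laneset.k,
        "ladder_index": result.laneset.ladder_index,
        "boundaries": result.laneset.boundaries.tolist(),
        "marker_rows": result.markers.rows.tolist(),
        "samples": [{"sample": r.sample, "lane": r.lane,
                     "n_peaks": len(r.peaks),
                     "top_peak_bp": r.peaks[0].peak_bp if r.peaks else None,
                     "pct_in_range": r.pct_in_range, "flags": r.flags}
                    for r in result.reports],
    }
    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    _write_plots(result, outdir)
    return outdir


def run(cfg: RunConfig) -> RunResult:
    """Load, crop, analyze, and export one gel image.

    All computation completes before the first output file is written, so
    a failing stage leaves the output directory untouched.
    """
    with _stage("input"):
        img = _pre.load_image(cfg.image)
        if cfg.roi is not None:
            img = _pre.crop(img, _pre.RegionOfInterest(*cfg.roi))
    result = analyze(img, cfg)
    with _stage("export"):
        write_outputs(result, cfg)
    return result
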