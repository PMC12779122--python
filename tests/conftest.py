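import numpy as np
import pytest

import gelqc as g


@pytest.fixture(scope="session")
def default_gel():
    """One default 9-lane simulated gel (ladder + 8 smears), fixed seed."""
    cfg = g.GelSimConfig(seed=7)
    img, truth = g.render_gel(cfg)
    return cfg, img, truth


@pytest.fixture(scope="session")
def denoised_gel(default_gel):
    cfg, img, truth = default_gel
    return cfg, g.denoise(img), truth


@pytest.fixture(scope="session")
def calibrated_gel(denoised_gel):
    """Denoised default gel with detected lanes, markers, and calibration."""
    cfg, den, truth = denoised_gel
    ls = g.detect_lanes(den, k=cfg.k, ladder_index=cfg.ladder_index)
    ml = g.detect_markers(g.ladder_profile(den, ls), g.LadderSpec(cfg.ladder_bp))
    cal = g.build_calibration(ml, den.shape[0])
    return cfg, den, truth, ls, ml, cal


def truth_laneset(cfg, truth):
    """LaneSet built from the simulator's true boundaries."""
    return g.LaneSet(truth.boundaries, k=cfg.k, ladder_index=cfg.ladder_index)


def truth_calibration(cfg, truth, n_rows):
    """Calibration from the true (rounded) marker rows."""
    ml = g.MarkerLocalization(rows=truth.marker_rows, bp_values=cfg.ladder_bp,
                              prominences=np.full(len(cfg.ladder_bp), np.nan))
    return g.build_calibration(ml, n_rows)


@pytest.fixture
def linear_profile_factory():
    """IntensityProfile with bp linear in row, built from a given raw curve."""

    def make(raw, bp_top=1000.0, bp_bottom=100.0, s=0.0, window=None,
             baseline=None):
        raw = np.asarray(raw, dtype=float)
        bp = np.linspace(bp_top, bp_bottom, len(raw))
        if baseline is None:
            baseline = g.quantify.estimate_baseline(raw)
        prof = g.IntensityProfile(bp=bp, raw_intensity=raw, baseline=baseline)
        return g.smooth(prof, s, window)

    return make
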