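# Methods

This note records the models, parameter choices, and numerical decisions
behind `gelqc`, in the spirit of a methods appendix: what is computed, under
which assumptions, and what the validation does and does not demonstrate.

## Image model and pre-processing

A gel image is a 2-D intensity matrix in [0, 1]; row 0 is the well end and
migration distance grows with the row index. Both camera conventions
(bright bands on dark background and the inverse) occur in practice, so
polarity is auto-detected at load time — a mostly dark field with few bright
features has median < mean — and can be overridden by constructing the
`GelImage` explicitly. All downstream code assumes bright bands; `denoise`
inverts dark-band images once and never re-inverts.

The cleanup chain is: grayscale hole filling by morphological
reconstruction (fills dark spots enclosed by brighter surroundings, e.g.
bubbles punched into bands; it never decreases a pixel), a median filter
(default 3 px), and a locally adaptive Wiener filter (default 5 px window).
The Wiener filter estimates local mean/variance per window, takes the mean
local variance as the noise power, and shrinks each pixel toward the local
mean in inverse proportion to local variance, so flat regions are smoothed
hard while band edges survive. It is implemented directly from those local
statistics so that zero-variance (constant) inputs are returned exactly.
Filter sizes follow the common defaults of the equivalent classic filters;
both are exposed in the run config. CLAHE contrast enhancement (8×8 tiles,
clip limit 0.01) is produced for overlays only — every measurement runs on
the denoised image, and results are identical whether or not the display
image is ever computed.

## Lane detection

Lanes are assumed vertical and of roughly constant width; `k` is user
input. A Canny edge map is computed with σ = 1 px; the high hysteresis
threshold comes from Otsu's method on the Sobel gradient magnitude of the
Gaussian-smoothed image (a standard auto-Canny heuristic) and the low
threshold is 0.4× the high. A horizontal-derivative Sobel operator applied
to the edge map scores each column by the total vertical-edge magnitude
passing through it; the 2·k highest-scoring columns are selected under
non-maximum suppression (window = `min_lane_width`, default
image_width/(4k), at least 3; score ties break toward the lower column for
determinism), sorted, and paired consecutively into lanes. Whether edges
should be ranked before or after the vertical-selectivity step is genuinely
open; this implementation ranks the Sobel-filtered scores.

Because the Sobel response to a one-pixel edge line peaks on the columns
adjacent to the line, detected boundaries can sit one to two columns off
the physical lane edge; on simulated gels all 18 boundaries of a 9-lane gel
are recovered within ±2 columns in ≥48/50 seeds. At the ladder lane the
band shoulders rotate the local gradient off-axis and Canny's non-maximum
suppression drops parts of the vertical boundary line (about 30 % of rows);
column scores integrate over all rows, so detection is unaffected. If
fewer than 2·k positive-score columns survive suppression, detection fails
with an explicit error; `override_lanes` (CLI `--boundaries`) is the
programmatic replacement for adjusting detections by hand.

## Ladder calibration

The ladder lane's per-row mean is min–max normalized; markers are its local
maxima (prominence ≥ 0.05 of the normalized range, minimum separation
profile_length/(3·n_markers) — scale-free defaults, both exposed). Surplus
peaks keep the most prominent n (ties toward the lower row); missing peaks
raise a calibration error that names both counts. Rows are matched to the
user's descending bp list in order: topmost peak = largest fragment.

The row→bp map interpolates **linearly in bp against pixel row** between
markers. Physically, migration is close to linear in log size, so the
piecewise-linear map has a chord error between knots; the tests quantify
this against the simulator's exact log-law and bound the map error by the
analytic chord-curve gap. Linear (not log-linear) interpolation is kept
deliberately: it is the behavior of the classic `interp1`-style calibration
this tool emulates, and with a 14-marker ladder the chord error stays below
a few percent over the calibrated span. Rows outside the outermost markers
are extrapolated linearly from the nearest two knots and flagged; metrics
warn when more than 5 % of a lane's signal falls on extrapolated rows. The
map must be strictly decreasing — a violation is a hard failure, never a
silent fix-up.

## Quantification

Sample profiles are per-row lane means. Smoothing is a Gaussian-weighted
moving average (window default: 5 % of the profile length, odd, ≥5;
kernel SD = (window−1)/5) blended as `I = s·I_smooth + (1−s)·I_raw`.
The blend is exact and affine in `s`, and the convolution uses reflected
boundaries so constants are preserved.

**Baseline.** The flat-field baseline is estimated by a one-sided
sigma-clipped mean of the raw profile: rows more than 2 SD above the running
mean (the bands/smears) are excluded over up to 5 iterations, and the mean
of the remaining signal-free rows is returned. The profile *minimum* was
considered and rejected: the minimum of n noisy rows sits ~3 noise SDs below
the floor, and the residual offset left on every row after subtraction
dilutes area fractions by several percent. A constant lane returns the
constant.

**Integration axis.** All areas are trapezoidal integrals of the
baseline-subtracted curve **along the row (migration) axis**. The trace is
signal per pixel row, so its row integral is total signal mass, and area
fractions are mass fractions — the quantity a fragmentation QC range is
meant to capture. Integrating the same trace against the non-uniform bp
coordinate instead would weight each unit of signal by the local bp-per-row
scale (for a log-normal smear this turns the CDF mass into a size-weighted
mass, biased by up to ~8 points at realistic widths) and was rejected.
Residuals are left signed rather than clipped at zero, so zero-mean noise on
signal-free rows cancels under integration instead of rectifying into a
positive bias; reported percentages are clamped to [0, 100].

**Peaks and areas.** Peaks are local maxima of `I` with prominence ≥ 5 % of
(max − baseline); an optional minimum bp separation prunes close peaks
keeping the more prominent. Integration bounds between adjacent peaks sit
at the valley (curve minimum) between them, with the profile ends outermost,
so the segments partition the curve and relative areas sum to exactly 100 %.
`pct_in_range` maps the bp range endpoints to fractional rows through the
calibration and sub-samples the curve linearly at those exact positions.
Noise peaks are a real phenomenon at low smoothing factors; the optional
`min_peak_area_pct` filter (default off) drops peaks below an area share
threshold after integration, which is the recommended mitigation along with
raising `s`.

## The simulator and what passing tests mean

The simulator renders what the analysis assumes: vertical lanes of constant
width (default 9 lanes of 20 px, 12 px gaps, 400×300 px image) on a
horizontally tilted background (level 0.06, tilt 0.08), a faint uniform
lane glow (0.10) that makes boundaries visible as step edges, ladder bands
as Gaussian bumps (SD 2 rows, amplitude 0.6) at rows given by the log-size
law `row = a + b·(log10 bp_max − log10 bp)` with a = 30, b = 150, additive
Gaussian noise (σ = 0.03), and occasional dark "hole" discs inside bright
bands. The default ladder is a 14-marker 1-kb-plus-style set (100–10000 bp).
Sample lanes hold point bands or log-normal smears; a log-normal with
median m and log-SD σ pushed through the migration law is exactly a
Gaussian row profile centered at row(m) with SD b·σ/ln 10, which gives
closed-form ground truth for peak position and for the mass in any bp
interval (a log-normal CDF difference). Default smears use m = 300 bp,
σ = 0.35 — the sonicated-genomic-DNA regime this tool targets, where
~95 % of fragments fall in 150–600 bp. Everything is deterministic in the
config seed.

The "agarose percentage" scenarios are phenomenological stress fixtures,
not gel physics: a single-slope log law cannot compress one size range
selectively, so departing from 1.0 % shrinks the slope (b = 150 − 90·|pct−1|)
and widens the band spread (SD = 2 + 2.5·|pct−1|). They reproduce the
qualitative failure modes of real gels — merged sub-1 kb bands on low-density
gels, merged >2 kb bands on high-density gels — and the tests assert exactly
that ordering, nothing quantitative about agarose chemistry.

Features of real gels the simulator does **not** emulate: tilted or curved
lanes, lane-to-lane bleed, saturation blooming, vignetting or vertical
background gradients, and camera PSF. Passing tests therefore demonstrate
correctness of the algorithms under the stated geometric assumptions, not
robustness to every pathology of bench photographs; the manual-override API
exists precisely for images outside these assumptions.

## Validation sizes and determinism

The automated validation uses desk-scale problem sizes chosen to keep the
whole suite fast while leaving the conclusions stable across seeds: 50
seeded gels for lane recovery (pass = all 18 boundaries within ±2 columns
on ≥48), 20 seeds for ladder recovery (all 14 markers within ±1 px, none
missed or spurious) and for smear peak recovery (mean absolute percent
error < 5 %), 10 smear parameterizations around the 300 bp sonication
regime for the CDF oracle (within 2 points), and analytic two-Gaussian
profiles with 1:1 / 2:1 / 9:1 area ratios (within 1.5 points).
`scripts/acceptance.py` re-runs the same measurements end-to-end from a
single command-line seed. Identical config and seed produce byte-identical
CSV outputs.

## Known limitations

- Boundary localization is biased by up to ~2 columns by the Sobel response
  geometry; lane means over ≥18 columns are insensitive to this.
- Piecewise-linear calibration has a structural chord error between widely
  spaced markers (largest near the small-fragment end of sparse ladders).
- `pct_in_range` monotonicity under range widening holds exactly only for
  noise-free profiles; with signed residuals, noisy signal-free rows can
  perturb it by a fraction of a point.
- Relative peak areas are shares of the valley-partitioned curve; a peak
  removed afterwards by `min_peak_area_pct` does not redistribute its share.
- No molarity/concentration quantitation and no cross-gel normalization.
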