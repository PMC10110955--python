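# Methods

`gpcal` analyzes somatic calcium-imaging recordings from intact cardiac
ganglionated plexi (GP): wide-field Cal-520 movies of GP neurons (and the
glial cells wrapping them) acquired at 10 Hz with 100 ms full-frame
exposure, in which brief cholinergic stimulations evoke ΔF/F₀ transients of
a few percent riding on a photobleaching baseline. This note documents the
models, estimators and numerical choices, what the synthetic-data generator
does and does not emulate, and the known limits of the method.

## Background subtraction and ΔF/F₀

Photobleaching puts a slow monotone decay F₀(t) under every trace. The
correction is two-step:

1. **Moving-average residual.** A centered 200-frame running mean is
   subtracted from the raw trace. The window shrinks *symmetrically* toward
   the trace ends (`h = min(99, i, n-1-i)`), which keeps the running mean
   exact on linear trends at every frame; an asymmetrically truncated window
   would be biased by roughly `slope × half-window` at the edges of a
   bleaching trace and would seed spurious signal regions there.
2. **1D signal mask.** Frames whose residual exceeds `threshold_k` (default
   3) times the noise SD seed signal regions; each region grows outward
   until the residual first falls below a re-entry level (default 0.5 SD),
   so event shoulders do not anchor the background fit. The SD is estimated
   robustly as 1.4826 × MAD of the residual, because a plain SD is inflated
   by the very transients being masked (a plain-SD mode exists for strict
   reproduction). Raising `threshold_k` can only shrink the mask.
3. **Background fit.** A cubic spline is fitted through the unmasked raw
   samples and evaluated at every frame, bridging the masked spans. The
   default is a *least-squares* spline with interior knots every 5 s
   (50 frames): bleaching varies over tens of seconds, so sparse knots track
   it exactly while averaging per-frame noise within each knot interval, and
   masked spans are bridged stably. The fully literal alternative — an
   interpolating spline through every unmasked frame (`mode="interpolate"`)
   — reproduces noise-free data exactly but propagates anchor noise into
   masked gaps (the gap-entry derivative is set by single noisy frames;
   mid-gap deviation grows like σ × gap/(4·frame)), which we measured as a
   ~24% median amplitude error under the recovery conditions below; it is
   retained for noise-free data and method comparison, not as the default.
   Outside the first/last unmasked frame the boundary value is held.
4. **Normalization.** ΔF/F₀(t) = (F(t) − F₀(t)) / F₀(t) with the
   *time-varying* fitted background as denominator, which makes event
   amplitudes bleach-invariant by construction (verified to 5% across 0–40%
   bleach). A non-positive fitted background is rejected as unphysical.

The procedure is single-pass by default (an optional second pass re-derives
the mask against the fitted background); it is fully deterministic.

## Evoked-response kinetics

For each stimulus, within a post-stimulus window (default 10 s):

- **Baseline**: median of the corrected trace over the 1 s preceding the
  stimulus.
- **Peak and amplitude**: earliest maximal frame in the window; the peak
  *value* is refined by a 5-point least-squares parabola around that frame,
  because the raw frame maximum rides the largest noise excursion and is
  biased upward by roughly the noise SD (the parabola rounds a true kink,
  e.g. a triangular apex, by ~3%). Amplitude = refined peak − baseline; a
  response that never exceeds baseline reports amplitude 0 and *missing*
  (NaN) durations, never 0 durations.
- **Threshold crossings** at 10/50/90% of amplitude above baseline are
  located on a ×100 cubic-spline upsampling of the window (reported
  durations are routinely shorter than the 100 ms frame, so sub-frame
  interpolation is required). FWHM spans the first up- to the last
  down-crossing of the 50% level (robust to multi-peak responses); rise
  uses the contiguous ascent into the absolute peak (last excursion below
  10% before the peak → first 90% crossing after it); decay uses the first
  sustained descent (first drop below 90%; the 10% crossing must stay below
  the level for >1.5 frames so single noisy frames on the shallow tail
  cannot pull it early).
- **Exposure deconvolution.** Full-frame integration widens a fast ascent
  approximately in quadrature; the reported rise is
  √(rise² − (0.92·Δt)²), floored at 20% of the raw value. The coefficient
  was calibrated on noise-free boxcar-integrated two-exponential transients
  across rise/frame ratios (residual bias ≤ ~11% at half-frame rises, ≤2%
  above one frame). FWHM and decay span several frames in practice and are
  not corrected.

**Epoch summaries.** The acquisition protocol delivers three stimulations
per drug epoch. Two summaries are implemented: `average_epoch` averages the
three measured metrics (missing durations are averaged over the defined
trials, with the count reported), and `measure_epoch` averages the three
*aligned waveforms* sample-wise and measures once. The waveform route is
the pipeline default (`epoch_method="waveform"`): it is what the protocol
describes and it triples the SNR before peak-picking, which matters for
antagonist-blocked responses near the noise floor (~0.008 ΔF/F₀).

**Block quantification.** Percentage remaining = 100 × during/before for
amplitude and FWHM. Response latency is a cell property, so the
antagonist-epoch peak search is confined to ±0.75 s around the cell's own
baseline-epoch peak latency; searching the full 10 s window would bias
weak blocked responses upward by ~1.3 noise SD through max-selection
(measured as ~+9% relative on the median percentage remaining, halved by
the latency constraint). Cells whose antagonist-epoch peak is ≤ 0.01 ΔF/F₀
are flagged out of the duration analysis (`included_in_duration=False`);
cells that never responded at baseline are an error and must be excluded
upstream.

**Spontaneous (glial) events.** Connected supra-threshold regions of the
corrected trace, against `threshold_k` × a noise SD estimated from
successive frame differences (median |ΔF|·1.4826/√2), which stays
calibrated even when events occupy much of the recording — a value-based
MAD is inflated several-fold near the top of the observed rate range.
False positives are controlled by a dual rule (≥2 consecutive frames at
3 SD, or a single frame at 5 SD; pure noise crosses 3 SD about once per
700 frames but 5 SD only ~3×10⁻⁷/frame), and overlapping transients inside
one region are counted as local maxima with ≥1 SD prominence. Evoked
analysis windows are excised before detection and removed from the
duration used for the frequency (reported both in Hz and per minute).
**Sampling limit:** at 10 Hz there is no dip frame between events closer
than ~0.2 s, so rates approaching 1.6 Hz are undercounted by pile-up
(~40% even with a perfect background); recovery within 15% holds at the
observed median rates (~0.3 Hz) at 10 Hz, and across the full range at
≥40 Hz sampling.

## Motion correction and trace extraction

Rigid integer-pixel registration by cross-correlation
(`phase_cross_correlation`, classic normalization) against a reference
frame (default: mean of the first 10 frames; optional subpixel refinement
reports fractional shifts but frames move by the rounded shift). The
reported (dy, dx) is the translation *applied to the frame* to align it
with the reference; exposed borders are edge-filled and a per-frame
valid-pixel fraction is logged. Registration is only defined up to the
reference's own alignment: the shift-recovery benchmark therefore pins the
gauge with a drift-free first second, after which known shifts up to ±5 px
are recovered exactly. An all-constant movie returns zero shifts with a
warning. ROI traces are the arithmetic mean over the label-mask footprint
per frame (linear in the movie, tested against a per-pixel loop).

## Synthetic recordings

The generator is phenomenological — no receptor gating or Ca²⁺ buffering —
and exists so every stage is testable by parameter recovery.

- **Composition**: F(t) = bleach(t) × (1 + evoked(t) + spontaneous(t)),
  evaluated at 1 kHz and averaged into 100 ms frames (emulating full-frame
  exposure), plus per-frame Gaussian noise. The multiplicative form makes
  the injected ΔF/F₀ amplitudes bleach-invariant, so correction errors are
  attributable to the correction. A Poisson shot-noise mode is not
  implemented; noise is additive Gaussian.
- **Bleach**: mono-exponential by default (fraction 0.3, τ = 120 s over a
  recording), bi-exponential available; total fractional decay < 1 and
  monotone by construction.
- **Transients**: difference of exponentials normalized to unit peak —
  two shape degrees of freedom, analytically controllable. Exact kinetics
  (peak time closed-form; crossings by Brent root-finding) provide the
  ground truth; a tabulated shape curve over the tau ratio inverts target
  (FWHM, rise) pairs to kernel taus. The family's rise/FWHM ratio has a
  supremum ≈ 0.2330 (the gamma-pulse limit); requested shapes above it clip
  to the limiting shape.
- **Cohorts**: per-cell amplitude and FWHM are log-normal with group
  medians set to the published WKY/SHR values (amplitude 0.03304 vs
  0.05351 ΔF/F₀; FWHM 0.08611 vs 0.1344 s) and dispersions derived from the
  published median 95% CIs via the asymptotic sampling law of the median
  (σ = ln(hi/lo)/(2·1.96·√(π/2n)); amplitude σ ≈ 0.91/1.06, FWHM
  σ ≈ 0.34/0.46 — cross-checked against the published 25/75 percentiles).
  The rise/FWHM ratio is log-normal (σ = 0.30, matching the decay-implied
  dispersion; the published rise CI is internally inconsistent with its own
  point estimate and was not used), clipped to the realizable range with
  its scale solved (Gauss–Hermite quadrature + Brent) so the *post-clip*
  rise median hits the configured value — the WKY target ratio sits 0.3%
  below the supremum, so naive clipping would shift the rise median by
  −10%. With this calibration the emergent 90–10% decay medians land at
  0.1187/0.1995 s, within 0.4%/1.4% of the published 0.1183/0.1967 s:
  decay is not a free knob (two shape dof), but the two-exponential pulse
  turns out to be consistent with all four reported medians. Each epoch
  delivers three stimulations with 10% log-normal trial-to-trial amplitude
  jitter; antagonist-epoch amplitudes scale by a per-cell block fraction
  (log-normal, median per genotype — presets 0.259/0.275 — σ = 0.5,
  capped at 1). Default noise is 0.2% of the initial fluorescence: the
  protocol's >0.01 ΔF/F₀ detectability filter requires 3·SD well below
  0.01, and the ~0.008 ΔF/F₀ blocked responses must remain measurable.
- **Ground truth**: every injected event appears exactly once, with dense
  exact kinetics; per-cell-epoch tables carry the exact mean of the trial
  amplitudes (the quantity epoch averaging estimates).
- **Movies**: ROI footprints painted with trace values on a flat
  background, rigid integer jitter applied per frame, true shifts returned;
  footprints must stay inside the frame under maximal jitter.

What the generator does **not** emulate: dye loading heterogeneity,
out-of-focus and neuropil contamination, correlated (shot/photon) noise,
non-rigid tissue motion, overlapping ROIs, and any receptor-level dynamics.
Passing recovery tests therefore demonstrates the estimators are correct
and well-conditioned under the stated statistical structure, not that real
recordings meet that structure.

## Statistics

Unit of analysis is the cell, as in the source cohorts (animal-level
clustering is reported in the tables but not modeled). A Shapiro–Wilk gate
(α = 0.05, any group rejecting → nonparametric; n < 3 or zero variance →
nonparametric with a warning) is logged; the right-skewed kinetic metrics
take the nonparametric branch. Two-group comparisons are two-sided
Mann–Whitney U — exact null when the smaller group has ≤ 8 observations and
no ties, tie-corrected normal approximation otherwise — with medians and
distribution-free order-statistic 95% CIs (ranks (l, n−l+1) with
l the largest rank keeping BinomCDF(l−1; n, ½) ≤ 0.025; for n too small
the full range is returned with its achieved coverage). Distribution-shape
comparisons use the two-sample Kolmogorov–Smirnov test (asymptotic p) with
ECDF tables and 25/75 percentiles (linear interpolation between closest
ranks). The genotype × treatment design uses a two-way ANOVA with Type II
sums of squares (statsmodels OLS; near-balanced data) and cell means ± SE;
an all-identical response vector reports the degenerate limit F = 0, p = 1.
α = 0.05, two-sided, throughout.

## Validation scales and measured behavior

The self-validation benchmarks (`gpcal.benchmarks`, run by
`scripts/acceptance.py` and the test suite) use these problem sizes, chosen
to make the Monte-Carlo error small relative to each tolerance:

- bleach fidelity: 100 bleach-only 60 s traces, noise 0.5% of F;
- kinetic recovery: 500 isolated events, amplitude 0.01–0.15 ΔF/F₀
  (log-uniform), FWHM 0.3–3 s (log-uniform; the resolvable range at
  10 Hz), rise at the study shape ratio 0.23, SNR uniform in 10–30;
- block recovery: 500 cells/group (the median's sampling noise at the
  study's 175 cells would rival the tolerance), block fractions 0.25/0.30;
- statistical layer: exact-MW enumeration on 25 small instances, 1000 null
  replicates at n = 95/80 drawn at the parameter level (the layer under
  test is the statistics, not 1000 full imaging pipelines), 100 KS
  instances;
- power: 200 full-pipeline cohorts at the published effect sizes,
  n = 95/80;
- motion: five 200-frame movies, shifts uniform in ±5 px.

Two measured behaviors worth knowing. First, at 10 Hz the ~0.1 s evoked
transients are broadened by the exposure (measured FWHM medians ~0.135 vs
~0.164 s for true 0.086/0.134 s); the distortion is monotone, so
rank-based genotype comparisons survive it, but absolute FWHM values at
this frame rate overestimate sub-frame truth. Rise times are compressed
toward a common floor and lose genotype contrast at 10 Hz. Second, the
measurement floor truncates the weak tail of the amplitude distribution
(cells below ~3 noise SD measure as ≈0), which *raises* end-to-end
Mann–Whitney power for amplitude (~0.96) above the parameter-level power of
the calibrated distributions (~0.89); both numbers are reported by the
acceptance script.

## Known limitations

- Single-channel, single-plane, rigid-translation motion model only.
- The spline background assumes bleaching varies slowly relative to the
  5 s knot spacing; steps (focus jumps, lamp flicker) are not modeled.
- Sub-frame kinetics at 10 Hz are estimator-limited as described above;
  the exposure deconvolution corrects rise only to ~10% at half-frame
  scales.
- Spontaneous-event counting saturates toward 1.6 Hz at 10 Hz sampling.
- The generator's noise is white Gaussian; correlated noise would raise
  false-event rates above the benchmarked values.
- Recordings longer than 12 min trigger a photo-damage warning, not an
  error.
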