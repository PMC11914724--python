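# Methods

This note documents the models, numerical choices and limitations behind
`ecgrisk`. Everything quantitative stated here is computed by the test suite
or by `scripts/acceptance.py`.

## Synthetic ECG generator

Each beat is a sum of five Gaussian deflections (P, Q, R, S, T) with
amplitudes in mV, centre offsets relative to the R peak in seconds, and
widths in seconds; beats repeat at RR = 60/heart-rate. Defaults follow
textbook surface-ECG morphology (R 1.1 mV / 22 ms width in a unit-weight
lead, T 0.35 mV / 80 ms, P 0.15 mV / 45 ms). A per-lead projection weight
scales the whole beat per lead, approximating a normal electrical axis
(e.g. II 1.0, aVR −0.78, V1 −0.35). Only the 8 independent leads are
simulated; III, aVR, aVL and aVF are always derived through the
Einthoven/Goldberger relations, so the linear lead identities hold exactly
by construction. White noise (default 0.01 mV SD) is added per lead. The
`qrs_scale` parameter widens Q, R and S jointly and stands in for
QRS-duration pathology.

What the generator deliberately does not emulate: baseline wander,
electrode artefacts, rhythm disturbance (every beat is identical), realistic
P/T dispersion across leads, or pathology-specific morphologies. Passing
tests therefore demonstrate the geometric and statistical correctness of
the pipeline, not clinical performance on real ECGs.

### Linked survival outcomes

Cohort subjects draw heart rate and QRS scale uniformly from configurable
ranges (defaults 50–120 bpm, 0.8–1.6). The per-interval hazard is
logistic: logit(h) = logit(h0) + β_hr·z_hr + β_qrs·z_qrs with features
standardized against their sampling ranges, so h ∈ (0,1) by construction.
Defaults: h0 = 0.02 per half-year over a 10-interval (5-year) grid,
β_hr = 1.8, β_qrs = 0 — giving a ~27% five-year event fraction and an
oracle (true-risk) held-out concordance of ≈ 0.86, comfortably above the
0.70 recovery bar so that the discrimination test measures the model, not
the effect size. Censoring is an independent exponential clock (mean
1200 days) applied to 30% of subjects plus administrative censoring at the
horizon. The censoring mechanism is a stand-in: real cohort censoring is
not modelled after any particular registry.

## Renderer

Pages are drawn directly with Pillow so that the mapping from sample index
to pixel is exact and can be saved as ground truth (baseline rows, window
boxes, pixel scales) for oracle tests. Conventions: origin top-left,
y down, positive mV up; 25 mm/s and 10 mm/mV; 1 small box = 1 mm =
8 px by default (2000 px panel centred on a 2200 px page). Grid lines are
drawn at rounded multiples of the pixel pitch — non-integer pitches are
supported and the calibration recovers them to within 2%. Lead labels are
printed inside each band; rhythm strips (default II, V1, V5 — the printed
dialect does not fix them, so they are configurable) occupy full-width
bands below the panel. Scan degradation = small rotation + Gaussian blur +
additive pixel noise, seeded.

## Digitizer

1. **Masks.** Colour pages: trace = all channels < 128; grid = red-dominant
   pixels. Greyscale: trace < 110, grid mid-grey. Thresholds were set on
   synthetic renders and are the main knobs to revisit for other print
   chains.
2. **Deskew.** For skew up to ±2°, the rotation that maximizes the
   sharpness (sum of squared bin counts) of the shear-corrected row
   histogram of trace pixels re-levels the baselines; the page is rotated
   back before any geometry detection.
3. **Calibration.** Small-box pitch = mean spacing of peaks in the grid
   mask's row/column projections (inlier-filtered, so alternating 6/7 px
   spacings average to a fractional pitch). Without a grid, the trace span
   is assumed to cover panel-duration × paper-speed millimetres, with an
   ink-width correction of one trace width.
4. **ROIs.** Lead baselines are the dominant peaks of the trace-pixel row
   histogram (a flat baseline concentrates ink in one row). Row bands are
   delimited by midpoints between neighbouring baselines — a pixel belongs
   to the nearer baseline, ties to the upper lead — which also excludes
   rhythm strips; columns are equal-width time windows from the leftmost
   trace pixel.
5. **Extraction.** Label glyphs are removed as connected components
   narrower than ~5 mm and shorter than ~4 mm. Within a column, ink can
   still form several vertical runs (residual glyph ink, neighbouring-lead
   overshoot); the run that overlaps the previously selected run's vertical
   range is taken — the trace is the one horizontally continuous curve —
   and its darkness-weighted centroid row becomes the sample. The lead
   baseline is the median centroid row of its window. A half-pixel
   horizontal registration offset corrects for the polyline's rightward ink
   extension (configurable per print chain; (width−1)/2 for a 2 px trace).
   Columns without ink are flagged missing; >50% missing columns marks the
   lead unreadable.
6. **Assembly.** Missing columns are linearly interpolated, the pixel-rate
   samples are linearly interpolated onto the 400 Hz grid and then
   band-pass/notch filtered (upsampling precedes filtering so that the
   100 Hz upper band edge is honest relative to the ~200 Hz pixel rate),
   and each lead's 2.5-s window is placed at its column offset in a
   zero-padded 10-s frame, with a per-sample mask distinguishing extracted,
   interpolated and padded samples.

## Filtering

A 3rd-order Butterworth high-pass (0.5 Hz) and low-pass (100 Hz) plus an
IIR notch (60 Hz, Q = 30), all zero-phase. Edge handling uses Gustafsson's
method (initial conditions chosen to minimize edge transients) rather than
reflection padding: on 2.5-s asynchronous windows that end mid-beat,
reflection padding distorts the sub-Hz response of the high-pass enough to
dominate the round-trip error budget at high heart rates; Gustafsson edges
roughly halve it. The identical chain is used for natively digital
preprocessing and inside the digitizer, so digitized-vs-digital comparisons
share one filter response. Resampling is polyphase rational resampling.

## Model inputs

1D: filter → resample → (optional asynchronous column masking on the
unpadded 4000-sample frame) → independent-lead selection → symmetric zero
padding to 4096 (48 zeros per side for 10 s). 2D: luminance conversion →
rhythm-strip crop → area (box-filter) resize to a ladder entry → inversion
to ink ≈ 1 on background ≈ 0 in [0,1]. The 11-entry resolution ladder is
anchored at 1×1, 27×76 and 310×868 with geometric interpolation of each
dimension between anchors.

## Networks and training

Implemented in NumPy with explicit backprop (im2col convolutions, Adam).
The 1D network is a strided stem convolution plus 4 residual blocks
(~42k parameters at default widths); the 2D network is a stem plus
inverted-bottleneck stages whose 3×3 convolution is full rather than
depthwise — at these widths the grouped variant buys nothing. The K-unit
head is zero-initialized so an untrained model predicts h = 0.5 in every
interval (loss K·ln 2), which keeps early optimization well conditioned.
Training: mini-batch Adam, early stopping on validation loss with
best-epoch restoration. BatchNorm is available but off in the 1D
discrimination runs: at a few hundred training subjects it consistently
hurt held-out concordance here. Optional circular time-shift augmentation
(1D) preserves rate and morphology while decorrelating phase and
stabilizes late-epoch generalization on small cohorts. Determinism: all
initialization and shuffling flow from the config seed; results are
reproducible up to floating-point reduction order.

Saliency is the vanilla gradient of the cumulative-hazard risk with respect
to the input, max-reduced over channels; since −ln(1−sigmoid(z)) is
softplus(z), the head's upstream gradient is exactly the hazard vector.

## Cohort handling

Records whose censored follow-up is shorter than 30 days are dropped
(30-day life status unknown; deaths inside 30 days are kept). Splitting is
by subject at 50/10/40, stratified by availability of 5-year life status
(death at any time, or ≥ 5 years of follow-up), with all of a subject's
records confined to one split.

## Evaluation

Digitization fidelity is per-lead Pearson r and MAE (mV) against the source
signal passed through the same filter/resample chain, restricted to the
samples the digitizer actually recovered (in-window); medians/means pool
all leads of all records. The reference choice isolates geometric
digitization error from filter response; comparing over in-window samples
only is a documented choice — including the zero-padded frame would inflate
r. The concordance index is Harrell's C with comparable pairs
(t_i < t_j, event_i = 1), risk ties counted ½, equal-time event pairs not
comparable, and a percentile bootstrap CI over records. Problem sizes used
by the shipped benchmarks: 50 records for the round trip, 500 subjects for
discrimination recovery, chosen as the smallest sizes at which the measured
quantities are stable.

## Known limitations

- Only the 3×4 (+ up to 3 rhythm strips) layout is supported; multi-page
  PDFs and vendor typography are out of scope (pages are consumed as
  rasters).
- Mask thresholds are tuned for the synthetic dialects (black trace, red or
  grey grid on white); heavily discoloured scans will need new masks.
- The label-permutation control shows a single-feature subtlety: with only
  one learnable risk factor in the data, a model amplifies whatever chance
  association a single permutation leaves in the training labels, so the
  null is evaluated as the mean over several whole-cohort permutations.
- Desk-scale networks and cohorts demonstrate recovery of a known risk
  ranking; they say nothing about performance at clinical scale.
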