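# ecgrisk

Most AI-ECG mortality models consume natively digital 12-lead waveforms, but
much of the world stores ECGs as printed pages or PDF rasters. `ecgrisk`
implements the three routes from an ECG to a time-to-mortality risk estimate
in one testable toolkit:

1. **natively digital 1D** — band-pass 0.5–100 Hz, 60 Hz notch, resample to
   400 Hz, zero-pad each lead to 4096 samples, keep the 8 independent leads
   (I, II, V1–V6), feed a residual 1D CNN;
2. **digitized 1D** — recover calibrated signals from a paper-format image
   (grid-pitch calibration, per-lead ROI detection, label-glyph removal,
   darkness-weighted trace extraction, interpolation, the same filter chain)
   and feed the same 1D network in the asynchronous 2.5-s format;
3. **image 2D** — greyscale the page, crop the rhythm strips, resize down a
   ladder of resolutions (1×1 … 27×76 … 310×868 px) and feed a 2D CNN.

Because the hospital data such pipelines are built on are restricted, the
package ships a synthetic generator: Gaussian P-QRS-T beat trains on the 8
independent leads (the four augmented limb leads are always derived via
III = II − I, aVR = −(I+II)/2, aVL = I − II/2, aVF = II − I/2), a pixel-exact
renderer for the hospital page dialect (4×3 panel of 2.5-s leads at
25 mm/s / 10 mm/mV, optional red millimetre grid, three 10-s rhythm strips,
2200×1700 px), scan-degradation transforms, and survival outcomes tied to
signal features through a discrete-time hazard — so the whole
render → digitize → model chain is verifiable end to end at desk scale.

## The survival model

Time is divided into K intervals (default: 10 half-years). A network emits
per-interval conditional hazards h_j ∈ (0,1) and is trained on the masked
negative log-likelihood

    L = −Σ_j m_j [ y_j ln h_j + (1−y_j) ln(1−h_j) ]

where y marks the fatal interval and the prefix mask m covers the intervals
a subject was observed in, which is how right-censoring enters. Survival is
S_k = Π_{j≤k}(1−h_j) and the risk score used for concordance is the
cumulative hazard −Σ_j ln(1−h_j). Networks (a residual 1D CNN for 4096×8
signal tensors, an inverted-bottleneck 2D CNN for images) are implemented in
NumPy with explicit backprop, which also makes vanilla-gradient saliency
maps (|∂risk/∂input|) a one-liner.

## Worked example

```python
import ecgrisk as er

sig = er.generate_signal(er.WaveTemplate(), heart_rate=72, seed=5)
page = er.render_paper_ecg(sig)                    # 2200 x 1700 px, grid on
digitized = er.digitize_ecg(page)                  # 12 leads x 10 s @ 400 Hz
report = er.fidelity_metrics(er.filter_resample(sig), digitized)
print(f"page: {page.shape}, grid detected: {digitized.quality['grid_detected']}")
print(f"median per-lead r = {report.median_r:.3f}")
print(f"mean |error| = {report.mean_mae*1000:.1f} uV")
```

prints

```
page: (1700, 2200), grid detected: True
median per-lead r = 0.992
mean |error| = 11.0 uV
```

i.e. the digitizer recovers the printed traces almost exactly: per-lead
Pearson correlation with the filtered source is 0.99 and the mean absolute
amplitude error is ~0.011 mV — about a tenth of one small grid box.

The survival side follows statsmodels conventions — a model object whose
`fit` returns a results object:

```python
model = er.SurvivalCNN(er.NetConfig(seed=0, batch_norm=False,
                                    time_shift_augment=True, lr=3e-3))
fit = model.fit(x_train, targets_train, x_val, targets_val)
print(fit.summary())
risk = fit.predict_risk(x_test)      # higher = earlier predicted death
```

On a 500-subject synthetic cohort whose hazard is driven by heart rate,
this desk-scale network reaches a held-out C-index of ≈ 0.85 against an
oracle (true risk ranking) of ≈ 0.86; with cohort-wide label permutation it
falls to chance (≈ 0.5).

## Command line

Each stage is exposed as a subcommand of `ecgrisk`:

```
ecgrisk simulate  --out cohort/ --n 100 --seed 1
ecgrisk render    --signals cohort/ --out pages/ [--no-grid] [--degrade scan]
ecgrisk digitize  --image pages/S00000.png --out signals/ [--no-grid-fallback]
ecgrisk prep-signals --signals cohort/ --out prep/ [--asynchronous]
ecgrisk prep-images  --in pages/ --ladder default --out resized/
ecgrisk train     --signals cohort/ --out runs/model --seed 0
ecgrisk evaluate  --model runs/model --signals cohort/ --out report.json
ecgrisk roundtrip --n 50 --seed 7 --degrade none --out fidelity.json
```

A YAML file (`--config run.yaml`, one section per subcommand) can preload
any option; unknown keys are rejected.

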