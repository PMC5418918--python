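# fecg

Fetal electrocardiogram (ECG) extraction from direct (scalp) and indirect
(abdominal) recordings, built around a segmented-beat modulation denoiser:
each beat is split into a fixed-length QRS segment and a variable-length
repolarization (TU) segment, TU segments are resampled ("modulated") to a
common length so a median template can be estimated across beats, and the
template is resampled back to each beat's own length for reconstruction.
The time-axis modulation lets the template follow beat-to-beat
repolarization-length changes caused by heart-rate variability, which
fixed-length template methods cannot.

The package provides:

- `fecg.signal_model` — core types (`Trace`, `RPeakSeries`, additive
  decompositions with conservation checks, SNR/correlation/summary reports);
- `fecg.ecg_io` — CSV traces, CSV record directories, a minimal built-in
  WFDB format-16 reader/writer (header + 16-bit signal + beat annotations),
  decomposition output with JSON sidecars;
- `fecg.preprocess` — zero-phase Butterworth band-pass prefilter (0.5–45 Hz);
- `fecg.sbmm` — beat segmentation, segment modulation/demodulation, template
  estimation, and the denoiser itself;
- `fecg.peak_detect` — Pan-Tompkins QRS detection (band-pass, derivative,
  squaring, moving-window integration, adaptive dual thresholds,
  search-back);
- `fecg.extraction` — the direct and indirect extraction cascades and the
  per-channel signal-quality table (amplitudes, DSNR/ISNR1/ISNR2, ρ);
- `fecg.metrics` — beatwise signal amplitude, 4·SD noise amplitude, dB SNR,
  Pearson correlation, Wilcoxon rank-sum, median/quartile summaries
  (midpoint-position percentile convention);
- `fecg.synthgen` — synthetic maternal + fetal mixture generator with exact
  additive ground truth (Gaussian-kernel beats, AR(1) heart-rate
  variability, √RR-scaled T waves, four-component noise model);
- `fecg.cli` — the `fecg` command-line tool.

## CLI

```sh
# generate a synthetic record directory (CSV channels + ground truth)
fecg simulate --out rec/ --seed 1 --duration 30

# run the cascades
fecg extract-direct   --record rec/ --out direct_out/
fecg extract-indirect --record rec/ --out indirect_out/ --channel 1

# per-channel quality table + summary statistics
fecg evaluate --record rec/ --out table.csv --mode pooled
```

All tunables (prefilter band/order, QRS windows, template statistic,
detector constants, simulation parameters) can be set in a YAML config
passed via `--config`; flags override config values.

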