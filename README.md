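# acmap

Analysis pipeline for auditory-cortex two-photon and widefield calcium
imaging, plus synthetic-data generators with planted ground truth so
every stage is testable by parameter recovery.

Stages (one module each under `src/acmap/`):

| module       | what it does |
|--------------|--------------|
| `synth`      | synthetic populations, trial responses, raw/neuropil/spike-probability traces, widefield movies with a planted tonotopic reversal, two-session ensemble data with controlled drift |
| `preprocess` | PSNR neuron filter (20·log10(max(F_raw−F_n)/σ_n), 36 dB), running-repetition exclusion (>1 cm/s, ≥5 clean reps per FOV), wavelet-based amplitude-rescaling control (denoised ×0.86, noise re-added) |
| `tuning`     | PT responsiveness (per-combination pre/post ANOVA, p<0.01), frequency response areas, unimodal/bimodal Gaussian classification by adjusted R² (0.4), best frequency, FWHM bandwidth in octaves |
| `topography` | FOV→global coordinates, local best-frequency IQR within 100 µm (≥5 neighbors), band fractions |
| `widefield`  | percent ΔF/F against a 15 s sliding cubic baseline, z>2 evoked detection (≥4/16 repetitions), per-pixel best-frequency maps, FOV merging, 0.25°-step radial reversal scanning, AC boundary (10 unresponsive pixels in a row), subfield parcellation |
| `ensembles`  | cell vectors (0.4 s / 0.55 s windows), sound×sound Pearson matrices with reliability diagonals, UPGMA + hybrid dynamic tree cut (deepSplit 2.5), cross-week cluster similarity and matched-neuron correlation |
| `stats`      | KS-normality-gated t / Wilcoxon / Mann-Whitney comparisons with mean±SEM reporting and star codes |

Support modules: `protocol` (stimulus schedules: 17 pure tones 4–64 kHz ×
5 SPLs, AM/complex sound sets, widefield tone schedule), `_wavelet`
(periodized sym4 DWT with universal soft threshold), `_treecut` (hybrid
dynamic tree cut with PAM-like assignment).

## CLI

```sh
acmap synth population --seed 1 --out out/pop
acmap synth traces     --config cfg.json --seed 1 --out out/tr
acmap synth widefield  --seed 1 --out out/wf
acmap synth sessions   --seed 1 --out out/sess

acmap preprocess psnr    --traces out/tr/traces.csv --out psnr.csv
acmap preprocess running --traces out/tr/traces.csv --protocol out/tr/protocol.json --out mask.json
acmap preprocess rescale --traces out/tr/traces.csv --out rescaled.csv

acmap tuning fit       --responses responses.csv --out fits.csv
acmap topo iqr         --neurons neurons.csv --out iqr.csv
acmap topo bands       --neurons neurons.csv --out bands.json
acmap widefield bfmap  --movie out/wf/movie.tif --protocol out/wf/protocol.json --out out/bf
acmap ensembles correlate --vectors out/sess/session1.npy --out corr.csv
acmap ensembles cluster   --matrix corr.csv --out clusters.json
```

Config JSON files map onto `acmap.synth.SynthConfig` fields.

## Conventions

- Frequencies are handled internally on the octave axis `log2(f / 4 kHz)`
  (the 17-tone grid is 0, 0.25, …, 4 oct); bandwidths are FWHM in octaves.
- Best-frequency ties break toward the lower frequency, everywhere.
- Thresholds are edge-inclusive exactly as documented: PSNR exactly 36 dB
  is retained, speed exactly 1 cm/s is clean, z exactly 2 is not evoked.
- All generators are deterministic under a fixed `rng_seed`.
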