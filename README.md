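# neurostates

Unsupervised behavioral-state segmentation from two movement sensors and
state-conditioned analyses of local field potentials (LFPs): band power,
directed interactions (Granger causality), and delta-phase → gamma-amplitude
cross-frequency coupling. A synthetic-data generator with known ground truth
stands in for recorded sessions, so every stage is testable end to end.

## What's inside

| module | purpose |
|---|---|
| `neurostates.synth` | ground truth: 3-state Markov chains, symbol streams, lognormal sensor draws, multichannel LFP with planted band content, VAR coupling and phase-amplitude coupling |
| `neurostates.sensors` | pose-table CSV ingestion (scorer/bodyparts/coords dialect), nose-speed, high-passed accelerometer magnitude, step resampling |
| `neurostates.segmentation` | median-split symbolization over {HiHi, HiLo, LoHi, LoLo}; 3-state discrete-emission HMM (Baum–Welch with restarts, Viterbi, canonical sleep/dmn/active labeling), dwell times, manual-label overlap |
| `neurostates.spectral` | 0.5-s epoching, Hann periodogram band power (delta 0.5–4, gamma 40–60, high-gamma 60–150 Hz), delta Hilbert amplitude, high-delta rule `min + (max-min)/2` |
| `neurostates.granger` | segment-aware VAR fitting, AIC order selection (max 20 ms), time-domain and Geweke spectral (conditional) causality, χ²/F significance with Benjamini–Hochberg FDR |
| `neurostates.cfc` | Butterworth band-pass, Hilbert phase/amplitude, amplitude-weighted coupling vector (strength ∈ [0,1], preferred angle) per behavioral state |
| `neurostates.auxstats` | Sarle bimodality coefficient; multi-sample circular common-median test |
| `neurostates.pipeline` / `cli` | config-driven simulate → segment → spectral → granger → cfc → report chain |

## CLI

```sh
neurostates --seed 1 --out out/ all          # full synthetic run
neurostates --config run.yaml --out out/ simulate
neurostates --config run.yaml --out out/ segment
```

Configuration is YAML; all defaults match the reference analysis (0.5-s
epochs and symbol steps, the three bands above, 20-ms max VAR order,
FDR Q = 0.05, 3 states / 4 symbols). Example:

```yaml
n_steps: 2400          # symbol steps to simulate (0.5 s each)
seed: 1
hmm:
  n_restarts: 10
granger:
  Q: 0.05
```

Outputs are plain CSV/TSV/JSON plus a float32+JSON sidecar for the LFP;
`report.json` aggregates everything with the config hash and seed.

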