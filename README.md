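# insdyn

Analysis pipeline for infrared-neural-stimulation (INS)-evoked auditory
thalamocortical dynamics: evoked-LFP dose-response quantification, wavelet
band-power statistics, temporal modulation transfer functions (tMTF), a
modified 0–1 test for chaos with a permutation-entropy stochasticity gate,
bias-corrected mutual information, spike-field coherence (SFC), and Bayesian
hierarchical / piecewise-spline regressions — exercised end-to-end on a
synthetic-data generator that emulates the experimental trial structure
(1 s trials, 200 ms prestimulus, 5-pulse laser trains, 0–4.5 mJ per pulse,
0.2–100 ms interpulse intervals, 30–60 trials per energy condition, LFPs
analyzed at 1526 Hz).

## Modules

| module | contents |
| --- | --- |
| `insdyn.core_data` | `StimulusTrain`, `AnalysisWindows`, `TrialRecording`, `TrialSet`; exact window/sample arithmetic; `save_trialset`/`load_trialset` (manifest.json + float32 LFP matrices + spike CSVs) |
| `insdyn.synthetic_data` | `GeneratorConfig`, `gen_lfp_trialset` (log-linear N1–P2 dose-response, band entrainment, ISI-locked component, 1/f background), `gen_spike_trains` (von Mises phase-locked point process), `gen_dynamics_series`, `gen_regime_features` |
| `insdyn.preprocess` | anti-aliased decimation to 1526 Hz, zero-phase Chebyshev-II 10 Hz high-pass, PSTHs, z ≥ 3.92 unit-responsiveness classifier |
| `insdyn.evoked_response` | N1–P2 detection (±2 SD peak criterion in the train + 150 ms window), onset→P2 RMS, dose-response tables |
| `insdyn.spectral_bands` | analytic Morlet CWT, band power `P_f = 2∫S_f df` (Simpson), dB change from the 200 ms baseline, shuffle-tested Pearson band correlations in 500 µJ energy bins |
| `insdyn.tmtf` | Bluestein (chirp-z) power exactly at the ISI frequency, tMTF = 10·log10(P_s/P_B) with the ±3 dB doubling criterion, <763 Hz Nyquist cutoff, energy-binned proportion tables |
| `insdyn.nonlinear_dynamics` | modified 0–1 chaos test (median-correlation Kc, 100 c-draws from U(π/5, 4π/5), σ = 0.5, N0 = N/10), permutation-entropy stochasticity gate, MI with 21-bin kernel-smoothed densities and quadratic (1/N) bias extrapolation, silhouette-selected K-means regime clustering |
| `insdyn.spike_field` | trial-averaged cross/auto-spectrum SFC, band-averaged SFC tables |
| `insdyn.bayes_models` | conjugate-Gibbs Bayesian linear / hierarchical / piecewise-spline regressions; MAP + 95% HDI summaries (significant ⇔ HDI excludes 0); knot detection from the mean-SFC derivative |
| `insdyn.pipeline`, `insdyn.cli` | staged orchestration with per-stage seeds, CSV/JSON report bundle |

## CLI

```bash
insdyn simulate --config cfg.json --seed 7 --out data/        # synthetic TrialSet
insdyn preprocess --in data/ --out prep/ --rate 1526 --hp 10  # rate + filter
insdyn analyze --seed 3 --out run/ [--config cfg.json] [--in data/]
insdyn chaos --in prep/ --nc 100 --seed 11                    # 0-1 test table
insdyn report --in run/                                       # print summary.json
```

`analyze` runs simulate → preprocess → evoked → spectral → tmtf → nonlinear →
sfc → bayes and writes `dose_response.csv`, `band_power.csv`,
`band_correlations.csv`, `tmtf.csv`, `tmtf_proportions.csv`, `chaos.csv`,
`sfc.csv`, `regressions.csv`, `summary.json`, plus the resolved `config.json`
for provenance. Runs are deterministic given `--seed`.

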