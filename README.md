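# gonogo

Analysis pipeline linking prestimulus EEG frequency components, poststimulus
ERP temporal components, and behaviour in the equiprobable auditory Go/NoGo
task — together with a fully ground-truthed synthetic data generator, so
every stage is verifiable without any archival recordings.

## What it does

- **synth** — simulates continuous 19-channel task EEG (1/f background,
  narrowband delta/alpha/beta oscillators with known topographies and
  per-trial/per-subject amplitude modulation), stimulus-locked ERP
  templates, blink/saccade EOG contamination with known propagation
  coefficients, and button-press behaviour whose subject-level measures
  carry planted Spearman correlations with driver amplitudes (Gaussian
  copula). Writes EDF+ plus a JSON truth record.
- **preprocess** — 0.1–30 Hz zero-phase bandpass, linked-ears
  re-referencing, polyphase down-sampling to 512 Hz, epoch extraction at
  −500..600 ms, an automated EOG-dropout screen, regression-based ocular
  correction (blink/non-blink split on event-related residuals),
  spherical-spline interpolation of up to 3 bad channels, −100..0 ms
  baseline correction, three-step automatic artifact rejection
  (>150 µV, >50 µV jumps, <0.05 µV change in any 100 ms window),
  prestimulus-press rejection and seeded Go/NoGo trial-count matching.
- **behaviour** — trial taxonomy (valid / omission / fast-RT ≤100 ms /
  slow-RT ≥600 ms / commission) and summary measures (error percentages,
  mean RT, RT variability).
- **spectra** — corrected single-sided prestimulus amplitude spectra:
  weighted DC correction, 10% cosine taper (×1.05 correction), zero-padding
  256→512 (×2 correction), DC–30 Hz at 1 Hz resolution.
- **pca** — covariance-matrix PCA with Kaiser-normalised Varimax (temporal)
  or Promax (frequency) rotation, inclusive ≥1.5 %-variance selection,
  µV-scaled loadings and per-subject global mean peak amplitudes.
- **linkage** — all cross-domain Spearman correlations with t-based
  two-tailed p (df = n−2), Bonett–Wright Fisher-z 95 % CIs, and
  significance banding (p ≤ 0.05 significant; 0.05 < p ≤ 0.10 near).

## CLI

All stages share `--seed`, `--out` and (where applicable) `--config` and
`--log-level`:

```sh
gonogo simulate  --out dataset/ --seed 1            # EDFs + truth.json
gonogo preprocess --in dataset/s01.edf --out epochs/ --seed 1
gonogo behaviour --events events.csv --responses responses.csv --out behaviour.csv
gonogo spectra   --epochs epochs/ --out spectra.csv
gonogo fpca      --spectra spectra.csv --out fpca/
gonogo tpca      --erps erps.csv --condition Go --out tpca-Go/
gonogo linkage   --measures measures.csv --out links.csv
gonogo run       --out out/ --seed 1                # full group pipeline
```

`gonogo run` produces `behaviour.csv`, `spectra.csv`, `fpca/`, `tpca-Go/`,
`tpca-NoGo/`, `measures.csv`, `links.csv` and a `manifest.json` with
per-stage trial counts and a config hash; identical config + seed give
byte-identical CSVs.

### EDF annotation convention

Stimulus onsets are stored as `stim:<condition>:<block>` (e.g.
`stim:Go:0`), button presses as `resp`; onsets are in seconds and mapped
back to the nearest sample on read.

## Layout

```
src/gonogo/
  montage.py     # 10-20 positions on the unit sphere
  io_core/       # Recording/EpochSet/MeasureTable, EDF+ I/O, CSV helpers
  synth.py       # synthetic data generator (ground truth)
  preprocess.py  # recording -> matched artifact-free epochs
  behaviour.py   # trial classification + summary measures
  spectra.py     # corrected prestimulus amplitude spectra
  pca.py         # covariance PCA + Varimax/Promax + scaling/selection
  linkage.py     # Spearman rho / p / CI / banding
  pipeline.py    # per-group orchestration
  cli.py         # click CLI
tests/           # unit, property and acceptance suites
scripts/acceptance.py
```
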