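# scgbeat

ECG-free heartbeat detection in seismocardiograms (SCG) by template matching:
a single-heartbeat SCG snippet is slid over the band-passed dorso-ventral
acceleration signal, the normalized cross-correlation (NCC) function is
computed at every lag, and its prominent local maxima mark the heartbeats.
Detections are scored against reference ECG R-peaks (Pan–Tompkins) with a
per-cycle TP/FP/FN/DE taxonomy, and ECG- vs SCG-derived inter-beat intervals
are compared via regression, correlation and Bland–Altman analysis.
A synthetic-record generator with ground-truth beat times makes every stage
testable without external recordings.

## Layout

| module | purpose |
| --- | --- |
| `scgbeat.io_records` | CSV / minimal WFDB record I/O, beat annotations, artifact-interval sidecars |
| `scgbeat.preprocess` | 1 kHz oversampling (linear), zero-phase Butterworth band-pass (SCG 7–30 Hz, ECG 0.5–40 Hz), powerline notch |
| `scgbeat.ecg_reference` | Pan–Tompkins R-peak detection (reference beats) |
| `scgbeat.template_matching` | template selection/suggestion, NCC computation, peak localization (prominence ≥ 0.5, min distance 500 ms) |
| `scgbeat.evaluation` | per-cycle TP/FP/FN/DE classification, sensitivity = 100·TP/(TP+FN+DE), PPV = 100·TP/(TP+FP+DE), IBI pair extraction |
| `scgbeat.stats` | OLS regression, R², Bland–Altman bias and 1.96·SD limits of agreement |
| `scgbeat.synthetic` | simulated SCG+ECG records (damped-oscillation beats, respiratory modulation, configurable SNR) with ground truth |
| `scgbeat.cli` | `scgbeat` command-line entry point |

## CLI

Each pipeline stage is independently scriptable; all artifacts are plain
CSV/JSON.

```bash
# simulate a record with ground truth
scgbeat simulate --duration 60 --hr 70 --snr 40 --seed 1 \
    --out rec.csv --truth truth.csv

# reference R-peaks
scgbeat rpeaks rec.csv --out rpeaks.csv

# NCC detection (explicit template bounds, or --ref for automatic suggestion)
scgbeat detect rec.csv --template 5.30,5.85 --case 1 --out beats.csv
scgbeat detect rec.csv --ref rpeaks.csv --case 1 --out beats.csv

# score detections and compare IBIs
scgbeat evaluate --ref rpeaks.csv --det beats.csv --out report.json
scgbeat agree --pairs pairs.csv --out agreement.json

# or everything at once
scgbeat run rec.csv --out-dir out/
```

`run` writes `rpeaks.csv`, `beats.csv`, `report.json`, `pairs.csv`,
`agreement.json` and `params.json` (every parameter actually used).
A YAML/JSON config file (`--config`) can set any parameter; explicit flags
win. Records are CSV (`t,scg,ecg`, or `scg,ecg` plus `--fs`) or WFDB
`.hea`/`.dat` pairs; optional motion-artifact intervals live in a
`<name>.artifacts.csv` sidecar (`start_s,end_s`) and exclude the overlapped
cardiac cycles from scoring.

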