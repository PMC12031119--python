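# radarvitals

Contactless vital-sign monitoring with an FMCW radar placed lateral to the
body: every range bin that contains a breathing or heartbeat signal is
selected (rather than a single "best" bin) using persistence diagrams —
sublevel-set filtration of the phase series and Vietoris–Rips filtration of
its time-delay embedding — and per-window vital rates are aggregated across
the selected bins by the median.

Because the original overnight recordings are private, the package ships a
labeled FMCW scene simulator (`radarvitals.simulate`) that produces raw IF
chirp cubes or complex range–time matrices together with ground-truth
per-bin labels, rate trajectories and reference belt/ECG traces, so the
whole pipeline is testable at desk scale.

## What is in the box

| module          | role |
|-----------------|------|
| `device`        | FMCW device model (range resolution c/2B, chirp slope, frame timing) |
| `simulate`      | scene → displacement field → IF cube / range–time matrix + ground truth |
| `processing`    | Hanning range FFT, chirp median, arctangent demodulation + unwrapping, 0.4–3 m bin restriction |
| `tda`           | time-delay embedding, sublevel H0, Vietoris–Rips H0/H1 (own GF(2) reduction, numba), birth–lifespan, diagram spread |
| `selection`     | per 15 s window / per bin breathing (VR + sublevel branches, strict-or-joint combination) and heartbeat (sublevel only) decisions |
| `epoching`      | 15 s / 5 s sliding windows; 7-of-10 quorum merge into 60 s rate windows |
| `rates`         | autocorrelation breathing rate, SWT-Symlet4 ECG rate, peak-based radar heart rate, median aggregation, MAE/MAPE/Bland–Altman |
| `artifacts`     | per-window magnitude std p90, skewness/kurtosis, no-selection vs selection group tables |
| `cli`, `config`, `io`, `pipeline` | YAML config, HDF5/CSV formats, end-to-end composition |

## CLI

```bash
# generate a labeled recording (HDF5) plus belt/ECG reference CSVs
radarvitals simulate --scene examples/scene.yaml --out rec.h5 --seed 1

# per-window, per-bin breathing/heartbeat selection masks
radarvitals select --in rec.h5 --out mask.h5 --evidence-csv evidence.csv

# 60 s-window vital rates from the selected bins (median over bins)
radarvitals rates --in rec.h5 --mask mask.h5 --out rates.csv

# agreement with the reference traces (MAE, MAPE, ±1 BPM, Bland–Altman)
radarvitals report --rates rates.csv --ref-belt rec.belt.csv \
                   --ref-ecg rec.ecg.csv --out report.json

# sweep empirical selection thresholds
radarvitals sensitivity --in rec.h5 --out sweep.csv
```

All selection thresholds live in a YAML config (`--config`); see
`radarvitals.selection.SelectionCriteria` for the fields and defaults.

## Data formats

Recordings are HDF5: `/range_time` (complex64, bins × time) or `/if_cube`
(frame × chirp × sample), device parameters as root attributes, ground
truth under `/ground_truth/*`. Reference traces are two-column CSV
(`time_s,value`). Masks are HDF5 with per-vital groups; rates and evidence
are CSV; reports are JSON. Every derived artifact embeds a config hash and
`report` refuses to mix mismatched configs unless `--force`d.
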