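# periop

Per-breath respiratory mechanics and intra-abdominal-pressure (IAP) coupling
analysis for multi-device operating-room recordings, plus a synthetic
OR-stream simulator with known ground truth.

During laparoscopic surgery the abdomen is insufflated with CO₂; the raised
IAP stiffens the respiratory system, which shows up in the ventilator
waveforms as higher peak pressures (volume-controlled ventilation) or lower
tidal volumes (pressure-controlled ventilation). This package implements the
full analysis chain from raw device streams to per-subject correlation
statistics:

- **`periop.simulate`** — single-compartment lung under VCV/PCV with an
  IAP-dependent compliance, insufflation/deflation events, repositioning
  steps, device-native sampling (20 ms waves, 40 ms insufflator, 60 s
  settings), per-device clock skew and missing samples. Every session
  carries its analytic per-breath ground truth.
- **`periop.ingest`** — clock-skew estimation (least squares over paired
  absolute/relative timestamps, reducing to CF = (Δt_abs − Δt_rel)/Δt_abs
  for two points), clock correction, NaN gap flagging on the nominal grid,
  and cropping of all channels to a common span.
- **`periop.mechanics`** — linear-phase FIR low-pass for the IAP channel
  (40/80 mHz edges, 0.5 dB ripple / 50 dB attenuation, group delay
  compensated), flow-based breath segmentation with hysteresis, per-breath
  PIP / PEEP / VT extraction, dynamic compliance Cdyn = VT/(PIP − PEEP),
  settings hold to breath onsets, per-breath IAP means, optional PIP
  detrending.
- **`periop.stats`** — per-subject Pearson correlation ("C") and multiple
  correlation from an OLS fit including the ventilation settings ("MLR")
  for Cdyn, PIP and (PCV only) VT versus IAP; group summaries with
  config-driven exclusions.
- **`periop.pipeline` / `periop.report` / `periop.cli`** — YAML-configured
  end-to-end runs, figures and a markdown report.

## CLI

```sh
# one synthetic session (CSV streams + JSON manifest)
periop simulate --preset pcv_limited --duration 3600 --seed 7 --out session/

# repair clocks/gaps and crop
periop ingest session/ --out clean/

# per-breath table
periop mechanics clean/ --out breaths.csv

# per-subject correlations and group summary
periop stats breaths.csv --out-results results.csv --out-summary summary.csv

# everything, for many subjects, from a YAML config
periop run --config analysis.yaml --out out/
```

A minimal `analysis.yaml`:

```yaml
seed: 7
exclude_subjects: [S11]
subjects:
  - {subject_id: S1, preset: vcv_standard, duration: 1200}
  - {subject_id: S2, preset: pcv_ideal, duration: 1200}
  - {subject_id: S3, data_dir: some/recorded/session}
```

Presets: `vcv_standard`, `pcv_ideal`, `pcv_limited` (rise-rate-limited PCV
where PIP stays under the set pressure and tracks the load), and
`repositioning` (mid-surgery compliance step that confounds the IAP
relation).

## Known limitations

- Observations are breaths; p-values carry no autocorrelation correction.
- The lung model is single-compartment with linear IAP→compliance coupling;
  no gas exchange, cardiovascular interaction, or leak modelling.
- Real device protocols (telegram parsing, video) are out of scope; sessions
  are read from the CSV + manifest layout the simulator writes.
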