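# smt2state

Analysis pipeline for two-state single-molecule tracking of membrane
proteins: molecules that alternate between a slow (substrate-engaged) state
and a fast (freely diffusive) state. The package provides

- **track_io** — track / cell-outline CSV tables, length filtering,
  single-molecule movie cropping, a plumbing nearest-neighbour linker;
- **trajectory_sim** — a seeded two-state switching-diffusion simulator on a
  spherocylinder cell membrane (localization noise, bleaching, zone-biased
  initial positions) with full ground truth for recovery tests;
- **diffusion_fit** — jump-distance (squared-displacement) Rayleigh/
  exponential mixture fitting by EM with BIC model selection and CDF R²;
- **condition_gmm** — pooled zero-mean Gaussian mixture over displacement
  components across experimental conditions with *shared* component
  variances (one set of diffusion coefficients for all conditions) and
  per-condition population weights, plus population-shift tables;
- **dwell_analysis** — confinement (residence) events (≥9 consecutive
  frames within a 120 nm radius), left-truncated exponential τ fits with
  bootstrap errors, pairwise Levene comparison across conditions;
- **spatial_map** — standardized-cell (3 × 1 µm) localization projection,
  probability heat maps, septal/lateral/polar zone statistics;
- **report_cli** — run configuration, full-pipeline orchestration, and the
  `smt2state` command-line interface.

## CLI

```sh
# simulate a synthetic track table
smt2state simulate --seed 1 --n-tracks 500 --out-tracks tracks.csv

# jump-distance mixture fit with BIC model selection
smt2state fit-jd tracks.csv --kmax 3 --out fit.json --per-k per_k.tsv

# pooled cross-condition GMM and population-shift table
smt2state fit-gmm --condition ctrl=a.csv --condition stress=b.csv \
    --reference ctrl --out gmm.json --shifts shifts.tsv

# dwell-time analysis and Levene comparison
smt2state dwell --condition ctrl=a.csv --condition stress=b.csv \
    --radius-nm 120 --min-frames 9 --out-dir dwell_out

# standardized-cell heat map
smt2state heatmap tracks.csv outlines.csv --out-tsv heatmap.tsv --out-png heatmap.png

# full pipeline from a YAML run configuration
smt2state report --config run.yaml --out-dir out
```

A simulate-mode run configuration looks like:

```yaml
simulate:
  D_slow: 0.08        # µm²/s
  D_fast: 0.57
  n_tracks: 1000
  seed: 1
  conditions:
    - {label: unstressed, f_slow: 0.50}
    - {label: vancomycin, f_slow: 0.36}
reference: unstressed
analysis: {k_max: 3, n_bootstrap: 1000}
output_dir: out
```

`smt2state report` writes `report.json`, shift/label/dwell tables (TSV) and
per-condition event CSVs; reruns with the same configuration are
byte-identical.

## Conventions

- Coordinates in µm, frames 0-based, frame interval in seconds
  (default 0.02 s); track tables are CSV with header
  `track_id,frame,x_um,y_um[,cell_id]`.
- Fitted diffusion coefficients are *apparent* (inflated by localization
  error); `MixtureFit.corrected_D()` exposes the static-error correction.
- A "track of 5 frames" means 5 detections (4 displacement steps); only
  consecutive-frame steps enter the fits.
- Dwell durations count intervals: an n-frame event lasts (n−1)·Δt.
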