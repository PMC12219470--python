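# duoscope

Analysis pipeline for dual-channel miniscope experiments in which a dynamic
calcium indicator (e.g. GCaMP) is co-expressed with a static nuclear
fluorophore (e.g. dTomato). The static channel provides stable landmarks so
that cells can be tracked across sessions even when they are not active,
enabling less biased estimates of longitudinal tracking statistics and
hippocampal representational drift.

The package contains:

- `duoscope.synthetic` — a multi-session, two-channel data generator with
  full ground truth (place fields, cross-talk, activity schedule, FOV
  jitter), so every downstream stage is testable without any download.
- `duoscope.footprints` — intensity-based cell detection for the static
  channel (local maxima + round-feature growth).
- `duoscope.registration` — centroid-distance matching across channels and
  sessions, and propagation of dynamic-channel identities through static
  landmarks.
- `duoscope.crosstalk` — trace projection onto footprints, per-cell linear
  cross-talk coefficients, circular-shuffle nulls, and the spectrally
  expected cross-talk ratio.
- `duoscope.tracking` — per-session tracking probability
  `p_m = (1/k) Σ_i N_mi / N_i`, pairwise reactivation rate
  `p_AB = ½ (N₂/N_A + N₂/N_B)`, activity-pattern proportions, and OLS slopes
  of metrics against the day interval.
- `duoscope.spatial` — behaviour segmentation (3 cm/s speed threshold,
  direction-split linearization onto 0–200 cm), cosine-kernel (5 cm
  bandwidth) occupancy and firing densities on 200 bins, Skaggs spatial
  information, within-session stability, circular-shuffle place-cell
  classification (500 shuffles, 95th-percentile conjunction rule), and
  population-vector correlation with zero-fill / intersect handling of
  inactive cells.
- `duoscope.pipeline` — end-to-end orchestration with a checksummed run
  manifest and a figure/CSV report.

## CLI

```bash
duoscope simulate --seed 1 --out sim/           # write a synthetic dataset
duoscope run-all  --seed 1 --out results/       # full pipeline on simulation
duoscope report   --results results/            # figures + per-figure CSVs
duoscope detect-static --image static.tif --out fps.h5
duoscope track --matrix activity.csv --out track.json
```

`run-all` accepts a YAML config with `experiment:` and `analysis:` sections
mirroring `duoscope.config.ExperimentConfig` / `AnalysisConfig`; defaults are
desk-scale (7 sessions, 150 cells/channel, 5-minute sessions at 15 fps) and
finish in a few minutes on one CPU. `ExperimentConfig.paper_scale()` gives
the full 15-minute / 30 fps schedule. Reruns with the same config and seed
produce byte-identical outputs (checksums are recorded in `manifest.json`).

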