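# riskseq

Rule-based segmentation of elevated-plus-maze (EPM) exploration into
risk-ranked behavioral sequences, dual-wavelength fiber-photometry
preprocessing to session-normalized zdF/F, peri-event alignment, and
sequence-resolved inference — plus a synthetic-data generator with known
ground truth so the whole pipeline is testable offline.

## What it does

- **maze** — plus-maze geometry and zoning (closed/open × proximal/distal
  × arm), frame-wise kinematics (speed, acceleration, horizontal
  movement), posture features (bounding-box area, aspect ratio, heading),
  polar heading histograms, Rayleigh tests, movement ECDFs.
- **sequences** — segments sessions into four risk-ranked sequence types
  (C→C, NoGo, Go, C→O) from a start-zone/orientation rule and a 50%
  stop-threshold rule, consuming manually annotated (BORIS-style)
  risk-assessment events; per-sequence metrics, counts, and the
  risk-assessment index (NoGo + Go over all sequences).
- **photometry** — zero-phase Butterworth low-pass (10 Hz), RANSAC
  scaling of the isosbestic (415-like) channel to the signal (470-like)
  channel, dF/F against the fitted reference, within-animal session
  z-scoring (pooled across hemispheres), Gaussian smoothing, automated
  fit-QC report.
- **perievent** — alignment to sequence-specific anchors (center crossing
  for C→C; first risk-assessment onset for NoGo/Go), ±3 s windows binned
  into 90 × 1/15-s bins, one unit per animal × hemisphere × event;
  pre/peri/post epoch means and comparisons with BH-corrected follow-ups.
- **inference** — Gaussian GEE of binned zdF/F on cubic B-spline time
  terms (df = 4) interacted with sequence type, AR(1) working correlation
  over within-unit bins, robust / bias-reduced / model-based covariances,
  joint Wald block tests (χ² or small-sample F reference); animal-level
  cluster bootstrap (1,000 resamples) for 95%/99% percentile bands,
  one-sample significance intervals, and pairwise band contrasts.
- **behavior_stats** — mixed and one-way ANOVAs with FDR-corrected post
  hocs, two-sample KS tests, session time-binning utilities.
- **synthetic** — scripted EPM sessions: waypoint trajectories that
  realize each bout type, simulated annotations, and interleaved
  two-channel photometry with shared motion artifact, bleaching, and
  per-type calcium transients, with analytic ground-truth zdF/F
  profiles.

## CLI

```sh
riskseq simulate   --config config.yaml --out session/ --seed 1
riskseq segment    --pose session/pose.csv --events session/events.csv --out sequences.csv
riskseq preprocess --photometry session/photometry.csv --out trace.csv --qc qc/
riskseq align      --trace trace.csv --sequences sequences.csv --out perievent.csv
riskseq fit        --perievent perievent.csv --seed 1 --out model/
riskseq report     --tables tables/ --out report/
```

`simulate` writes pose, BORIS-style event, and Neurophotometrics-style
photometry CSVs plus the ground-truth bout table. `segment` reads wide or
DeepLabCut-dialect pose CSVs (`--config` supplies geometry/zone/tracking
keys).

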