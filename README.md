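# chemoquant

Quantification pipeline for leukocyte chemotaxis experiments and the
companion biochemistry, with seeded synthetic-data generators so every stage
is testable offline:

- **tracks** — per-track path length, velocity (um/min along the total
  path), directionality index (cosine of the angle between the net
  start-to-end displacement and the gradient axis, in [-1, 1]), exclusion
  filters (object volume < 16 um^3, static cells, tracks shorter than
  50 um), mid-recording ~60 min window selection, group mean ± s.e.m.,
  rank-sum (exact for small n, tie-corrected normal otherwise) and t-test
  comparisons, transwell induced-migration subtraction, and
  reference-group normalization.
- **polarization** — object vs. intensity-weighted centroids of segmented
  cells, the coordinate-ratio polarization index
  `1 - |(X_signal/X_object) * (Y_signal/Y_object)|` (plus a
  translation-invariant centroid-displacement companion), moment-ellipse
  aspect ratio, and population gating (< 0.5 polarized, > 0.8 unpolarized).
- **biosensor** — per-frame ratio of mean intensity over the source-facing
  half of the cell perimeter to the source-facing half of the cell area,
  and the per-cell time series relative to stimulation onset.
- **binding** — SPR background correction, steady-state affinity fitting of
  `Req = Rmax / (1 + KD / C)` by nonlinear least squares (log-parameter
  positivity), percent-of-maximal binding, sedimentation fraction bound,
  and kinase fold normalization (zero-protein activity set to 1).
- **synthetic** — biased persistent random-walk track generator (independent
  persistence and bias knobs, truncated-normal speeds, chemokinesis speed
  multiplier), elliptical cell images with controllable signal-centroid
  offset and membrane enrichment, one-site isotherms, and beta-mixture
  aspect-ratio populations. Every generator takes an explicit seed and is
  bit-reproducible.

## CLI

One top-level command with per-assay subcommands:

```sh
chemoquant simulate-tracks --n 100 --bias 0.5 --seed 1 --out tracks.csv
chemoquant analyze-tracks --tracks tracks.csv --axis 1,0 --out out/
chemoquant polarization --images imgs/ --channel rac1gtp --out out/
chemoquant biosensor --frames frames/ --channel akt-ph --out out/
chemoquant fit-spr --isotherm iso.csv --background dopc.csv --out fit.json
chemoquant kinase-fold --table kinase.csv --out fold.csv
chemoquant report --config examples/demo_config.yaml
```

File dialects: track CSV
(`track_id,frame,t_min,x_um,y_um,volume_um3,group`), isotherm CSV
(`conc_uM,response_RU`), kinase CSV (`conc_uM,activity`), and multi-page
TIFF (page 1 = 0/1 mask, pages 2+ = channels) with a `<file>.tif.json`
sidecar (pixel size, channel names, source direction, frame time). All
writes are atomic and CSV numbers are full precision.

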