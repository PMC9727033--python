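# palmpipe

Quantitative-imaging pipeline for single-molecule cluster dynamics:

* **simkit** — synthetic PALM movies (2400 frames, 20 Hz, 256 px ROI,
  160 nm/px by default), EMCCD noise, photoswitching emitters, cluster
  birth/death with two-population exponential lifetimes, plus
  confocal-style spot fields — all with explicit ground truth, so every
  downstream stage can be scored.
* **localize** — frame-wise spot detection by a pixelwise
  generalized-likelihood-ratio test, subpixel maximum-likelihood
  integrated-Gaussian fitting (Gauss-Newton / Fisher scoring on the
  Poisson likelihood, CRLB-based uncertainties), and a deflation loop that
  recovers dim emitters overshadowed by bright neighbours.
* **spatialcluster** — DBSCAN grouping of localizations
  (length-scale 120 nm, N_min 4 by default, minPts-inclusive) and
  plasma-membrane / cytoplasm / nucleus assignment from region masks.
* **tcpalm** — time-correlated burst extraction within each spatial
  cluster (dark-gap splitting), burst lifetimes (first-to-last detection
  span), short/long-lived classification at a 100 s cutoff, per-region
  τ_avg ± SEM summaries, clusters-per-cell and detections-per-cluster
  statistics, unpaired t tests, and a gap-sensitivity sweep.
* **punctaquant** — confocal puncta segmentation (median-subtraction →
  LoG → mean + 2·SD threshold → 3×3 opening → 8-connected labelling),
  c-in / c-out intensity metrics and enrichment, secondary-channel
  quantification inside puncta, fusion/fission/deformation total-intensity
  conservation checks, polygon/mask region means, and per-slice to
  whole-cell count extrapolation.
* **pipeio / pipeline / cli** — schema-versioned CSV, TIFF stacks with
  required pixel-size/frame-rate metadata, YAML configs, a JSON run
  manifest, and a deterministic end-to-end pipeline.

## Command line

```sh
palmpipe run --config cfg.yaml --seed 1 --out out/       # full pipeline
palmpipe sim movie --seed 1 --out sim/                   # synthetic movie + tables
palmpipe sim spots --n-spots 20 --out spots/             # puncta fixture
palmpipe localize --in movie.tif --out locs.csv --gain 900 --baseline 100
palmpipe cluster --locs locs.csv --mask mask.tif --eps 120 --nmin 4 --out cl/
palmpipe tcpalm --clusters cl/clusters.csv --locs cl/localizations_labeled.csv \
    --frame-rate 20 --gap 20 --cutoff 100 --out tc/
palmpipe puncta quantify --in image.tif --bg-rect 0 20 0 20 --out puncta.csv
palmpipe puncta events --events events.json --out events.csv
```

`palmpipe run` writes `manifest.json`, `config.yaml`,
`ground_truth_clusters.csv`, `localizations.csv`, `clusters.csv`,
`bursts.csv` and `summary.json`; two runs with identical config and seed
are byte-identical (the manifest timestamp aside). One master seed expands
to per-stage child seeds via `numpy.random.SeedSequence`.

## Conventions

Coordinates are continuous nanometres, origin at the upper-left pixel
corner; pixel *(i, j)* spans half-open intervals, 0-based. Localization
tables carry `frame, x_nm, y_nm, photons, background, sigma_nm,
uncertainty_nm`. Every CSV starts with a `# palmpipe-table v1 kind=...`
schema line and readers reject unknown schemas. Lifetimes require an
explicit frame rate — there is no silent default.

Known limitations (documented, out of scope): no stage-drift correction,
no astigmatic/3D PSFs, no sCMOS pixel-dependent noise maps, no
multi-emitter joint fitting beyond the deflation loop, no 3D puncta
segmentation (stacks are max-projected).
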