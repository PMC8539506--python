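# cryofront

Computational chain for IR-thermography monitoring of vial freezing in
freeze-drying, plus pore-structure statistics of the resulting dried
cakes:

* **`cryofront.synthetic`** — physically structured synthetic inputs with
  known ground truth:
  * a 1-D nodal vial-freezing simulator (liquid cooling, instantaneous
    nucleation with an adiabatic heat-balance frozen fraction, sharp
    bottom-up front for shelf-loaded vials / mushy two-sided freezing for
    suspended vials, VISF vacuum-pulse and spontaneous nucleation modes);
  * a thermal-stack renderer emulating an IR camera (6 acquisition lines ×
    8 pixels per 10 mm cake, 0.1 fps, graybody emissivity model, sensor
    noise, neighbour-nucleation humps);
  * an SEM-like porous-image generator (beta-distributed pore diameters,
    charging gradient, pore texture) with a ground-truth pore table.
* **`cryofront.ir`** — acquisition-line extraction (no smoothing),
  graybody emissivity correction, per-line min/max extrema, and
  extremum-then-average line → vial → batch traces.
* **`cryofront.front`** — freezing-front tracking from the Hmax proxy
  (ON-shelf only), front velocity and two-segment phase labelling,
  frozen-layer gradient, freezing-interval duration, and qualitative
  gradient-inversion labels (bottom pixel LOWEST/HIGHEST before/after
  nucleation, VISF inversion YES/NO/UNCLEAR/NA).
* **`cryofront.mia`** — multivariate image analysis segmentation:
  brightness equalization, moving-window neighbourhood matrix, PCA score
  images, score thresholding, Canny edge second filter, inclusive
  50–1000 px dimensional filter, per-pore region properties.
* **`cryofront.stats`** — beta(Q-Q) distribution assessment and
  dispersion (sample variance, Q1/Q3, IQR) comparison across groups, with
  ON- vs OFF-shelf pairing.
* **`cryofront.pipeline` / CLI** — reproducible end-to-end runs with YAML
  configs, explicit seeds and SHA-256 manifests.

## CLI

```bash
cryofront --help                     # subcommand overview
cryofront simulate      --seed 7 --out out/freeze     # simulate+render+extract+front
cryofront sem-generate  --seed 7 --out out/pores      # generate+segment+stats
cryofront run-all       --seed 7 --out out/all
cryofront scenario-matrix --seed 7 --out out/matrix   # loading x nucleation design

# stage tools (also installed standalone)
ir-extract    --stack out/freeze/stack.tif --times out/freeze/timestamps.csv \
              --lines out/freeze/lines.csv --emissivity 0.91 --out traces.csv
pores-segment --image a.png --sidecar a.json --score-quantile 0.8 --out pores.csv
pores-stats   --table pores.csv --beta-a 1.2 --beta-b 15 --out report.csv
```

All commands accept `--config run.yaml` (see `cryofront.pipeline.RunConfig`
for the schema) and `--seed N`; a seeded rerun is byte-identical.

## File formats

Thermal stacks are multi-page 16-bit grayscale TIFF in centikelvin with a
timestamps CSV; acquisition-line definitions, traces, pore tables and
dispersion reports are tidy CSV; SEM images are 8-bit PNG with a JSON
sidecar (pixel size, cake level); run manifests are JSON.

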