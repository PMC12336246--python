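# compresscan

Predict and measure soft-tissue deformation under compression garments
(sports leggings) on the lower limbs.

The package combines two routes to the same quantity and compares them:

* **Analytical prediction** — orthotropic fabric constants are fitted from
  uniaxial-tension and pure-shear records; circumferential garment stretch
  is converted to interface pressure through an elastic half-space
  surface-deflection relation; the fabric layer carries a thick-walled
  cylinder (Lamé) stress field; static tissue deformation follows a
  linear-elastic law with an exactly equivalent Neo-Hookean (C1, D1)
  parameterization; dynamic deformation integrates the forced damped
  garment oscillator with classical RK4 and maps it to an effective
  interface pressure.
* **Scan measurement** — STL body-scan meshes are sliced into
  cross-sections (or marker-colored contour rasters are thresholded),
  contours are resampled to uniform arc length, anchored at their vertex
  centroid, and converted to angular radius profiles; deformation is the
  per-angle radius difference between the no-garment control and the
  garment condition. Anchoring each profile at its own centroid cancels
  rigid displacement between scans.

A synthetic-data module generates every required input with exact ground
truth (Fourier contours, lofted limb meshes, rendered marker images,
linear stress–strain records, sinusoidal vibration traces), so the whole
pipeline can be validated offline.

## CLI

```sh
compresscan synth --samples 4 --seed 1 --out-dir fixtures/   # fixture tree
compresscan fit-fabric fixtures/stress_strain/sample_4.csv --out-dir out/
compresscan predict --sample 4 --out-dir out/
compresscan measure fixtures/ --condition legging_4 --out-dir out/
compresscan simulate-dynamic --pressure 1000 --radius 50 --out-dir out/
compresscan compare out/pred.json out/meas.json --out-dir out/
compresscan run --seed 1 --out-dir run/                      # full pipeline
```

All subcommands accept `--config` (YAML, merged over defaults in
`compresscan.pipeline.DEFAULT_CONFIG`), `--seed`, `--out-dir` and
`--log-level`. Exit codes: 0 success, 2 invalid input, 3 stage failure.

`compresscan run` executes synth → fit-fabric → predict → measure →
simulate-dynamic → compare and writes `report.json` (versioned schema),
`measured.csv`, and a log. Identical config + seed give identical
numerical outputs.

## Layout

```
src/compresscan/
  fabric_mechanics.py   # stress–strain fitting, orthotropic compliance
  continuum_model.py    # pressure, Lamé field, static/dynamic deformation
  scan_geometry.py      # STL slicing, contour extraction, radial profiles
  synthetic_data.py     # ground-truth generators and fixture battery
  pipeline.py           # orchestration + ANOVA/Shapiro comparison stats
  cli.py                # click CLI
  data/                 # bundled fabric and garment-section tables
```
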