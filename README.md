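# seedscreen

Binary seed-variety genuineness screening from spectral and RGB seed
phenotypes: hyperspectral cube I/O and reflectance calibration, per-seed
segmentation and mean-spectrum extraction, a 54-feature machine-vision
branch, successive-projections-algorithm (SPA) wavelength selection,
RF / SVM-RBF / MLP classifiers with a stratified 3:1 ten-run evaluation
protocol, an accuracy-threshold active-learning model-update loop, and a
simulator that generates all of the above with known ground truth.

## Test

```bash
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance criteria (SPA oracle
equivalence, Bayes-sanity / parameter recovery, update-loop behaviour,
extraction round-trips, protocol conformance, full-vs-selected
generalization trend); everything else is per-module unit/property
tests.

## CLI

```bash
seedscreen simulate --seed 1 --out spectra.csv        # synthetic 2-category table
seedscreen extract cube.hdr --out spectra.csv         # ENVI cube -> per-seed spectra
seedscreen features scan.png --out features.csv       # RGB scan -> 54-feature table
seedscreen spa spectra.csv --out spa.json             # characteristic wavelengths
seedscreen evaluate spectra.csv --algorithm svm --out report.json
seedscreen update train.csv external.csv --out log.json
seedscreen run experiment.yaml                        # full pipeline from a config
```

`seedscreen run` takes a YAML/JSON `ExperimentConfig`: one input source
(`scenario` | `spectra_csv` | `feature_csv`), a `surface_mode`
(`germ` / `non-germ` / `mixed`), a `feature_mode` (`full-spectrum` /
`spa` / `rgb-54`), an `algorithm` (`rf` / `svm` / `mlp`), evaluation
`runs`, optional `update` settings and a `seed`; it writes a manifest
plus JSON artifacts to `outdir`.

## Package layout

| module | contents |
| --- | --- |
| `seedscreen.hsi` | `Hypercube`, ENVI read/write, flat-field calibration, 400–1000 nm band trim |
| `seedscreen.segmentation` | Otsu/fixed threshold masks, per-seed mean spectra, `SpectrumTable` CSV I/O |
| `seedscreen.features` | 54 shape/colour/texture features per seed, per-class distribution-overlap report |
| `seedscreen.spa` | SPA projection chains, validation-RMSE subset selection, exhaustive oracle |
| `seedscreen.classifiers` | stratified 3:1 splits, SVM (c, g) grid search, RF/SVM/MLP training, ten-run evaluation |
| `seedscreen.update` | external per-variety verification, accuracy-threshold active-learning loop |
| `seedscreen.simulate` | variety spectral signatures, spectra/hypercube/feature simulators, reference scenarios |
| `seedscreen.pipeline` / `seedscreen.cli` | experiment orchestration, manifests, `seedscreen` CLI |
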