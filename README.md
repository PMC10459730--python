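# leafspec

Coarse–fine wavelength selection and pigment mapping from visible–near-infrared
leaf reflectance spectra.

`leafspec` implements an end-to-end chemometrics pipeline for the simultaneous
quantification of four photosynthetic pigments (chlorophyll a / b, total
chlorophylls, total carotenoids, mg/L) from 646-band (430–900 nm) hyperspectral
leaf images:

- **hsi_io** — ENVI-style cube I/O (BSQ/BIL/BIP), white/dark reflectance
  correction `R = (R0 − Rb)/(Rw − Rb)`, elliptical-ROI pixel harvesting and
  mean-spectrum extraction.
- **wet_chem** — reference chemistry: absorbance triplets (A665/A649/A470) to
  pigment concentrations.
- **preprocessing** — Savitzky–Golay smoothing, standard normal variate (SNV),
  and their composition, with per-pigment defaults.
- **partitioning** — SPXY calibration/prediction split (Kennard–Stone on a
  joint max-normalized X/Y distance).
- **pls** — SIMPLS partial least squares regression collapsed to a single
  affine map, seeded k-fold cross-validation, and R², RMSE, RPD metrics.
- **cars** — competitive adaptive reweighted sampling: Monte Carlo subsampling,
  exponentially decreasing retention schedule (`r_j = a·e^(−bj)` with
  `r_1 = 1`, `r_N = 2/p`), adaptive reweighted sampling, RMSEcv-scored runs.
- **iriv** — iteratively retained informative variables: balanced random
  binary-inclusion submodels, Mann–Whitney classification into
  strong/weak/uninformative/interfering, iterated elimination, and greedy
  backward elimination.
- **visualization** — pixel-wise model inversion into concentration maps,
  band-ratio leaf segmentation, enhanced Lee despeckling, blue→red
  pseudo-color rendering.
- **synthetic** — a forward simulator (Gaussian absorption features on a
  red-edge baseline, scatter / noise / smooth drift distortions, structured
  nitrogen × leaf-position concentration effects) with ground truth, used by
  the entire test suite in place of the unavailable instrument data.
- **pipeline** — study orchestration comparing PLSR vs CARS–PLSR vs
  CARS–IRIV–PLSR per pigment, with a comparison report.

## Tests

```bash
python -m pytest tests/
```

`tests/test_acceptance.py` holds the acceptance criteria, including a
10-seed full-scale (435 × 646) recovery study (a few minutes on one CPU).

## Command line

```bash
leafspec simulate --n-samples 435 --seed 1 --out spectra.csv --truth truth.json
leafspec partition --spectra spectra.csv --pigment chla --out split.json
leafspec run --spectra spectra.csv --pigment chla --selector cars-iriv \
    --seed 1 --report report.csv --models-dir models/
leafspec extract --cube leaf.hdr --white white.hdr --dark dark.hdr \
    --roi roi.json --out spectrum.csv
leafspec map --cube leaf.hdr --model models/chla_cars-iriv.json --out chla.png
```

`leafspec run` accepts a YAML config (`--config study.yaml`) mirroring the
fields of `leafspec.pipeline.StudyConfig`.

## Python API sketch

```python
import leafspec as ls

spectra, truth = ls.generate_dataset(ls.SimulationConfig(seed=1))
y = truth.concentrations["chla"]
X = ls.PreprocessRecipe("sg+snv").apply(spectra.values)
split = ls.spxy_split(X, y, fraction=0.75)

subset, trace = ls.cars_select(
    X[split.calibration_indices], y[split.calibration_indices],
    wavelengths=spectra.wavelengths, n_runs=100, seed=7,
)
model = ls.fit_plsr(
    X[split.calibration_indices][:, subset.indices],
    y[split.calibration_indices], n_latent=8,
)
metrics = ls.evaluate(
    model, X[split.prediction_indices][:, subset.indices],
    y[split.prediction_indices],
)
print(metrics.r2, metrics.rmse, metrics.rpd)
```
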