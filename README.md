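# seedhsi

A reusable pipeline for single-seed classification from near-infrared
hyperspectral images (288 bands, 1000–2500 nm):

1. **Calibration** — raw counts → reflectance via white/dark reference frames,
   `R = (I_S − I_D) / (I_W − I_D)`.
2. **Segmentation** — reverse mask (background 0, seed 1) with Otsu or fixed
   thresholding, connected-component labelling, small-object removal.
3. **Object spectra** — one mean spectrum per seed.
4. **Chemometric preprocessing** — detrend, asymmetric weighted-least-squares
   baseline, Savitzky–Golay derivatives, SNV, EMSC, OSC, mean centring; all
   composable into fit-on-calibration / apply-to-prediction chains with six
   named presets (`pt1`…`pt6`).
5. **Modelling** — Kennard–Stone 95/5 calibration split, venetian-blinds
   cross-validation, PLS-DA (NIPALS), PLS-compressed RBF C-SVM and
   single-hidden-layer ANN discriminant models, per-class
   sensitivity/specificity/class-error reports and the
   `100 − max(class error)` overall-accuracy rule.
6. **Wavelength selection** — genetic algorithm (population 64, double
   crossover, mutation 0.005, 50% convergence) with PLS RMSECV fitness.
7. **Synthetic data** — seed-shaped hypercubes and spectra tables with known
   class signals, batch effects, scatter and noise, so every stage is testable
   without proprietary images; includes a 1057-row study-layout preset.

## Test

```bash
python -m pytest -q tests/
```

The suite includes a stochastic GA band-recovery test (a couple of minutes on
one CPU); everything else runs in seconds.

## CLI

```bash
seedhsi simulate --seed 1 --out table.csv --cube-out demo.img
seedhsi calibrate --cube demo.img --white demo_white.img --dark demo_dark.img --out refl.img
seedhsi segment  --cube refl.img --out labels.txt
seedhsi extract  --cube refl.img --labels labels.txt --annotations demo_objects.csv --out spectra.csv
seedhsi run      --config pipeline.yaml --out-dir results/
ga-select --spectra spectra.csv --seed 7 --out ga.json
```

A pipeline config is a small YAML file:

```yaml
spectra: spectra.csv        # or: simulate: study / cube: raw.img + white/dark
target: endophyte_status    # label column to classify
chain: pt6                  # preprocessing preset or explicit step list
split_fraction: 0.95
cv_splits: 10
seed: 1
model:
  classifier: plsda         # plsda | csvm | annda
  n_lv: 4                   # or "auto" (CV minimum)
```

Each run writes `report.csv` / `report.json` (per-class Cal/CV/Pred
sensitivities and class errors plus overall accuracy) and the resolved config
with its hash, so reruns are byte-identical.

## File formats

- Hypercubes: ENVI-style `.hdr` text header + flat binary (BSQ written; BSQ,
  BIL, BIP read), wavelengths stored in the header.
- Spectra tables: CSV with `object_id, cultivar, endophyte_status, batch_date`
  followed by one column per wavelength (nm).
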