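# extractopt

Design-of-experiments optimization of multifrequency ultrasonic-assisted
extraction of antioxidant compounds from seaweed. The package implements the
complete modelling chain used in such studies: a Box–Behnken design (BBD)
over four process factors, second-order response-surface fits with full
ANOVA adequacy diagnostics, a small feed-forward neural surrogate with
hidden-layer selection, genetic-algorithm (GA) optimization of the
extraction conditions, and the AAD/SEP/RMSE/R² statistics comparing the two
surrogates. It ships the complete 27-run dataset of a published
*Sargassum horneri* extraction study, so the whole analysis is reproducible
end to end.

## The problem and the models

Four factors control the extraction: ethanol concentration X₁ (30/50/70 %),
sonication time X₂ (20/35/50 min), temperature X₃ (20/40/60 °C), and
ultrasonic frequency X₄ (26/35/40 kHz). Four responses are measured per run:
total phenolic content (TPC, mg GAE/g), total flavonoid content (TFC,
mg CAE/g), and DPPH and ABTS radical scavenging (% inhibition).

Each response is modelled by the full second-order polynomial in the coded
factors xᵢ,

    Y = β₀ + Σᵢ βᵢxᵢ + Σᵢ βᵢᵢxᵢ² + Σᵢ<ⱼ βᵢⱼxᵢxⱼ    (15 terms for k = 4),

fitted by ordinary least squares on the 27-run BBD (24 edge-midpoint runs +
3 center replicates). Term significance uses partial (Type-III) F tests; the
center replicates supply pure error for the lack-of-fit test; adequacy is
summarized by R², adjusted R², CV% and the adequate-precision signal-to-noise
ratio (max ŷ − min ŷ)/√(p·MSE/n). A 4–H–4 tanh/linear perceptron trained by
damped least squares (Levenberg–Marquardt family) or BFGS on a 65/20/15
train/test/validation split provides the alternative surrogate; a real-coded
GA (tournament selection, blend crossover, Gaussian mutation, elitism)
maximizes a weighted min-max-normalized combination of the predicted
responses over the factor box, verified against an exhaustive lattice search.

Because the frequency levels are unequally spaced, the coding of factor
levels matters: `affine` coding (26→−1, 33→0, 40→+1, so 35 kHz → +2/7) is
the package default, because it — and not ordinal level-index coding —
reproduces the study's published predicted values (see `docs/methods.md`).

## Worked example

```python
from extractopt import fit_quadratic, anova, predict, load_table1_fixture

design, observed, rsm_pred, ann_pred = load_table1_fixture()
model = fit_quadratic(design, observed["tpc"], "tpc")
report = anova(model, design, observed["tpc"])
print(round(report.r2, 4), round(report.adequate_precision, 2))
center = design.actual.loc[[11]]          # 50 %, 35 min, 40 °C, 35 kHz
print(round(float(predict(model, center)[0]), 2))
```

prints

```
0.937 13.04
67.37
```

— the TPC surface explains 93.7 % of the response variance, its
signal-to-noise ratio is 13.04, and the model's center-point prediction is
67.37 mg GAE/g, matching the study's published predicted value for the
center runs. The equivalent command-line run is

```
extractopt all --outdir out --ann-seed 1 --ga-seed 1
```

which writes per-response coefficients, ANOVA tables, adequacy statistics,
the neural-surrogate sweep, the GA optimum and the surrogate-comparison grid
into `out/`, each file stamped with the package version, config hash and
seeds.

The numbered scripts under `analysis/` retrace the study as a narrative:
`01_fit_response_surfaces.py` (fits and diagnostics),
`02_train_ann_surrogate.py` (neuron sweep and training),
`03_compare_prediction_ability.py` (AAD/SEP/RMSE/R² grids),
`04_optimize_conditions.py` (GA vs lattice oracle) and
`05_synthetic_validation.py` (known-truth recovery and CI coverage). Each
writes its tables under `results/`.

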