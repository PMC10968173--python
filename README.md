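# tbtoa — trabecular bone texture analysis for knee osteoarthritis progression

`tbtoa` is a Python package for predicting long-term knee osteoarthritis
(KOA) progression from the *texture* of subchondral trabecular bone on plain
radiographs. It is aimed at researchers in musculoskeletal imaging and
biostatistics who want a tested, reusable implementation of the full chain —
fractal texture descriptors, progression labelling, penalised risk models,
and cross-validated ROC evaluation — that runs end-to-end on synthetic data,
because the cohorts this methodology targets are access-restricted.

## The method

**Texture descriptors.** Over a limited range of scales the radiographic
texture of trabecular bone behaves like a fractional Brownian surface: the
mean squared intensity increment at pixel lag *d* follows a power law
*V(d) ∝ d^{2H}*, where *H* is the Hurst exponent (surface fractal dimension
*FD = 3 − H*). The quadratic-variation estimator regresses log *V* on
log *d* and takes *Ĥ* = slope/2. A knee is summarised by a patchwork of 16
rectangular ROIs tiling the tibial subchondral band (tagged medial /
central / lateral); each ROI is analysed in the horizontal (HF) and vertical
(VF) increment directions and in two physical scale bands — micro (lags
≤ 0.4 mm) and milli (0.6–1.2 mm) — giving **64 descriptors per knee** (TBT),
plus their 24-month changes (ΔTBT).

**Outcome labels.** At months 0/24/48, a knee is a *radiographic progressor*
if its medial joint-space width loses < 0.7 mm in the first 24 months but
≥ 0.7 mm between months 24 and 48, and a *symptomatic progressor* if its
normalised WOMAC pain score (0–100) worsens by < 9 then ≥ 9 points. The four
groups — radio-symptomatic (1), radiographic-only (2), symptomatic-only (3),
non-progressors (4, requiring no progression on either plateau or knee) —
define a primary case/control analysis (group 1 vs 2∪3∪4) and four secondary
scenarios.

**Risk models.** Logistic regressions combine texture blocks with forced-in
adjustment covariates (age, sex, BMI; KL and JSNM grades; optionally
log-transformed uCTX-II, sNTXI, sHA biomarkers), written
`TBT + ΔTBT ← CLIN + KL + JSNM` for "texture adjusted for clinical and
radiological covariates". The texture blocks carry an L1 (LASSO) penalty —
baseline and follow-up descriptors are strongly correlated — with the
penalty strength chosen by AIC (= 2k − 2·loglik, k = nonzero coefficients
+ 1); adjustment covariates are never penalised. Models are compared by AUC
under repeated stratified 10-fold cross-validation, with DeLong confidence
intervals and paired DeLong tests against the reference model on pooled
out-of-fold scores.

**Synthetic ground truth.** A spectral fractional-Brownian generator
produces textures with known *H* (the estimator's oracle), and a cohort
generator draws clinically structured knees whose trajectories straddle the
progression rules with margin and whose 24-month texture decline is coupled
to radiographic progression — so parameter recovery, label agreement and
signal detection are all checkable without any restricted data.

## Worked example

```python
from tbtoa import CohortSpec, generate_cohort, label_cohort, CVConfig
from tbtoa.progression import ProgressionModel

cohort = label_cohort(generate_cohort(CohortSpec(n_knees=597, seed=1)))

model = ProgressionModel(cohort, spec="M3", scenario="primary")
print(model.n_cases, model.n_controls)

reference = ProgressionModel(cohort, "M1", "primary").cross_validate(
    CVConfig(repeats=10, seed=0)
)
result = model.cross_validate(CVConfig(repeats=10, seed=0), reference=reference)
print(reference.summary())
print(result.summary())
```

prints

```
196 401
M1 [primary]  AUC 0.569 (0.520-0.617)  BACC 0.50  PPV 0.30  NPV 0.67  p vs ref -
M3 [primary]  AUC 0.754 (0.715-0.793)  BACC 0.59  PPV 0.54  NPV 0.72  p vs ref 0.000
```

The scenario holds 196 radio-symptomatic cases against 401 controls in this
draw. The reference model (baseline texture + clinical adjustment, M1) sits
near chance on this synthetic cohort, while adding the 24-month texture
change (M3) lifts the pooled cross-validated AUC to ~0.75; the paired DeLong
test against M1 rejects at any conventional level. `model.fit().summary()`
shows the AIC-selected LASSO fit itself, including which descriptors
survived the penalty.

The same analysis runs from the shell:

```bash
tbtoa synth cohort --n 597 --seed 1 --out cohort.csv
tbtoa eval run --cohort cohort.csv --models M1,M3,M4 --repeats 10 --out results.csv
tbtoa pipeline run --config config.json --out runs/
```

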