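# Methods

This note documents the models, estimators and design choices behind
`tbtoa`, the parameters that matter, what the synthetic generators do and do
not emulate, and the package's numerical conventions.

## 1. Fractal texture model and the quadratic-variation estimator

Subchondral trabecular texture on a radiograph is modelled locally as a
fractional Brownian surface with Hurst exponent `H ∈ (0, 1)`: the mean
squared intensity increment at physical lag `r` follows `V(r) = C·r^{2H}`.
Rough, dense trabecular patterns correspond to low `H` (high fractal
dimension `FD = 3 − H`), smoother, rarefied patterns to high `H`.

The estimator computes, per ROI and per increment direction (HF = along
image rows, VF = along columns), the empirical variogram
`V(d) = mean[(I(x + d·e) − I(x))²]` at integer pixel lags `d = 1..max`,
with exact pair counts, then fits ordinary least squares of `log V` against
`log(d·Δx)` restricted to one scale band and reports `Ĥ = slope / 2`.
Two conventions follow from the variogram definition: every descriptor is
invariant to adding a constant to all intensities, and multiplying
intensities by `c` scales `V` by `c²` without moving the log–log slope, so
the descriptors are insensitive to radiographic brightness and contrast
calibration — the property that makes them usable across acquisition
protocols.

**Scale bands.** The variograms of trabecular bone show a regime break
around 0.5 mm; fitting is therefore split into a *micro* band (lags
≤ 0.400 mm, individual trabeculae) and a *milli* band (0.600–1.200 mm, the
trabecular network). Band edges are closed and configurable
(`ScaleBands`). At the default 0.1 mm/px spacing the bands contain pixel
lags 1–4 and 6–12 respectively; both hold the ≥ 2 lags the fit requires
with margin. A band with fewer than two usable lags raises an error rather
than silently extrapolating; a zero variogram value inside the band (a
constant texture) is likewise an explicit error.

**ROI patchwork.** Sixteen rectangular ROIs tile a user-supplied tibial
bounding box in a 2 × 8 grid, tagged by column: columns 0–2 medial, 3–4
central, 5–7 lateral (6/4/6 ROIs). The grid shape and compartment map are
arguments; the geometry of the band itself (detection of the tibial
plateau) is deliberately out of scope — the bounding box is an input.
With 2 bands × 2 directions this yields 64 descriptors per knee and visit;
the longitudinal change ΔTBT is the componentwise difference
(24-month − baseline). Descriptors default to `Ĥ`; `FD = 3 − Ĥ` is a
monotone relabelling and available via `kind="FD"`. `Ĥ` is reported
unclipped — pathological ROIs may fall outside (0, 1) — because the models
standardise features anyway and clipping would hide estimator failures.

## 2. Synthetic fractional Brownian textures

The texture oracle synthesises surfaces by spectral filtering: white
Gaussian noise is transformed to frequency space, multiplied by an
amplitude `∝ f^{−(H+1)}` (power `f^{−(2H+2)}`, the 2-D fractional Brownian
convention; DC set to zero), and inverse transformed; the real field is
standardised and affinely mapped onto the 16-bit range.

Two refinements matter numerically. The filter power at each discrete
frequency is the *alias-folded* continuous spectrum (summed over the 7 × 7
nearest alias images): a sampled continuous field receives all
beyond-Nyquist power through aliasing, and omitting it depletes the
small-lag variogram enough to bias `Ĥ` upward by +0.2 at `H = 0.2`.
Synthesis also runs on a doubled grid with a central crop to suppress the
wrap-around correlation of circular convolution. With both refinements the
estimator recovers `H ∈ {0.2, 0.5, 0.8}` comfortably within the 0.10
tolerance the acceptance suite enforces per band × direction cell
(20 surfaces of 256²; the worst cell sits near 0.06 mean bias, at the milli
band of smooth surfaces where few lags enter the fit).

## 3. Progression labelling

Joint-space width (JSW) and normalised WOMAC pain trajectories at months
0/24/48 define two rules, both read with a strict first clause and a closed
second clause, exactly as the clinical definitions state them:

* radiographic: `(jsw0 − jsw24 < 0.7 mm) ∧ (jsw24 − jsw48 ≥ 0.7 mm)`;
* symptomatic: `(p24 − p0 < 9) ∧ (p48 − p24 ≥ 9)` on the 0–100 scale.

The case-defining radiographic rule uses the **medial** plateau; the
lateral plateau and the contralateral knee's pain enter only the
non-progressor definition, which requires all four flags false. Knees
matching no definition (e.g. lateral-only structural progression) are
labelled `excluded`: the original study design guaranteed every knee a
group, but arbitrary synthetic or external data do not, and silently
binning such knees would corrupt the scenarios. Scenario constructions
(primary, s1–s4) are set algebra over groups and are validated by count
identities rather than hard-coded sizes.

## 4. Synthetic cohort generator

The generator emulates the *structure* of a nested case–control KOA cohort
of ~600 knees — not its radiographic appearance. Fixed defaults (chosen
once, a priori):

| parameter | default | rationale |
|---|---|---|
| group probabilities | (192, 102, 103, 200)/597 | published group sizes |
| KL 1/2/3 probabilities | 0.126 / 0.511 / 0.363 | published marginals |
| female fraction | 0.590 | published marginal |
| age, BMI | N(61.5, 8.9) yr, N(30.7, 4.8) kg/m² (clipped) | typical KOA trial cohort |
| JSW losses, non-progressing / progressing period | U[0, 0.6] / U[0.7, 1.6] mm | straddle the 0.7 mm rule with margin |
| pain changes, non-progressing / progressing period | U[−5, 8] / U[9, 30] points | straddle the 9-point rule with margin |
| baseline per-ROI Hurst | knee level N(0.70, 0.04) + ROI level N(0, 0.02) | mid-range roughness, realistic within-knee coherence |
| radiographic-progressor texture effect | baseline −0.02; 24-month knee-level change −0.05 (SDs 0.04 knee, 0.02 ROI) | a modest signal: detectable through CV at n ≈ 600 but far from separable, mirroring the weak-signal regime the models target |
| biomarkers (uCTX-II, sNTXI, sHA) | log-normal, log-shifts +0.25 (radiographic) / +0.10 (symptomatic) | right-skewed positives with group overlap |
| tabular descriptor noise | N(0, 0.02) per descriptor | estimator-scale noise |

Because the trajectory windows sit strictly on either side of the rule
thresholds, re-applying the labelling rules to generated trajectories
recovers the intended group for every knee — the generator is validated by
the labeller, not trusted.

Two fidelity levels produce descriptors: *tabular* adds estimator-like
noise directly to the per-ROI ground-truth `H` (fast; the default), and
*imaging* renders each ROI as a fractional Brownian patch at its
ground-truth `H` (64 px ROIs, constant mid-grey outside the patchwork) and
runs the full variogram extractor on the images. The rendered images are
texture phantoms: they carry no bone contours, osteophytes, joint space or
acquisition artefacts, so passing tests demonstrate correctness of the
measurement chain, not performance on real radiographs.

## 5. Penalised logistic models

Model formulas combine texture blocks (TBT, ΔTBT; optionally restricted to
one compartment) with forced adjustment blocks (CLIN = age, sex, BMI;
KL; JSNM; BIO = log-transformed uCTX-II, sNTXI, sHA). The canonical M1–M8
registry is in `tbtoa.design`. Conventions: KL and JSNM enter as numeric
ordinal scores; sex is 0/1; biomarkers are log-transformed by default
(toggle `log_biomarkers`); no interaction terms.

The fit minimises the average logistic negative log-likelihood plus
`λ · Σ w_j |β_j|` with `w_j = 1` on texture descriptors and `w_j = 0` on
the intercept and forced covariates. The L1 penalty addresses the strong
correlation between baseline and follow-up descriptors that destabilises an
unpenalised fit; `λ` is selected by AIC (`2k − 2·loglik`, `k` = nonzero
coefficients + 1) over a descending 8-point grid spanning two decades below
the smallest all-zeroing `λ_max`, traversed with warm starts. AIC-based
selection is deliberately liberal: it keeps all of an injected signal block
at the cost of a few near-zero noise coefficients, so support quality is
best judged by coefficient mass, not count.

The solver is FISTA (accelerated proximal gradient) on the standardised
design with gradient-based adaptive restart, a Lipschitz step from a
power-iteration spectral norm, and soft-thresholding applied only to
penalised coordinates — forced covariates can shrink but never vanish.
Default stopping: generalised-gradient sup-norm ≤ 1e-6 (single fits) or
1e-4 inside cross-validation, where scores only feed rank-based metrics and
the looser tolerance changes pooled AUCs by < 1e-3. Standardisation
(mean/SD) is computed per training fold at fit time and stored with the
results, so held-out scoring can never leak test-fold statistics.

## 6. Evaluation

AUC is the tie-corrected Mann–Whitney pair statistic. Uncertainty and model
comparison use DeLong's placement-value method: per-case and per-control
placements give `var(AUC) = S10/m + S01/n`, a normal 95% CI truncated to
[0, 1], and — because all models under one CV configuration share fold
assignments and are scored on the same knees — a paired z-test on the
difference of correlated AUCs.

Cross-validation is stratified k-fold (default 10) repeated R times; repeat
`r` draws folds from seed `seed + r`. The published protocol uses R = 300;
desk-scale runs here use R = 10–25, which is past the point where pooled
AUCs stabilise to ±0.005. Per-repeat out-of-fold scores are averaged per
knee into one pooled score vector on which all headline metrics are
computed; this aggregation (the protocol leaves it open) is the one that
yields paired score vectors for the DeLong test. Threshold metrics (BACC,
PPV, NPV) are evaluated at probability 0.5 (configurable); PPV/NPV are NaN
with a warning when no knee crosses the threshold. A permutation null
(`permute_labels=True`) permutes the response once per evaluation and uses
it throughout — fitting, scoring, metrics. Pooled out-of-fold null AUCs
center slightly below 0.5 (≈ 0.49 at n = 600): penalised fits chase noise
in the training folds whose complement necessarily anti-correlates, the
usual finite-sample pessimism of cross-validated nulls.

## 7. Pipeline and reproducibility

`run_pipeline` ties generation, labelling and evaluation together from one
JSON config; every stochastic stage derives from the single config seed,
and rerunning a config reproduces all numeric outputs bit-for-bit (the run
directory timestamp aside — fix `run_name` to pin it). The manifest lists
the config, library versions and a SHA-256 hash of every output file.

`scripts/acceptance.py` recomputes the headline quantities at these problem
sizes: 20 surfaces of 256² per roughness level for estimator recovery; a
5970-knee draw for relabelling agreement and the non-progressor fraction;
five independent 600-knee cohorts with 10-fold × 10-repeat CV for the
M1/M3 comparison, the DeLong p-value, the permutation null and the win
fraction — sizes at which each quantity's run-to-run variation is small
relative to the effects reported.

## 8. Known limitations

* The fitted models and AUCs describe synthetic cohorts; nothing here
  validates clinical performance on real radiographs.
* Tibial ROI placement is an input; no landmark detection is provided.
* The imaging fidelity renders stationary single-`H` patches per ROI; real
  trabecular texture is anisotropic and non-stationary within ROIs.
* Alternative fractal estimators (fractal signature analysis, Whittle),
  femoral ROIs, MRI features and non-logistic learners are out of scope.
* The AIC/LASSO interplay (penalise-then-select-by-AIC, adjustment
  covariates unpenalised) is one coherent reading of a protocol that names
  both tools without specifying their combination; both knobs are exposed.
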