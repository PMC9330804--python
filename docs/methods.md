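# Methods

## Overview

`rifpk` is a simulation-plus-benchmark study of how well off-the-shelf
supervised learners predict rifampicin pharmacokinetics (PK). It has three
parts:

1. a **virtual phase-2 trial**: 83 tuberculosis patients, once-daily oral
   rifampicin at 10–40 mg/kg for 14 days, doses rounded to the 150-mg tablet
   strength, with plasma sampling at pre-dose and 0.5, 1, 1.5, 2, 3, 4, 6, 8,
   12 and 24 h after dose on treatment days 7 and 14 (83 × 2 × 11 = 1826
   observations);
2. a **nonlinear mixed-effects (NLME) PK simulator** generating those
   concentrations, plus error-free 20-point rich profiles per occasion from
   which true AUC_0–24h is derived by noncompartmental analysis (NCA);
3. a **machine-learning benchmark**: LASSO, GBM, Random Forest and XGBoost
   predicting either the concentration series or AUC_0–24h under six
   input-richness scenarios, evaluated with subject-grouped 5-fold
   cross-validation.

## Structural PK model

One-compartment disposition with first-order absorption, Michaelis–Menten
(saturable) elimination, enzyme-turnover autoinduction and dose-dependent
bioavailability:

    dAg/dt  = −ka·Ag
    dAc/dt  =  ka·Ag − ENZ·VMAX·C/(KM + C),   C = Ac/V
    dENZ/dt =  kENZ·(1 + EMAX_ind·C/(EC50_ind + C)) − kENZ·ENZ,  ENZ(0) = 1

Each daily dose enters the gut as a bolus of F(dose)·dose. The enzyme pool
ENZ multiplies VMAX: sustained exposure stimulates enzyme production, raising
elimination capacity toward (1 + EMAX_ind)-fold over a time scale set by
kENZ — this is the autoinduction that makes week-2 exposure lower than
week-1 exposure at the same dose. Bioavailability rises saturably with dose
above a reference dose, capturing saturation of first-pass extraction:

    F(dose) = F_ref · (1 + F_EMAX·(dose − D_ref)/(F_ED50 + dose − D_ref))   for dose > D_ref.

Central volume scales linearly and VMAX allometrically (exponent 0.75) with
fat-free mass (FFM), the covariate the data-generating model actually uses.

### Default parameter values

The study this package emulates cites a published rifampicin population PK
model whose numeric estimates are not reproduced here; all values below are
**documented calibration defaults** living in configuration, not code. The
disposition and induction constants are patterned on the published rifampicin
autoinduction model class; the elimination capacity and the variability
magnitudes were calibrated once so that the simulated trial reproduces the
reported behavior of the original realization (median concentrations ~10–17
mg/L with a 95% interval reaching ~60–70 mg/L at the top doses, AUC_0–24h of
roughly 50–900 h·mg/L across 450–2700 mg, and a clear week-1 → week-2
exposure drop).

| parameter | default | units | meaning |
|---|---|---|---|
| ka | 1.7 | 1/h | absorption rate |
| V | 87.2 | L | central volume at FFM 45 kg |
| VMAX | 175 | mg/h | max elimination at baseline enzyme |
| KM | 35 | mg/L | Michaelis constant |
| kENZ | 0.0132 | 1/h | enzyme turnover (t½ ≈ 2.2 d; induction ~90% complete by day 7) |
| EMAX_ind | 1.16 | – | max fold-stimulation of enzyme production |
| EC50_ind | 0.07 | mg/L | half-max stimulation concentration |
| F_EMAX, F_ED50, D_ref | 0.5, 67 mg, 450 mg | – | dose-dependent bioavailability (F ≤ 1.5) |

Random effects are log-normal. Defaults: inter-individual variability (IIV)
on ka (ω² = 0.09), V (0.02) and VMAX (0.04); inter-occasion variability (IOV)
on ka (0.04) and F (0.02), re-drawn per treatment week; residual error
combined proportional (10%) + additive (0.05 mg/L), truncated at 0 mg/L.
These correspond to 14–31% coefficients of variation, clinically plausible
for rifampicin. Larger first-guess magnitudes (e.g. 27% CV on VMAX) were
rejected during calibration because the Michaelis–Menten nonlinearity
amplifies low-VMAX tails into exposure outliers that no covariate can
explain, which made the features-only prediction task substantially harder
than in the study being emulated (grouped-CV R² ≈ 0.2 rather than ≈ 0.55 for
the tree learners, with the linear model on par with the trees instead of
clearly behind them).

### Numerics

Dosing is integrated interval-by-interval (14 daily intervals) with
`scipy.integrate.solve_ivp` (LSODA, rtol 1e-8, atol 1e-10), the gut bolus
applied at each interval start and the state carried across intervals. An
evaluation time falling exactly on a dose time is evaluated *before* that
dose's bolus, so the pre-dose (TAD = 0) sample is the trough of the preceding
interval — on day 7 that is the steady-state trough of day-6 dosing, not
zero. IOV switches parameter values at the week boundary (dosing interval 8
onward uses occasion-2 ka and F). Against the closed-form linear
one-compartment solution (induction off, KM ≫ C_max) the solver is accurate
to better than 1e-4 relative; the residual Michaelis–Menten linearization
error is first-order in C_max/KM and dominates any comparison made at
moderate KM.

## Virtual population

Covariates are sampled parametrically, not bootstrapped: sex, HIV
co-infection and race (binary majority/other) are Bernoulli; height and age
are truncated normal; weight and FFM are drawn jointly per sex from a
correlated bivariate truncated normal (rejection sampling inside the
truncation box, additionally enforcing FFM < WT), preserving the WT–FFM–sex
dependence. BMI is derived as WT/(HT/100)². The distribution parameters of
the emulated trial are not published; the defaults describe an adult,
predominantly male African TB population (WT ~52–56 kg, FFM ~36–46 kg,
WT–FFM correlation 0.9) and are fully configurable.

Dose allocation is either `random` (each subject's mg/kg group drawn
uniformly from {10, 20, 25, 30, 35, 40}, dose = group × WT rounded to the
nearest 150-mg multiple, ties upward — "round up" is available behind a
switch) or `fixed_printed` (the realized allocation of the emulated trial:
14 dose levels from 450 to 2700 mg with fixed subject counts summing to 83).
The emulated study described "13 doses" but listed 14 values and counts; the
14 listed values are used.

## NCA

AUC_0–24h is computed per subject-occasion by the linear trapezoidal rule on
the 20-point rich grid (TAD 0, 0.25, 0.5, 0.75, 1, 1.5, 2, 2.5, 3, 4, 5, 6,
8, 10, 12, 14, 16, 18, 21, 24 h — the grid density is a design choice
spanning absorption and elimination; only the count of 20 is inherited).
Error-free concentrations are integrated by default, so derived AUCs are true
values by construction; a linear-up/log-down variant and integration of the
perturbed concentrations are available as sensitivity switches. On this grid
the trapezoid truncation error for realistic profiles is well under 1%.

## Scenarios and benchmark protocol

Base features: DOSE, OCC, BMI, AGE, SEX, RACE, WT, HT, HIV, FFM (+ TAD for
series targets). Scenarios add 0, 2 (TAD 2, 4 h) or 6 (TAD 0.5, 1, 2, 4, 8,
24 h) of the subject's own observed (error-perturbed) concentrations from the
same occasion; scenarios 1–3 target the 11-point series per occasion,
scenarios 4–6 target AUC_0–24h. Input time-points are deliberately also
predicted (a full profile from a limited sample); concentration features are
never pooled across occasions, since IOV would make cross-occasion features
leaky.

Outer evaluation: 5 folds grouped by subject ID (each subject in exactly one
test fold; fold sizes 17/17/17/16/16). Tuning: inner grouped 5-fold splits of
each outer-training set, selecting by mean inner-validation RMSE. LASSO, GBM
and RF are tuned by exhaustive grid search, XGBoost by a sequential heuristic
(four stages: learning rate + trees, depth + min child weight, row/column
subsampling, L1/L2 penalties; each stage's winner frozen). Grids are ordered
from more to less regularized and strict improvement is required to move, so
ties resolve toward regularization. Default grids are deliberately compact —
LASSO: 13-point λ grid 1e-4–10; GBM: 300 trees × depth {3, 5} × learning
rate {0.05, 0.1}; RF: 200 trees × max-features {√p, p/3} × min-leaf {5, 1};
XGB: three sequential stages (learning rate {0.05, 0.1} × trees {300, 500};
depth {3, 5} × min-child-weight {5, 1}; subsample {0.8, 1} × λ {2, 1}) — so
that the full 6 × 4 × 5 benchmark runs in minutes on one CPU; all grids are
configuration-overridable. The grids intentionally exclude very-low-capacity
settings (e.g. 100 trees at depth 2), which noisy inner validation tends to
select for the features-only scenario at this sample size, and exclude
column subsampling for boosting, which with only 11–17 features regularly
drops the dominant TAD feature from entire trees. LASSO features are
z-scored on training rows only (L1 penalties are scale-sensitive); tree
learners see raw features. Predictions are not clipped at zero by default
(negative predictions are a real, reported property of unconstrained
regressors here); clipping is opt-in.

Feature importances: impurity/gain importances for GBM/RF/XGB, normalized to
sum 1, ties broken alphabetically. LASSO importance is not evaluated by
default — its linear ranking is unreliable for this nonlinear problem — but
absolute standardized coefficients are available behind an override.

## Evaluation

R² = 1 − SS_res/SS_tot, Pearson r, RMSE (precision) and MAE (bias), in
target units. RMSE/MAE are reported fold-averaged with (min–max) range; R²
and Pearson are stored both fold-averaged and pooled over all test
predictions, and reports never conflate the two (fold-mean is the display
default). The prediction-interval VPC pools all outer-fold test predictions
(each subject predicted exactly once), and shows per-TAD empirical 2.5th /
50th / 97.5th percentiles of predictions and observations, plus TAD-pooled
overall intervals; quantiles use linear interpolation.

## Seeding

A single master seed fans out via named `numpy` SeedSequence substreams
(design, trial, ruv, folds, learners), so identical configurations are
byte-identical end-to-end and individual stages can be re-run in isolation.
Benchmark cells derive their own substreams from (seed, scenario, algorithm,
fold).

## What the generator does and does not emulate

The synthetic data reproduce the design (n, dosing, schedule), the dominant
PK nonlinearities (saturable elimination, autoinduction, dose-dependent F),
covariate correlation structure, and the three variability layers of the
study conditions. They do not emulate: real assay error structure
(heteroscedasticity beyond proportional + additive), dropout or missing
samples, dosing-time deviations, multi-level race, or any model
misspecification — real data are not generated by the very model class used
to describe them. Passing benchmarks here therefore demonstrate that the
protocol and learners behave as reported *under the stated generating model*,
not that the learned models would transfer to clinical data.

## Known limitations

- The structural/variability parameter values are calibrated defaults, not
  the unpublished estimates of the cited model; quantitative metric values
  shift with the realization and seed, so only the qualitative orderings
  (more input concentrations → better prediction; TAD/DOSE dominating
  importances; trees beating LASSO on the series task; LASSO strongest for
  AUC with rich input) are treated as reproducible claims.
- Fold-mean R² on 83 subjects is sensitive to which subjects land in which
  fold (a test fold whose observed variance is small can push R² far below
  its pooled counterpart); both variants are reported.
- The sequential XGBoost search is a heuristic: it can miss joint optima that
  an exhaustive grid would find.
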