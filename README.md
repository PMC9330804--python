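# rifpk

Simulation and machine-learning benchmark for rifampicin pharmacokinetic
(PK) prediction.

Rifampicin, the backbone of tuberculosis therapy, has notoriously complex
PK: saturable (Michaelis–Menten) elimination, autoinduction of its own
clearance over the first treatment weeks, dose-dependent bioavailability,
and high inter-occasion variability. Its efficacy tracks the exposure index
AUC_0–24h/MIC, so predicting either the full plasma concentration–time
profile or AUC_0–24h from sparse clinical data is of direct practical value
(e.g. as fast input to exposure–response models). This package asks: *how
well can generic supervised learners do that job, and how much observed
concentration data do they need?*

It provides, as a reusable, tested pipeline:

- **Virtual trial simulation** — 83 subjects with correlated covariates
  (weight, fat-free mass, height, age, sex, HIV, race), once-daily oral
  rifampicin 10–40 mg/kg for 14 days (doses rounded to 150-mg tablets),
  sampled at 11 time-points after dose on treatment days 7 and 14 (1826
  observations), generated from a nonlinear mixed-effects model
  (one-compartment, Michaelis–Menten elimination, enzyme-turnover
  autoinduction, dose-dependent bioavailability, IIV + IOV + residual error):

      dAg/dt  = −ka·Ag
      dAc/dt  =  ka·Ag − ENZ·VMAX·C/(KM + C),  C = Ac/V
      dENZ/dt =  kENZ·(1 + EMAX·C/(EC50 + C)) − kENZ·ENZ

- **Noncompartmental analysis** — true AUC_0–24h per subject-occasion by the
  linear trapezoidal rule on error-free 20-point rich profiles.
- **ML benchmark** — LASSO, GBM, Random Forest and XGBoost predicting the
  concentration series (scenarios 1–3) or AUC_0–24h (scenarios 4–6) from
  demographics + 0, 2 or 6 observed concentrations per occasion, under
  subject-grouped 5-fold cross-validation with inner grouped 5-fold
  hyperparameter tuning, plus gain/impurity feature-importance rankings and a
  prediction-interval visual predictive check (VPC).

See `docs/methods.md` for the model, default parameters and design choices.

## Worked example

The analysis is a chain of numbered drivers (library code lives in
`src/rifpk/`; everything is also scriptable via the `rifpk` CLI —
`rifpk run-all --seed 1 --out results` runs the whole chain):

```sh
python analysis/01_simulate_trial.py --seed 1 --out scratch/run
python analysis/02_derive_auc.py    --out scratch/run
python analysis/03_build_scenarios.py --out scratch/run
python analysis/04_run_benchmark.py --seed 1 --out scratch/run   # several minutes
python analysis/05_evaluate.py      --out scratch/run
```

`01_simulate_trial.py` prints, for seed 1:

```
subjects: 83  observations: 1826 (expected 83 x 2 x 11 = 1826)
dose levels (mg): [450.0, 600.0, 750.0, 900.0, 1050.0, 1200.0, 1350.0, 1500.0, 1650.0, 1800.0, 2100.0, 2250.0, 2400.0, 2550.0, 2700.0]
observed concentrations: median 15.2 mg/L, 95% interval 0.7-54.6 mg/L
median error-free concentration day 7: 16.5 mg/L, day 14: 14.2 mg/L (autoinduction lowers week-2 exposure)
```

i.e. the design produces exactly the planned 1826 concentrations, exposures
span the clinically observed range, and week-2 medians sit below week-1
(autoinduction). `05_evaluate.py` then prints the benchmark grid —
fold-mean R², RMSE and MAE per scenario × algorithm (abridged; seed 1):

```
 scenario algorithm  r2_fold_mean  rmse_mean  mae_mean
        1       GBM          0.66       8.01      5.62
        1     LASSO          0.52       9.80      6.86
        1        RF          0.53       9.36      6.65
        1       XGB          0.64       8.16      5.67
        3       GBM          0.96       2.81      1.73
        3     LASSO          0.74       7.16      4.83
        4     LASSO          0.57     154.21    104.75
        6     LASSO          0.99      21.54     15.29
        6       XGB          0.96      47.48     27.93
VPC (XGB, scenario 3): prediction 95% PI 0.8-50.6 mg/L (median 15.2); observed 0.7-54.6 mg/L (median 15.2)
scenario-1 importance ranking (GBM): DOSE, TAD, FFM, BMI
scenario-1 importance ranking (XGB): DOSE, TAD, BMI, FFM
```

Read: with features only (scenario 1) the tree learners reach R² ≈ 0.5–0.7
on the concentration series and beat the linear LASSO; adding 2 or 6
observed concentrations per occasion improves every algorithm monotonically
(scenario 3 R² ≈ 0.95, RMSE ≈ 3 mg/L); for AUC_0–24h with 6 concentrations
the *linear* model is the strongest (R² ≈ 0.99) because AUC is a summary
quantity nearly linear in the observed concentrations; and the importance
rankings recover the true design drivers (dose and time after dose) ahead of
the correlated body-size covariates. The VPC shows the predictions matching
the observed median exactly while slightly under-covering the upper exposure
tail — feature-driven regressors cannot reproduce variability that none of
the features explains.

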