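# roscopk

Population pharmacokinetics of oral roscovitine (seliciclib) and its
carboxylate metabolite M3 — simulation, SAEM estimation and model
diagnostics for a nonlinear parent–metabolite model with saturable
first-pass metabolism.

Roscovitine, a protein-kinase inhibitor evaluated in adult cystic-fibrosis
patients, shows strongly non-linear oral pharmacokinetics: part of every
dose is converted pre-systemically to the carboxylate M3, and the
converted fraction shrinks as the dose grows. `roscopk` implements the
full modelling chain for this system, for pharmacometricians who want to
simulate trials, refit the model on (synthetic or real) concentration
data, or study dose–exposure behaviour:

* **Structural model** — saturable bioavailability
  `F_dose = D/(D + D50)` with `F_M3 = 1 − F_dose`; absorption as a sum of
  two inverse-Gaussian input densities for the parent (modes `T1max` and
  `T1max + dT2max`, weights `π1`/`1 − π1`) and one for M3; linear
  two-compartment parent disposition with conversion `kmet` → M3 and
  first-order M3 elimination `ke`; one shared apparent volume V/F.
* **Population layer** — log-normal inter-individual variability on 7
  parameters with two correlated pairs, PPI and height covariate effects,
  proportional (parent) and combined (M3) residual error, 5 ng/mL
  quantification limits handled as left-censored data.
* **Synthetic-trial generator** emulating the originating study design
  (23 subjects, 200/400/800 mg arms, 8 nominal sampling times).
* **SAEM estimator** with censoring-aware MCMC, importance-sampling
  observed likelihood, BICc, empirical Bayes estimates and shrinkage;
  first-order(-lag) absorption comparison models.
* **Diagnostics** — NPDE and prediction-corrected VPC, goodness-of-fit
  tables.
* **Monte Carlo dose scenarios** — AUC(0–12h) distributions and
  parent/metabolite AUC ratios per dose.

See `docs/methods.md` for the model equations, numerical choices and
limitations.

## Worked example

Simulate 1000 subjects per dose arm from the final model and summarise
exposure:

```python
from roscopk.population import FINAL_MODEL
from roscopk.simulation import dose_exposure_table

print(dose_exposure_table(FINAL_MODEL, n=1000, seed=1).round(2).to_string(index=False))
```

```
 dose_mg  auc_parent_median  auc_parent_q1  auc_parent_q3  auc_met_median  auc_met_q1  auc_met_q3  ratio_median  ratio_q1  ratio_q3
     200             497.24         273.19         877.90         1322.26      773.27     2217.13          0.37      0.25      0.56
     400            1495.82         842.95        2523.52         2629.43     1541.92     4412.36          0.56      0.40      0.81
     800            4064.39        2319.01        6541.54         5224.72     3075.51     8767.78          0.75      0.56      1.04
```

AUCs are in ng·h/mL. Doubling the dose from 200 to 400 mg nearly triples
the parent's median exposure (497 → 1496) while M3's merely doubles
(1322 → 2629), and the median AUC ratio climbs from 0.37 to 0.75 across
the dose range — the signature of the saturable first pass: at higher
doses a larger fraction of the dose escapes conversion.

A full synthetic-study round trip from the shell:

```bash
roscopk generate --seed 1 --out trial.csv
roscopk fit --data trial.csv --seed 1 --out fit.json
roscopk npde --data trial.csv --model fit.model.yaml --out npde.csv --plot npde.png
roscopk vpc  --data trial.csv --model fit.model.yaml --out vpc.csv  --plot vpc.svg
roscopk simulate --dose 200,400,800 --n 1000 --seed 1 --out sim.csv
```

`fit.json` carries the estimated population parameters, −2LL, BICc and
shrinkage; the trace CSV lets you inspect SAEM convergence per parameter.

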