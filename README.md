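# fenofed

A mechanism-based population pharmacokinetic (PK) model of the fenofibrate
food effect, packaged for simulation, nonlinear mixed-effects estimation
and model evaluation.

## The scientific problem

Oral fenofibrate (a sustained-release 250 mg capsule) is rapidly and
completely converted by esterases to fenofibric acid, the active species
measured in plasma.  Its absorption increases substantially when the dose
is taken with food, and the increase depends on the meal's calorie load
and fat content.  Instead of a categorical "fed/fasted" covariate, the
model here represents the gastrointestinal mechanics explicitly with five
compartments — drug in stomach (X1), drug in duodenum (X2), fenofibric
acid in the central compartment (X3), meal calories in stomach (X4) and
duodenum (X5, in units of 100 kcal):

```
dX1/dt = -kg_eff · X1                 kg_eff = TVkg · (1 + E_food)^w(t)
dX2/dt =  kg_eff · X1 - kma_eff · X2  kma_eff = k_ma · (1 + E_bile · X5)
dX3/dt =  kma_eff · X2 - k_el · X3
dX4/dt = -kg' · X4
dX5/dt =  kg' · X4 - k_out · X5       C(t) = X3 / (Vc/F)_eff
```

Food acts three ways: gastric emptying of drug is boosted by a factor
`1 + E_food` during a window `[MTIME1, MTIME2)` after each meal (a
change-point covariate, `w(t)` the window indicator); duodenal calories
stimulate bile secretion and scale the combined metabolism/absorption
rate linearly; and the meal type shrinks the apparent central volume
(`E_Vc1` standard meal, `E_Vc2` high-fat meal), which encodes the gain in
absorbed fraction F as a fold change `1 / (1 + E_Vc)`.

Between-subject variability is log-normal (`e^eta`) on `kg` (shared with
`kg'`), `k_el` and `Vc/F`, with between-occasion variability (`e^kappa`)
on `k_el` and `Vc/F`, and a proportional residual error.  Estimation uses
a first-order conditional (FOCE-I) approximation of the marginal
likelihood: per-subject empirical Bayes modes by Newton iterations, the
objective from the linearised marginal with the residual variance taken
at the conditional predictions.

The package is aimed at pharmacometricians who want to simulate food-type
and calorie scenarios, re-estimate the model on their own (or synthetic)
crossover data in NONMEM-style event format, and run the standard
evaluation toolbox (PRED/IPRED/CWRES, visual predictive checks, subject
subsampling bootstrap).

## Worked example

```python
import numpy as np
from fenofed import (ModelParameters, FoodType, EventSchedule,
                     derived_fed_parameters, solve_profile)

params = ModelParameters()          # final-model estimates as defaults
for cal, ft in [(686.3, FoodType.STANDARD), (908.0, FoodType.HIGH_FAT)]:
    d = derived_fed_parameters(params, cal, ft)
    print(f"{ft.name:9s} kg {d.kg_fed:.3f} /h  kma {d.kma_fed:.2f} /h  "
          f"Vc/F {d.vc_fed:.2f} L  F-fold {d.bioavailability_fold:.2f}")

prof = solve_profile(
    params, EventSchedule.single_dose(250.0, FoodType.STANDARD, 686.3),
    t_grid=np.array([1., 4., 12., 24., 72.]))
print("conc @ 1,4,12,24,72 h:", np.round(prof.conc, 4))
```

prints

```
STANDARD  kg 0.067 /h  kma 0.23 /h  Vc/F 7.82 L  F-fold 1.65
HIGH_FAT  kg 0.067 /h  kma 0.24 /h  Vc/F 6.95 L  F-fold 1.86
conc @ 1,4,12,24,72 h: [0.1768 1.6843 3.6067 2.311  0.3104]
```

i.e. a standard 686.3 kcal meal raises gastric emptying by 61.7% for
6.94 h, raises the absorption rate constant from 0.198 to 0.23 h⁻¹, and
shrinks the apparent volume from 12.9 to 7.82 L — a 1.65-fold gain in
bioavailability (1.86-fold for the high-fat meal).  Concentrations are
fenofibric acid in µg/mL after a single 250 mg dose with the meal.

Fitting uses statsmodels-style model/results objects.  On a shipped
synthetic 6-subject crossover fixture:

```python
from fenofed import MBPKModel, ModelParameters
from fenofed.datagen import fixture_dataset

model = MBPKModel(fixture_dataset("small"), ModelParameters())
res = model.fit(free=("tv_kg", "k_el", "vc_over_f", "omega_kg"), se=True)
print(res.summary())
```

```
FOCE-I fit of the mechanism-based food-effect PK model
  subjects: 6   observations: 216
  OFV: 366.409   converged: True   iterations: 9 (238 evaluations, 5.5 s)

  parameter        estimate         SE     RSE%
  tv_kg            0.040126    0.00583     14.5
  k_el              0.17011     0.0692     40.7
  vc_over_f          18.078       7.71     42.7
  omega_kg          0.16797     0.0979     58.3
```

Diagnostics hang off the results object: `res.residual_table()`,
`res.vpc(n_replicates=1000)`, `res.bootstrap(n_replicates=1000,
fraction=0.9)`.  A synthetic 24-subject three-way crossover trial
(fasted / 686.3 kcal standard / high-fat period, sampling at 1–72 h) is
generated with `generate_trial(TrialDesign(), params, seed=...)`, which
also returns the hidden true random effects for recovery experiments.

The same pipeline is scriptable from a shell:

```sh
fenofed generate --n-subjects 24 --seed 1 --out run/
fenofed fit --dataset run/trial.csv --out run/fit/
fenofed vpc --dataset run/trial.csv --n-replicates 1000 --out run/vpc/
fenofed report --n-subjects 1000 --seed 1 --out run/report/
```

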