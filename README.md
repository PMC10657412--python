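# tdnode

Tumor-dynamic neural-ODE modelling of longitudinal tumor size data, with
kinetic-metric extraction and explainable overall-survival prediction.

## The problem

Clinical oncology trials record each patient's tumor burden as the sum of
longest lesion diameters (SLD, mm) at irregular visits before and after
treatment start. Classical tumor-growth-inhibition (TGI) analysis fits a
parametric law — e.g. the biexponential
`y(t) = y0 (e^{KG t} + e^{-KS t} - 1)` with growth rate `KG` and shrinkage
rate `KS` — and uses the per-patient rates to predict overall survival
(OS). `tdnode` replaces the hand-chosen law with a *learned* one: an
encoder–decoder neural ODE discovers a single vector field `f_θ` shared by
the whole population, while two per-patient encodings capture
patient-to-patient variability:

* an initial latent state `z(0) ∈ R⁴` from pre-treatment data (GRU
  encoder), and
* a 2-dimensional kinetic encoding from the seen post-treatment data
  (attention-LSTM encoder).

Each patient's measurement times are rescaled by their last seen
measurement time `T`, so the decoder integrates
`dz/dτ = f_θ(z, p̂)`, `τ = t/T ∈ [0, 1]` (and beyond 1 when
extrapolating), where `p̂` is the dimensionless encoder output. Because a
field satisfying the generalized homogeneity `f(z, p̂)·T = f(z, p̂·T)`
absorbs time rescaling into its parameters, the rescaled output
`p = p̂ · T` behaves as a pair of kinetic rate metrics in the patient's own
time units: multiply all times by `a > 0` and `p` is multiplied by `a`
*exactly*, while predictions are unchanged. Training enforces this
structure with prefix augmentation — every truncation of a patient's
series, each with its own `T`, labelled by the full series — which
simultaneously teaches unbiased extrapolation beyond a truncated
observation window `w` (default 32 weeks).

The learned metrics feed a gradient-boosted proportional-hazards layer
(xgboost Cox objective + Breslow baseline) evaluated by Harrell's c-index
with 5-fold cross-validation, explained with exact TreeSHAP attributions,
and linked back to the dynamics by decoding metric perturbations along the
first principal component of the metric cloud.

Because the trial data such models are developed on are access-restricted,
the package includes a synthetic-trial simulator (biexponential TGI
trajectories, proportional + additive noise, jittered visit schedules,
three arms, a kinetics-linked exponential survival model and
administrative censoring) with known per-patient ground truth, so every
stage is testable at desk scale.

## Worked example

```python
import numpy as np
from tdnode import SimConfig, simulate_trial, split_train_test, TrainConfig
from tdnode.model import TumorDynamicsModel

cohort, truth = simulate_trial(SimConfig(n_patients=100, seed=7))
train_c, test_c = split_train_test(cohort, 0.8, seed=7)

model = TumorDynamicsModel(train_c, TrainConfig.desk(epochs=10, seed=0))
results = model.fit()
print(results.summary())

rec = test_c.records[0]
print(np.round(results.predict(rec, np.array([0., 12., 32., 64.])), 1))
print(results.kinetic_metrics(test_c).head(3).round(3))
```

Output from this exact script:

```
Tumor Dynamics Neural-ODE Results
============================================
epochs                      10
learning rate               0.003
weight decay (L2)           0.001
batch size                  16
observation window (wk)     32.0
ODE tolerance               0.0001
latent dim c / metric dim k 4 / 2
SLD mean mu (mm)            77.547
SLD sd sigma (mm)           164.493
initial masked RMSE         0.5985
final masked RMSE           0.3956
training patients           80
============================================
[67.1 55.4 63.  73.6]
  subject_id   arm       p1      p2       T  os_weeks  event
0    sim0005  arm3  179.478  -2.633  30.096   130.000      0
1    sim0011  arm3  175.020  -5.160  30.636   130.000      0
2    sim0015  arm1  -27.698 -19.281  17.505    19.306      1
```

The masked RMSE is in Z-scored SLD units (multiply by `sigma` for mm);
the large `sigma` reflects the heavy right tail of simulated SLD under
two years of unchecked exponential growth in the worst arm. The predicted
curve for the first held-out patient dips from 67 mm at treatment start to
55 mm at week 12, then regrows — the first 32 weeks are *estimates* (data
the encoder saw), later times are *extrapolations*. Each metrics row is
one patient's kinetic encoding `p = p̂·T` plus their temporal scale `T`
(weeks): the two arm-3 shrinkers get similar encodings, well separated
from the arm-1 early-death patient, which is exactly the structure the
survival layer (`results.survival_analysis(test_c)`) exploits.

A command-line interface mirrors the library:
`tdnode simulate | fit | predict | metrics | evaluate | os | explain`
(see `tdnode --help`).

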