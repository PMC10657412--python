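# Methods

This note documents the model, the data conventions, the synthetic-trial
generator, the numerical choices, and what the shipped desk-scale
experiments do and do not demonstrate.

## Data conventions and normalization

A patient record is a strictly time-ordered series of SLD measurements
(mm), with treatment start at week 0; times ≤ 0 are pre-treatment.
Patients with at most one post-treatment measurement are excluded
(longitudinal modelling is undefined for them); the filter is idempotent.
Cohorts are split at the subject level (default 80/20, `round()` on the
training count, seed-determined).

SLD values are Z-scored with the *training* cohort mean μ and sample
standard deviation σ (n−1 denominator; the denominator convention is
recorded in the checkpoint, so either convention is reproducible). The
test cohort reuses the training statistics unchanged.

Times are rescaled per patient. With an observation window `w` (32 weeks
by default), the last seen index `l` is the largest index with time ≤ w,
the temporal scale `T` is the last seen time, and all of the patient's
times — including unseen ones, which map beyond 1 — are divided by `T`.
The last pre-treatment index β (1-based) is the largest index with time
≤ 0, falling back to 1 for patients with no pre-treatment visit, whose
first measurement then serves as the pre-treatment state. A measurement
at exactly t = 0 is deliberately both the last pre-treatment point and
the first post-treatment point; the two encoder inputs overlap at β.
Patients whose last seen time is ≤ 0 cannot be rescaled and are excluded
from modelling with a logged warning.

## Model

Four trainable modules:

* **Initial-condition encoder**: 2-layer GRU (hidden 10) over the
  pre-treatment (τ̃, ỹ) pairs, then a linear head to the latent initial
  state z(0) ∈ R⁴. Layer count is a design choice; the reference
  configuration states only "multi-layer" with hidden dimension 10.
* **Parameter encoder**: the seen post-treatment points (indices β..l,
  with τ̃_β set to 0 because the decoder evolves autonomously from τ = 0)
  are partitioned into adjacent-pair rows (τ̃_j, ỹ_j, τ̃_{j+1}, ỹ_{j+1}).
  Width-4 linear preprocessors feed a single-head scaled-dot-product
  attention (dim 100) for keys/values; the query is a width-4 residual
  stack followed by an LSTM (hidden 100). Attention output and query are
  concatenated and compressed by a residual stack (width 100, 3 blocks)
  to the 2-dimensional encoding p̂.
* **Vector field** f_θ: residual SELU network (hidden width 21, 3
  blocks) on the 6-dimensional augmented state [z, p̂]; its last two
  output components are forced to exactly zero, so the parameter channels
  are constant along every trajectory by construction. The output layer
  is zero-initialized (null field at the start of training) because a
  random residual field explodes over the long normalized horizons that
  prefix augmentation produces.
* **Reducer**: two fully connected SELU layers mapping the first four
  state components to the scalar normalized SLD; it cannot see the
  parameter channels.

### Units and the homogeneity structure

In rescaled time the dynamics obey dz/dτ = f(z, p̂) on τ ∈ [0, 1] (and
beyond 1 for extrapolation). If f satisfies the generalized homogeneity
f(z, p̂)·T = f(z, p̂·T), the dimensionless encoding plays the role of a
kinetic-rate–times–T group, and `p = p̂·T` is reported as the patient's
kinetic metric pair in their own time units. Two consequences, exact by
construction and regardless of training state:

* multiplying all of a patient's raw times by a > 0 multiplies `p` by a
  and leaves predictions at correspondingly scaled query times unchanged
  (weeks→days scales metrics by 7);
* homogeneity of the *learned* field is not architecturally enforced —
  it is encouraged by the augmentation scheme — and
  `homogeneity_defect()` reports the relative violation as a diagnostic.

The decoder consumes p̂ (dimensionless) rather than p; the survival layer
and all reports use p. Both are retained on every `KineticMetrics`.

### Augmentation, batching, loss

For every training patient, each prefix of length j = 2..m becomes its
own profile, renormalized by its own T = t_j, with labels spanning the
*full* parent horizon so the decoder is explicitly trained to extrapolate
past its input. The augmented count is exactly Σᵢ (mᵢ − 1). Augmentation
order is deterministic (subject id, then j); only the training seed
shuffles it. Labels start at index β with τ̃_β := 0; prefixes ending at a
non-positive time (impossible for the simulator's visit schedules) would
be skipped with a warning.

Batches left-pad heterogeneous members and carry binary masks. In the
default `pack` mode the masks gate recurrent-state updates and attention
rows, making batched computation *identical* to per-patient computation
(float-exact, verified to ~1e-14); the `repeat-first` mode reproduces the
alternative convention of padding with the first observation pair, which
perturbs recurrent states and is retained only for fidelity experiments.

The loss is the RMSE over all labelled positions of the batch, pooled
across members (so patients are weighted by their measurement count, and
the batched loss equals a per-patient loop exactly). Optimization is Adam
(default lr 5e-5, L2 weight decay 1e-3, batch size 8, 150 epochs in the
full-scale configuration); no schedule, clipping or early stopping.

### Integration: two routes

*Inference* (`integrate`, `predict_profile`) uses adaptive
Dormand–Prince 5(4) (scipy's RK45, rtol = atol = 1e-4 by default),
integrating segment-by-segment so every requested time is an exact step
endpoint — this removes dense-output interpolation error and is what
makes the solver agree with a dense fixed-step RK4 reference to ≤ 1e-3
at tol 1e-4 on smooth fields.

*Training* uses discretize-then-optimize: a fixed-grid RK4 on the
autodiff tape, where each batch member is advanced with its own uniform
step (horizon divided by a member-specific step count, target step 0.25
normalized-time units, 8–64 steps), and off-grid label times are read off
by member-local cubic Hermite interpolation. Because the grid of a member
depends only on that member, batched and unbatched trajectories are
bit-identical — adaptive batched stepping could not guarantee this. The
continuous-adjoint alternative would require backpropagating through an
adaptive solver; at the network sizes used here the discretize-first
route is simpler, exactly pack-invariant, and its gradient is the
gradient of the actually-computed loss.

The autodiff engine itself (`_autodiff.py`) is a small float64
reverse-mode tape over numpy arrays, finite-difference-verified for every
operation the networks use.

## Evaluation protocol

Predictions are compared to observations at post-treatment measurement
times only (the decoder's domain starts at τ = 0), in mm. Measurements
at t ≤ w are *seen* (estimates), later ones *unseen* (extrapolations).
RMSE and R² (1 − SS_res/SS_tot against the resample's own label mean) are
bootstrapped by resampling prediction–label pairs globally with
replacement (1000 resamples by default) and summarized as median ± MAD.
Residual-vs-time bias uses LOWESS (fraction 0.3) on each of 200 bootstrap
resamples with a pointwise 2.5/97.5 percentile band. The window sweep
re-normalizes, re-predicts and re-summarizes at w = 16/24/32 weeks.

## Survival layer

The per-patient metrics (p₁, p₂) — optionally PCA-reduced
(mean-centered, unscaled, since both coordinates share units; loadings
sign-fixed to a nonnegative leading coordinate) and optionally joined
with baseline covariates — feed a gradient-boosted Cox model (xgboost
`survival:cox`; 100 rounds, depth 3, learning rate 0.1 as overridable
defaults). Risk orientation is fixed: higher score = higher hazard.
Survival curves come from the Breslow baseline cumulative hazard of the
training data (S(0) = 1 guaranteed). Risk margins are evaluated as the
double-precision sum of leaf values over the boosted trees (the boosting
library's own predict rounds to single precision). Harrell's c-index
(lifelines) with patient-level 5-fold cross-validation, seeded folds,
refolding with a shifted seed if a fold lacks events. Shapley
attributions are computed exactly in double precision by subset
enumeration with the cover-weighted conditional expectation (the TreeSHAP
convention; feasible because the feature sets have at most ~8 features,
with a library fallback beyond that) — local additivity then holds to
1e-15, and the values agree with the library's single-precision TreeSHAP
to ~1e-6.
Principal-component perturbation decodes p + δ·loading (δ on an even
grid over [−2, 2], 500 perturbations plus the original at δ = 0) with
the patient's own z(0), dividing by T before decoding since the decoder
consumes the dimensionless encoding. Kaplan–Meier curves per arm are
compared with the pointwise median and 2.5/97.5 percentiles of the
per-patient predicted survival curves.

## Synthetic-trial generator

Trajectories follow the biexponential TGI law
y(t) = y₀(e^{KG t} + e^{−KS t} − 1) for t ≥ 0 and y₀e^{KG t} before
treatment — chosen because its parameters are exactly the classical
kinetic quantities (KG, KS, nadir time ln(KS/KG)/(KG+KS)) that make
parameter-recovery experiments meaningful. Defaults, chosen once as
trial-realistic: baseline y₀ log-normal (median 60 mm, CV 40%); three
arms with (KG, KS) log-normal medians (0.02, 0.02), (0.01, 0.04),
(0.005, 0.08) /week, CV 40%; proportional noise 10% + additive 2 mm,
clamped at 0 (retained zero-SLD visits are the complete-response
analogue); one pre-treatment visit at −4 weeks and post-treatment visits
every 6 ± 1 weeks up to 104 weeks or death. Survival is exponential with
log hazard −4.3 + log KG − log KS (growth hurts, shrinkage protects;
intercept calibrated so the worst arm's median OS is ≈ 50 weeks and the
overall event fraction ≈ 0.4 under administrative censoring at 130
weeks). Early deaths that would leave fewer than two post-treatment
visits are redrawn, so every emitted patient is eligible. Synthetic
baseline covariates (noisy transforms of the kinetics plus pure-noise
age) stand in for real trial covariates. All randomness flows from one
seed; output files are byte-reproducible.

What the generator does *not* emulate: RECIST categorization, informative
dropout other than death, dose modifications or PK, lesion-level data,
measurement-error correlation within patient, and any cap on tumor
burden — unbounded exponential growth over two years produces a heavy
right tail (σ of order 100 mm) that is harsher than real SLD
distributions. Passing tests on this generator therefore demonstrate
mechanism recovery and calibration of the pipeline, not clinical
performance on trial data.

## Desk-scale study and known limitations

The shipped experiments (test fixture and `scripts/acceptance.py`) use a
250-patient trial, a 200/50 split, reduced widths (GRU 8×2, LSTM and
attention 24, postprocessor 32×2, vector field 16×2, reducer 8), Adam at
lr 3e-3, batch 16, 40 epochs — sizes chosen so a full study runs in
minutes on one CPU. At this scale:

* all exact structural properties hold to float precision
  (units-equivariance, packing invariance, frozen parameter channels,
  loss pooling, augmentation conservation);
* the first principal component of the learned metrics tracks the true
  log(KS/KG) on held-out patients with |Spearman ρ| ≈ 0.9;
* unseen-extrapolation RMSE decreases monotonically as the observation
  window widens from 16 to 32 weeks;
* the survival layer's cross-validated c-index from learned metrics
  matches (and slightly exceeds) the c-index of the true simulated log
  hazard;
* the model is *not* yet pointwise-unbiased: the LOWESS residual band
  (half-width ≈ 1.5 mm at n ≈ 700 prediction pairs) sits several mm from
  zero at early and late times. The bias shrinks roughly in half between
  20 and 40 epochs and is an under-training/capacity effect of the
  reduced configuration; the residual-band diagnostic is reported
  honestly rather than relaxed, and the injected-bias positive control
  confirms the diagnostic itself has power.

Other limitations: no dosing/PK inputs or covariate-conditioned
encoders; no alternate solver families; no competing risks or
time-varying covariates in the OS layer; single-lesion-sum scalar only.
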