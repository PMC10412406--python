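# Methods

## Model

`survfuse` predicts right-censored survival from two sample-aligned omics
views under a proportional-hazards assumption λ(t|x) = λ₀(t)·exp(risk(x)).
The risk function is a small neural network with four stages:

- **Per-omics highway encoders.** A linear projection p → l followed by three
  gated blocks `x_out = H(x)·T(x) + x·(1 − T(x))`. H is affine + ReLU and T an
  affine + sigmoid gate. The architecture leaves the transform activation and
  the input-width reduction open; we use a single linear projection and ReLU
  transforms, and initialise gate biases at −1 so training starts close to the
  identity carry (a stable regime for deep gated stacks).
- **Factorized bilinear model.** The j-th cross-omics feature of patient i is
  the bilinear form z⁽¹⁾ᵀ Uⱼ Vⱼᵀ z⁽²⁾, evaluated as an inner product of the two
  rank-d projections; the l×l interaction matrix is never materialised. Rank d
  is not identifiable from the outputs alone; default d = 16 trades expressive
  interaction rank against parameter count at l = 50.
- **Feature and graph fusion.** Fused features Z = (Z⁽¹⁾+Z⁽²⁾) ⊕ Z⁽ᶜ⁾ (width
  l + m). Per-omics affinity graphs use an exponential kernel on squared
  Euclidean distance with bandwidth μ·δ², δ² the median off-diagonal squared
  distance of that view — a scale-free choice, so the graphs are invariant to
  isotropic rescaling of the features. Directed k-nn support (self excluded,
  distance ties broken by ascending sample index) is symmetrised as
  (A + Aᵀ)/2 before use; mutual-knn and elementwise-max symmetrisation are
  available via `symmetrize=`. The fused graph is the elementwise mean, and
  the convolution matrix Â = D̃^{−1/2}(A+I)D̃^{−1/2} has spectrum in [−1, 1].
- **GCN + Cox head.** Z_h = sigmoid(tanh(Â Z W₁) W₂); risk = βᵀZ_h with no
  intercept (the partial likelihood is shift-invariant, so an intercept is
  unidentifiable). Graph mixing is applied in the first layer only; the
  second layer is dense. A `two_hop` flag applies Â in both layers for the
  conventional variant, off by default.

## Loss, ties and the baseline hazard

Training minimises the negative Cox partial log-likelihood with risk set
R(i) = {j : Oⱼ ≥ Oᵢ} — the standard convention in which patient i belongs to
its own risk set and tied event times enter each other's denominators
(Breslow tie handling). A strict-inequality risk set would make the
single-patient term ill-defined, so the inclusive form is used deliberately.
The log-sum-exp is stabilised by max subtraction. After training, the
cumulative baseline hazard is the Breslow step function
H₀(t) = Σ_{t_k ≤ t} d_k / Σ_{j∈R(t_k)} exp(risk_j); with all risks zero it
reduces exactly to the Nelson–Aalen estimator, which the tests exploit as an
independent oracle.

Optimisation is deterministic full-batch Adam (learning rate 2e−4) for at
most `max_epochs` = 500 epochs, stopping early when the training loss fails
to improve by `tol` = 1e−6 for `patience` = 20 consecutive epochs. Cohorts of
a few hundred to ~1000 patients make full-batch training exact and cheap; no
minibatching, dropout, weight decay or other regularisation is applied. All
parameters are Glorot-uniform initialised from a single seeded generator, so
a fit is bit-reproducible from `random_state`. The entire network is NumPy
with hand-derived analytic gradients; every gradient path is verified against
central finite differences in the test suite.

## Transductive evaluation

The estimator's `fit(X, y, train_mask=...)` builds the graph over **all**
samples it is handed while restricting the loss (and the Breslow estimate) to
the masked training samples: held-out patients participate in message passing
but never in the objective. This transductive default reflects how
graph-based survival models are usually scored; a stricter
`graph_mode="test_only_graph"` trains on a graph over the training samples
only and folds new patients into the graph purely at prediction time.
`predict(X_new)` always rebuilds the affinity graph over fit ∪ new samples
with the fitted weights held fixed.

## Ablation wirings

All variants share the same two-layer head so that wiring, not capacity, is
compared: FULL (fused graph + fused features); NO_FBM (fused graph, additive
features only, width l); NO_GRAPH and HIGH_FF (identity graph, fused
features — definitionally the same network); LOW_FF / FBM_FF (identity graph,
one feature block); GCN_SINGLE (one omics' encoder and graph). Hidden widths
default to h1 = 30, h2 = 15 (unspecified in the source architecture; chosen
as a gentle taper from the fused width 60 to the Cox head).

## Evaluation metrics and protocol

- **Concordance index.** Over pairs where the earlier observed time is an
  event (pairs whose earlier time is censored, or with both members censored,
  are not comparable): 1 for a correctly ordered pair, 1/2 for tied risks
  (Harrell convention — a strict inequality would penalise ties
  asymmetrically), 0 otherwise.
- **Cumulative AUC.** For each distinct event time t, cases are patients with
  an *observed event* before t and controls are patients with Oⱼ > t; scores
  are accumulated over all (case, control, t) triples. Restricting cases to
  events is deliberate: a patient censored before t contributes no known
  event and cannot serve as a case.
- **Stratification.** Median split of risks with boundary samples assigned to
  the low-risk group (deterministic); two-group log-rank test with a 1-df
  chi-square p-value. Kaplan–Meier curves and the log-rank statistic are
  computed by lifelines, pinned by hand-worked fixtures in the tests.
- **Protocol.** Repeated random 80/20 holdout (default 20 repeats, one seed
  per repeat); a draw whose train or test part contains no event is resampled
  with a warning. The graph neighbourhood size k is selected by 5-fold inner
  cross-validation on training data (folds stratified by event status), ties
  going to the smaller k; `k_sensitivity_sweep` reports the robustness of the
  C-index across k.

## Preprocessing

Fixed stage order per omics view: align samples (ID intersection, survival
table order) → drop features with > 10% missing values → impute remaining
gaps by weighted k-nearest neighbours (k = 10, inverse plain-Euclidean
distance over mutually observed features; zero-distance donors short-circuit
to their mean) → log(x + 1), natural log by default with base 2 available →
keep the top 6000 gene / 600 microRNA features by variance (ties keep
original column order) → z-score each feature with the population (1/n)
variance convention. On a complete matrix the first two stages are identities,
which the tests assert. An optional quantile-discretisation stage (4
equal-probability bins, re-centred to zero mean) exists but is off by
default: the downstream encoders, kernel graphs and bilinear fusion all
assume continuous inputs, and coarse-graining them loses ranking information.

## Synthetic cohorts

`simulate_cohort` emulates the statistical structure the model assumes:
cluster-structured latent factors read out into two correlated omics views
(shared neighbourhood structure), plus a planted log-hazard
risk = β_add·(w₁ᵀx⁽¹⁾ + w₂ᵀx⁽²⁾) + β_cross·(x⁽¹⁾ᵀ M x⁽²⁾) with sparse random
additive weights (20 informative features per view) and a rank-3 cross-omics
interaction, both at their natural scale. Event times are exponential
(optionally Weibull via `weibull_shape`) with rate baseline_scale·exp(risk −
mean risk); the mean-centring keeps time scales stable across effect sizes.
Censoring is an independent exponential whose rate is calibrated to a target
proportion — in closed form (mean_i c/(c+λᵢ), solved by Brent's method) for
the exponential case, by seeded Monte-Carlo bisection for Weibull shapes.

Defaults sketch a mid-sized cancer cohort at reduced feature dimensionality:
n = 300 patients (real cohorts of this kind run ~370–1020), 500 gene and 100
microRNA features (scaled down from the 6000/600 kept after real-data
filtering), three latent clusters, unit observation noise, 50% target
censoring (real cohorts span roughly 0.39–0.86). The generator does **not**
mimic sequencing count noise, library-size effects or real marginal
distributions, so passing recovery tests demonstrates that the estimator
finds planted additive and multiplicative structure in correlated Gaussian
views — not that it attains any particular accuracy on real tumor cohorts.

## Problem sizes used by tests and the acceptance script

Unit and property tests run on cohorts of 5–120 samples with reduced network
widths. End-to-end checks use n = 300 cohorts: signal recovery averages 5
cohorts × 5 holdout repeats, the ablation comparison 8 cohorts, and the
acceptance script 3 cohorts × 3 repeats (recovery) and 5 cohorts (ablation),
with 500–1000 null simulations for log-rank calibration. These sizes were
chosen so the full pipeline, including training, demonstrates its behaviour
at desk scale.

## Known limitations

- Proportional hazards with a time-constant risk score: no time-varying
  covariates or competing risks.
- The cross-omics (FBM) advantage over the additive-only wiring is real but
  modest on simulated cohorts — a flexible encoder/GCN stack can partially
  approximate low-rank multiplicative structure — so ablation orderings are
  statistical, not strict, statements.
- Dense n×n graphs and full-batch training are exact but quadratic in the
  cohort size; the implementation targets cohorts up to a few thousand
  patients.
- Metrics are the plain (uncorrected) concordance and cumulative AUC; no
  IPCW/Uno-style censoring correction is provided.
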