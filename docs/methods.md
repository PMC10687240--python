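# Methods

This note documents the models, parameter choices and limitations of the
package in its own terms: what each stage assumes, which knobs matter,
and what the synthetic experiments do and do not demonstrate.

## Problem setting

A cohort of `P` participants is measured at `N` discrete, equally spaced
waves (`t_1..t_N`, biannual in the motivating setting). Each
participant-wave carries a vector of continuous features (partially
observed) and three binary survey flags. The outcome at each wave is a
binary disease label derived by OR over inclusive diagnostic thresholds
(HbA1c ≥ 6.5 %, fasting plasma glucose ≥ 126 mg/dL, 120-min OGTT glucose
≥ 200 mg/dL) and the survey flags. Participants already positive at
`t_1` are excluded; the prediction target of interest is the label at
`t_N`.

Labels are treated as properties of the wave at which the criteria are
met; prediction horizons are expressed entirely through the windowing
module (each task's label step strictly follows its input steps), rather
than by shifting the label series itself.

## Synthetic cohort generator

The generator is first-class, tested code: it defines the study
conditions for every downstream stage.

**Mechanism.** Each participant has a latent glycemia trajectory
`z_t = z_{t-1} + d_p + σ ε_t` (random walk; per-participant drift
`d_p = μ + 0.15 η_p`, step noise σ = 0.2). The three biomarkers are
affine-plus-noise transforms of `z_t` whose slopes put all three
diagnostic thresholds near `z ≈ 1.7–1.8`, so the criteria are partially
redundant, as clinically expected. The disease state is absorbing: once
a participant crosses any threshold, the latent level is floored at 1.9
and fasting glucose is held at or above its threshold, so derived
prevalence is non-decreasing in time. Survey flags switch on only with
probability (0.6, 0.4, 0.15) given diagnosis in the prior wave —
mirroring "diagnosed in the last two years" recall items — and therefore
never create labels on their own.

**Calibration.** Two scalar knobs are solved by bisection against the
derived-label prevalence: the baseline latent level (first-step target)
and the common drift μ (last-step target), each to well within the ±1
percentage-point contract; unreachable targets raise a `CalibrationError`
naming the target. All random draws are made once per seed and reused
across bisection evaluations, so generation is bit-reproducible.

**Features.** `n_informative` non-biomarker features are linear in `z_t`
with signed couplings drawn in ±[0.6, 1.2] (signs alternate), plus unit
noise; remaining features are low-rank correlated Gaussian noise
independent of the outcome. Missingness is injected MCAR with
per-feature rates drawn from a configured range; the missingness
mechanism of real registry data is unknown, so MCAR is an explicit
assumption, not a claim — MAR/MNAR variants are out of scope. Labels
always derive from pre-mask values (ground truth is retained).

**What passing tests show.** That the pipeline recovers planted signal
under MCAR missingness and absorbing dynamics. They do not show
performance on real cohort data: real feature distributions, units,
informative missingness, measurement drift and label noise are not
modelled, and the synthetic signal (biomarkers included among the
features) is far stronger than the real-world case, which is why the
scaled experiment's AUCs sit near 99 rather than near 92.

## Bidirectional recurrent imputation

Per direction (forward and time-reversed), the imputer maintains a
hidden state `h` that is decayed per step by `γ_t = exp(−relu(W_γ δ_t +
b_γ))`, where `δ_t` is the per-feature time since last observation;
the decayed hidden state regresses the current feature vector
(`x̂_t = W_o (γ_t ⊙ h_{t-1}) + b_o`), observed entries overwrite the
estimates, and the complement vector together with the mask feeds a tanh
recurrent cell. The loss is mean squared reconstruction error on
observed entries in both directions plus a consistency penalty
`λ ‖x̂^f − x̂^b‖²` (λ = 0.1). Imputed values are the unweighted mean of
the two directional estimates, inverse-transformed from per-feature
z-scores fitted on observed entries; observed cells are preserved
exactly. The feature-regression branch and the classification head of
the original multi-task formulation are omitted: the imputer's only job
here is to feed a separate classifier.

Defaults: hidden size 16 (pipeline) / 32 (library default), Adam at
1e-2, 40–100 epochs, minibatch 128–256 participants. Gradients of the
full unrolled objective are hand-derived and checked against finite
differences (relative error ~1e-8). Constant features get unit SD in
normalization to avoid division by zero. The imputer is applied twice in
the pipeline: on the wide post-filter panel before selection, and again
on the selected features only, so that uninformative features cannot
distort the final imputation.

A per-feature linear-interpolation-then-mean fallback (`method="interp"`)
exists for fast smoke runs and as an independent comparison point.

## Feature selection

Features with ≥ 80 % missing values at *any* wave are dropped first (the
bound is strict: survival requires missing fraction < 0.8 at every
wave). The design table pairs each participant-wave row over waves
`1..N−1` with that wave's label (a `last_step` layout — step `N−1`
features against the step-`N` label — is selectable; neither layout is
claimed to be canonical). Features are z-scored; an L1-penalized linear
regression of the 0/1 label is fitted over a log-spaced penalty grid
(16 points, 10^−3.5..10^−0.5); 5-fold CV chooses the penalty by the
one-standard-error rule (the sparsest penalty within one SE of the
minimum CV loss), the standard parsimony rule for selection-oriented
lasso fits. An L1-logistic family is available behind a flag.
Constant columns are dropped with a warning. Selected features are the
nonzero support, ranked by |coefficient| with name tie-breaks.

## Classifiers and progressive training

The classifier is a stacked recurrent network (LSTM by default; GRU and
tanh-RNN run in the identical loop for baselines) with inverted dropout
between layers and a linear head on the final time-step's top hidden
state; the loss is binary cross-entropy on the sigmoid output. Batch
size 32 and dropout 0.2 are the study's stated settings; optimizer
(Adam, 1e-3 library default), hidden size (64 library default), layer
count (4 default; 5 is a config switch that mainly buys variance) and
epoch budget (100 with patience 15) are package defaults, all exposed in
`TrainConfig`. All cells' backward passes are finite-difference checked.

After each epoch the validation AUC is computed with dropout disabled;
the returned state carries the weights of the best epoch (earliest on
ties, epoch 0 = the initialization acting as a fallback). In a
progressive sequence, task 1 starts from a seeded fresh initialization
and task `k > 1` starts from task `k−1`'s best-epoch weights exactly
(identity asserted in tests). Variable sequence lengths across tasks
need no padding: recurrent cells accept any length, only the feature
width is fixed. Participants who convert at an intermediate wave remain
in later tasks with their labels held at 1 (absorbing), an assumption
the windowing module makes explicit rather than silently dropping them.

A single-class validation fold makes AUC undefined and raises
immediately with a re-stratification hint rather than returning a
degenerate score.

## Evaluation and ensembles

Folds (default 5) are stratified on the final wave's label; one fold
assignment per repetition is reused across all tasks of all submodels,
so held-out participants are unseen by every training stage of that
repetition, and the held-out fold doubles as the validation set for
best-epoch selection (the study conditions give no separate tuning
split; with one held-out set, epoch selection and reported metrics
necessarily share it). Feature z-scoring is fitted on the training folds
only. Each repetition reshuffles folds with a fresh derived seed
(all derived seeds stay below 2^31); the per-repetition score of a
configuration is its fold mean, and tables report mean ± SD over
repetitions (SD over repetition means, not over all fold values — the
alternative convention would shrink SDs roughly by √folds).

Non-progressive baselines train once on fixed input-step subsets
predicting step `N` — at `N = 7`: `t1–t6`, `t4–t6`, `(t2, t4, t6)`,
`(t3, t6)` — and GRU/RNN baselines use the full-history subset.
Ensembles soft-vote member submodels' final-task probabilities with
equal weights; the sweep covers both scheme-pairs, all four triples and
the quadruple (7 combinations), optionally plus the (1,4) and (2,4)
pairs. Classification threshold for accuracy/recall/precision/F1 is 0.5
(exposed in config); AUC uses midrank tie handling.

## Problem sizes

The packaged default experiment uses 1000 participants × 7 waves × 12
features (5 informative), prevalence calibrated 4 % → 16 %, missing
rates 5–30 %, hidden size 16, 2 recurrent layers, 12 epochs with
patience 4, and 3 repetitions × 5 folds — sizes chosen so the complete
sweep (15 progressive tasks + 6 baselines per fold, 19 configurations
scored) runs in a few minutes on a single CPU while leaving every
qualitative contrast (progressive vs non-progressive, singles vs
ensembles) measurable. Larger cohorts and deeper networks are purely a
matter of config.

## Known limitations

- MCAR-only missingness; no informative-missingness mechanisms.
- The generator does not reproduce real cohort feature inventories,
  units or distributions; near-ceiling AUCs on synthetic data are a
  property of the planted signal, not a performance claim.
- No significance testing between configurations; reports are
  descriptive mean ± SD.
- No type-1/type-2 disease discrimination; labels are a single binary
  state.
- Single-threaded numpy training: practical for panel-scale data
  (thousands of participants, tens of features), not for long sequences
  or wide feature spaces.
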