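# Methods

## Data model

A patient record is discretized into half-open 6-month age bins
[k·0.5, (k+1)·0.5) years; a bin with at least one heart-failure
hospitalization (HFH) carries the label y = 1. Each step's covariate vector
holds 19 numbers: age (years), two one-hot sex indicators, four one-hot
congenital-lesion-type indicators (severe / shunt / valvular / other), 11
binary co-morbidity (CM) indicators and a cumulative surgery count collapsed
across surgical-complexity levels. The model input at step i is this vector
concatenated with the step-i HFH indicator — 20 numbers in total — and the
training target is the HFH indicator at step i+1 (plus the three acute-CM
indicators at i+1 for the multi-task variant). Eight CMs are *static*:
encoded 1 from their onset bin onward (absorbing), reflecting lifelong or
chronic-after-diagnosis conditions. The three *acute* CMs (acute myocardial
infarction, infective endocarditis, sepsis) may recur and are 1 only in bins
containing an event. Modelling is restricted to steps at age ≥ 40, where
most HFHs occur; truncated timelines are re-indexed and patients left with
fewer than two steps are dropped.

## Architectures

All variants share a dense input layer (width = hidden width) and a sigmoid
output head, and differ in the recurrent core:

* **GRU cell.** z = σ(W_z[h, x]), r = σ(W_r[h, x]),
  h̃ = tanh(W_h[r⊙h, x]), h′ = (1−z)⊙h + z⊙h̃, with separate weights and
  zero-initialized biases for each gate. The update is a convex combination
  of a bounded state and a tanh term, so the state stays in (−1, 1).
* **DHTM.** A stack of GRU blocks (default 2, configurable 1–4) with
  pre-norm layer normalization and residual connections around each block;
  the initial dense layer makes block input/output widths equal so the
  residual add is well-defined. With all GRU weights zero each block passes
  its input through unchanged — the gradient path the residuals exist for.
* **DHTM+C.** Branch 1: dense → GRU → affine gives the 3 acute-CM logits;
  their sigmoid is the CM prediction ĉ. Branch 2 consumes the *pre-sigmoid*
  CM logits through dense → GRU. The HF head sees [GRU1 state, GRU2 state,
  ĉ]. No residual connections or layer normalization: the auxiliary CM loss
  already injects gradient at every time step.
* **LSTM baseline.** Standard input/forget/output-gate recurrence (forget
  bias initialized to 1), same wrapper, no normalization or residuals.

Default hidden width is 64, matching the weight-inspection convention of one
row per input × 64 hidden units; the test suite trains width-32 models,
which are sufficient for the synthetic signal and fit desk-scale runtimes.

Weight initialization is uniform with fan-in scaling from a seeded
generator; all randomness (initialization, batch order, splits, simulation)
derives from explicit integer seeds, and the pipeline derives component
seeds deterministically from one global seed.

### Input normalization

Raw inputs mix binary indicators with age in tens of years. Each input
column is centered at its training-split mean and scaled by its standard
deviation *only when that deviation exceeds 1* — so age is brought to unit
order while binary indicators keep their natural scale rather than being
inflated by a small denominator. The (mean, scale) pair is part of the
trained model's encoding contract: it is stored in the checkpoint and
applied identically during evaluation and rollout feedback.

## Objective and training

Events are rare (a few positive steps per positive patient), so the default
objective is the α-weighted focal loss with α = 0.25, β = 2; β = 0
recovers α-weighted cross-entropy exactly, and plain cross-entropy is
available. For DHTM+C the four output channels (HF + 3 acute CMs) are
summed with equal weight, so the total decomposes exactly into an HF term
and a CM term, both logged per epoch.

Training is teacher-forced: observed y_i and c_i are the next-step inputs.
Variable-length sequences are padded to the batch maximum with a step mask;
masked steps contribute zero loss. Reduction is sum over time steps, mean
over patients in the batch, which keeps the gradient scale stable across
batch sizes. Optimization uses Adam (lr 1e-3) with batches of 64 patients
for 30 epochs by default; probabilities are clamped to [1e-7, 1−1e-7]
before logs so the loss is always finite, and a non-finite loss aborts
training with the epoch named. Splits are patient-level — never by time
step — at 63.75% train / 11.25% validation / 25% test, sized by flooring
the validation and test fractions and giving the remainder to train.

Static baselines flatten each timeline into independent
(input at t−1 → label at t) rows: L2 logistic regression, and a linear SVM
(C = 1) whose decision values are mapped to probabilities by a Platt-style
sigmoid fitted on the training rows.

## Trajectory rollout

After a forward pass over the observed window, covariates are frozen at the
last observed values and the model's predicted HFH probability replaces the
HFH input channel (DHTM+C also feeds back its three predicted acute-CM
probabilities). The raw probability — not a thresholded value — is fed back
by default, with binarized feedback available as an option; age is frozen by
default (the "fix the last observed inputs" convention) with an option to
advance it half a year per step; surgery never advances. Feedback cadence is
configurable (default: every step). Rollout is exactly prefix-consistent: a
horizon-H forecast agrees bit-for-bit with any shorter forecast on their
common prefix. The standard evaluation window gives each model 30 observed
steps (15 years) starting at age 40 and scores the next 20 steps (10
years); patients with shorter records are skipped and reported.

## Thresholds and evaluation

Pooled per-step training scores define: frequency = k/(m+k) (positive steps
over all steps), conservative = p̄ (mean score of true event steps),
balanced = (p̄+n̄)/2, and the optimized threshold = the F1-maximizing value
on the validation split over a fixed grid of step 0.001 on [0, 1], ties
broken toward the smallest threshold. Next-step evaluation reports AUROC
(the Mann–Whitney pairwise statistic, ties counting one half) and AUPRC in
the step-function / average-precision convention — chosen because it never
optimistically interpolates between PR points — over pooled (patient, step)
predictions. Trajectory evaluation pools, for each future year y, horizon
steps 2y−1 and 2y across patients and reports F1 / precision / recall at
the chosen threshold plus per-year AUROC/AUPRC (NaN when a year is
single-class); F1 is defined as 0 when no positives are predicted and none
exist. A cumulative mode pooling years 1..y is available as a flag.
First-layer inspection exports the signed dense-layer weight matrix (inputs
× hidden units) whose magnitudes indicate which inputs drive the hidden
activities.

## Synthetic cohorts

The real provincial CHD records cannot be redistributed, so the generator
emulates their published summary structure. Per patient: sex is uniform;
one lesion type is drawn from the published HF-positive lesion mixture;
chronic CMs switch on at a uniformly drawn onset step with class-conditional
prevalence (HF-positive vs HF-negative patients use the respective published
columns, e.g. chronic kidney disease 30.4% vs 2.3%); acute CMs follow a
per-step hazard matched to the target patient-level prevalence (a
per-patient sampling mode is also provided); surgeries accrue at a small
per-step rate. A patient is HF-positive with probability
1 − (1 − hf_base_rate)^(T−1); positive patients draw their total HFH count
from the published mixture over {1, 2, 3, 4, ≥5} (the ≥5 tail is a
truncated geometric over 5–12, a bounded stand-in for the unspecified
tail), and event steps are placed without replacement with sampling weights
planted_effect^(# acute CMs at the previous step). With planted_effect ≤ 1
placement is uniform — the purely marginal, release-style simulation; the
default profile uses this mode with a per-step base rate calibrated so the
patient-level HF prevalence matches the published 9160/84113 ≈ 0.109.

A memoryless per-step logistic hazard cannot reproduce the published
heavy-tailed per-patient HFH count distribution, so the count mixture is
authoritative and the planted effect acts through placement weights; this
keeps the count distribution exact while making the planted effect an
odds-style multiplier on where events land.

The *planted-signal profile* used by the learnability tests fixes, once:
2000 patients × 40 steps, planted effect ×20, acute-CM hazard 0.08 per step
(accelerated relative to the published patient-level prevalences so the
temporal effect is identifiable at this scale), hf_base_rate 0.007 (≈24% of
patients HF-positive), and the published class-conditional chronic-CM
prevalences. A back-of-envelope Bayes calculation (class separation from
chronic CMs ≈ 0.95 pairwise, within-class acute-CM timing ≈ 0.8 pairwise,
≈ 3:1 mix of cross-class to within-class negative pairs) put the optimal
pooled AUROC near 0.9, leaving headroom above the 0.85 learnability bar.

What the generator does **not** emulate: the joint covariate distribution
of real patients, age-at-first-HFH statistics, informative censoring and
death, surgery–CM dependence, and any CM–CM correlation beyond the shared
HF-status conditioning. Passing tests therefore demonstrate that the
implementation recovers known planted structure — not clinical-grade
accuracy on real cohorts.

## Numerical and design notes

* The recurrent stack runs on an in-package reverse-mode autodiff tape over
  numpy, verified against finite differences; the models are small enough
  that this is fast at desk scale (a 2000-patient, 40-step, width-32
  training run of 30 epochs takes on the order of a minute).
* The cohort-comparison binomial test is exact (one-sided in the direction
  of the observed deviation by default, two-sided by flag). At the exact
  background rate 9160/84113 the severe-lesion depletion row reproduces the
  published p ≈ 0.017.
* Pre-norm placement of layer normalization (normalize, then GRU, then
  residual add) is used; post-norm is not implemented.
* The surgery variable is a cumulative count by default; a binary-per-step
  interpretation can be produced by thresholding the column externally.
* Checkpoints are single .npz archives holding the architecture spec, the
  feature-encoding contract (column order and normalization) and the named
  parameter arrays; the loader validates shapes.

## Known limitations

* No GPU or multi-threaded execution; determinism is guaranteed only for
  single-threaded runs on one platform.
* The Cox-type recurrent-event survival baseline is out of scope; so are
  irregular-interval gap weighting and integrated-gradients attribution.
* Frozen-age rollout means decade-long forecasts ignore aging unless the
  age-advance option is enabled.
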