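# Methods

## Problem and model

`deeppbs` monitors the mortality risk of very-low-birth-weight preterm
infants in the NICU in real time. The inputs are four continuously recorded
1-Hz vital signs — heart rate (HR, bpm), respiratory rate (RR,
breaths/min), peripheral oxygen saturation (SPO2, %), and mean blood
pressure from either an invasive arterial line (ART-M) or a non-invasive
cuff (NIBP-M), in mmHg — plus nine fixed clinical variables (sex,
gestational age, birth weight, prior length of NICU stay, and five
mutually exclusive race indicators).

Each infant's last 80 h of recording is reduced to S = 960 five-minute
steps. The supervision signal is per-step: for infants who died, every
step in the final 6 h before death is labeled *alert*, everything else
*not alert*; survivors are all *not alert*. The *turning point* is the
step at which an infant transitions from not-alert to alert; the terminal
padded step encodes "no transition".

The model is a detection–verification architecture with seven blocks:

1. **Linear projection**: `H_X = ReLU(X W_x + b_x)` for the signal matrix
   `X ∈ R^{S×n_v}` (n_v = 1500) and `h_g = ReLU(G W_g + b_g)` for the
   global vector `G ∈ R^9`, with `h_g` tiled over the S steps.
2. **Highway network**: `l_highway` gated-residual layers
   `g*t + (1−g)*H` with `g = σ(H W_g + b_g)`, `t = ReLU(H W_t + b_t)`.
3. **Embedding LSTM**: three stacked LSTM layers, each with a residual
   connection; the three layer outputs are mixed per step by a 3-way
   softmax over `Concat(outputs) W_l + b_l`.
4. **Gate**: a point-wise sigmoid gate over
   `Concat(L̄_X, H_g, L̄_X*H_g, L̄_X−H_g)` convexly fuses the signal
   embedding with the tiled clinical embedding.
5. **Modeling LSTM**: one residual LSTM layer producing the per-step risk
   state `M̄`.
6. **Detector**: `l_cnn` depthwise-separable convolution layers
   (kernel 7, length-preserving symmetric zero padding, batch
   normalization, ReLU) followed by a softmax over the S time positions:
   the turning-point distribution `TP`.
7. **Verifier**: two linear heads score every step under the
   "before-turning-point" and "after-turning-point" regimes
   (`P_b = M̄ W_nw + b_nw`, `P_a = M̄ W_w + b_w`); the raw prediction
   splices them at the selected turning point,
   `P = softmax(concat(P_b[:tp], P_a[tp:]))`, and the verified prediction
   subtracts/adds learned sequence transforms (single LSTM layers with
   input and state size 2) of the two logit sequences before the softmax.
   The step at `tp` itself belongs to the "after" part (0-based,
   half-open), consistent with `tp` being the first alert step.

**Turning-point selection (evaluation).** If `max(TP) > 0.5` that step is
chosen outright. Otherwise `k = Round(L/960)` top-probability candidates
are collected and the latest-in-time candidate is accepted iff its
probability exceeds `4/L`; otherwise "no turning point" (the terminal
padded step) is returned. We take `k = max(1, Round(L/960))`: the literal
rounding yields zero candidates for any sequence shorter than 480 steps,
which would disable the branch entirely on scaled runs. Ties are always
broken toward the latest step. During training the turning point is simply
`argmax(TP)`.

**Loss.** Three terms combined as
`L = β·L_detection + L_prediction + 2·L_verification`:

- `L_detection`: focal loss `w·α·(1−p)^γ·(−log p)` on `p = TP[true tp]`
  with γ = 2, α = 1, and w = 1.3 on the terminal padded step (the target
  for infants with no turning point) and 1 elsewhere;
- `L_prediction` and `L_verification`: weighted negative log-likelihood
  over unmasked steps of `P` and `P_verified` respectively. Not-alert
  steps weigh 1; alert steps weigh
  `(n_not_alert / n_alert) × 0.1153`, recomputed per training fold. We
  normalize by total weight (weighted mean, not sum) so the loss scale is
  independent of sequence length. Probabilities are clamped at 1e-12
  before logs.

## Training regimen

Adadelta (learning rate 0.5, ρ = 0.9, ε = 1e-6) with classic L2 weight
decay λ = 3e-7, batch size 6, 60 epochs at full scale; gradients are
clipped to global L2 norm 5.0; an exponential moving average of all
trainable parameters (decay μ = 0.999, convex form
`E ← μE + (1−μ)W`) is what gets evaluated. Every epoch the training set is
rebuilt as all dying infants plus `round(n/6)` randomly drawn survivors
(n = number of dying infants). The held-out fold is evaluated every 50
steps (and once at the end of training) with the EMA weights, and the
checkpoint with the best accuracy×recall is kept. Fourfold
cross-validation is stratified by outcome so every fold contains both
classes; all randomness (fold split, per-fold initialization, resampling,
dropout) flows from one root seed through named substreams.

Two implementation choices not dictated by the architecture:

- **Feature standardization.** Signal features and global variables are
  z-scored per training fold (statistics from unmasked steps only; padded
  rows stay exactly zero; validation folds reuse the training fold's
  statistics). Raw vital-sign magnitudes (tens to low hundreds) otherwise
  saturate the sigmoid/tanh nonlinearities and prevent training.
- **Numerical backend.** The model and both training loops run on a small
  reverse-mode automatic-differentiation engine over NumPy
  (`deeppbs._tensor`) with a fused LSTM primitive whose
  backward-through-time pass is hand-written; every primitive is verified
  against central finite differences in the test suite.

## Preprocessing

Valid ranges (values outside become missing): HR (0, 250], RR (0, 120],
SPO2 (0, 100], ART-M [10, 90], NIBP-M (10, 90]. Endpoint openness is
honored exactly. Recordings longer than 80 h keep their last 80 h;
shorter ones (but ≥ 6 h; shorter are excluded) are zero-padded at the
front, and padded segments are masked out of the prediction losses and
metrics. Imputation runs before rolling and segmentation, on the
per-second signal table of each infant, so pad zeros never leak into
rolling means. The absent blood-pressure channel (each infant has exactly
one of ART-M / NIBP-M) is zero-filled, not imputed — it carries no
information for that infant.

The causal 5-min rolling mean is emitted per second (`rolled[t] =
mean(x[t−300:t])`); the first 5 min initialize it, so an 80-h recording
yields 959 consecutive non-overlapping 5-min segments of
5 signals × 300 rolled values = 1500 features, plus one appended all-zero
terminal segment (final length 960). Segment k's label is decided by its
end time: alert iff the infant died and the end time lies in
`(death − 6 h, death]`. All indices are 0-based with half-open intervals.

## Imputation

Six techniques: mean / median / mode of each signal's observed values
within one infant's window (mode is taken over integer-rounded values,
since the mode of continuous data is ill-defined; ties go to the smallest
value); decision-tree and Bayesian-ridge single imputation via chained
equations (each signal regressed on the other concurrent signals,
scikit-learn `IterativeImputer`, max 10 iterations, tolerance 1e-3); and
multiple imputation drawing five completed datasets from the
Bayesian-ridge posterior with independent seeds. Observed entries are
never modified. Downstream comparison runs fourfold cross-validation per
technique and averages fold metrics, additionally averaging over the five
datasets for multiple imputation.

## Synthetic cohorts

The generator emulates the statistical structure the monitor assumes, not
neonatal physiology. Per infant: gestational age ~ N(26.7, 2.3) weeks
(clipped to [22, 32), dying infants shifted ~1.5 weeks lower), birth
weight linearly tied to GA around 929 ± 281 g, 51% male, five race
categories, one randomly assigned blood-pressure source, and a CRIB-II
score that is higher for dying and more premature infants. Signals are
Gaussian noise around GA-adjusted baselines (HR 155 ± 10 bpm, RR 50 ± 8,
SPO2 93 ± 3 %, mean BP ≈ 27 ± 5 mmHg with a +1 mmHg/week GA slope —
mean arterial pressure close to GA in weeks is the usual preterm rule of
thumb). Values are clipped inside the valid ranges so that, with
artifacts and missingness disabled, every clean sample is in-range.

Dying infants deteriorate along a linear ramp starting
`onset_hours = 6 h` before death (death coincides with the recording
end): HR −25, RR +15, SPO2 −12, mean BP −10 by the time of death, with
noise SD inflated ×2 after onset. The onset time is the ground-truth
turning point. Artifacts replace a configurable fraction of samples
(default 1%) with out-of-range spikes (dropouts to 0 or implausible
highs); missingness is missing-completely-at-random per sample (default
5%). Timestamps are elapsed seconds; everything is a pure function of the
spec and its seed.

What the generator does **not** emulate: autocorrelated physiologic
dynamics (bradycardia/desaturation spells), non-random missingness,
sensor drift, inter-signal causal structure, or any specific pathology.
Passing tests therefore demonstrate that the pipeline and model recover
the structure they assume — not clinical performance on real NICU data,
whose headline numbers require the original private cohort.

## Scaled study conditions

The turning-point-recovery experiment runs at desk scale, chosen once:
40 infants per replicate cohort, half of whom die (a balanced design
keeps ≥ 6 dying infants in every training fold, which epoch resampling
requires), 8-h recordings → S = 96 steps, hidden size 8, 100 epochs with
evaluation every 25 steps, and EMA decay 0.9 (at a few hundred steps a
0.999 shadow would still sit at the initial weights). Three replicate
cohorts/seeds are pooled. Success criteria: ≥ 70% of dying validation
infants localized within ±6 segments (30 min) of the true onset, and
per-step alert recall above the 95th percentile of a label-shuffled null
at the same 0.5 threshold.

## Numerical and degenerate-case choices

- Parameter initialization: uniform with 1/√fan-in bounds, seeded.
- Batch normalization: batch statistics in training, running averages
  (momentum 0.1) in evaluation.
- Softmax is computed with a detached max-shift (exactly
  gradient-equivalent, numerically stable).
- `p = 0` inside a log is clamped to 1e-12 with a warning.
- An all-masked sequence, a fully missing feature, an empty turning-point
  distribution, death before the evaluation window, and out-of-range
  turning points all raise informative errors rather than propagating
  NaNs.
- The EMA recurrence is the standard convex form `E ← μE + (1−μ)W`; the
  transposed variant `E ← (1−μ)E + W` diverges for μ = 0.999 and is not
  used.
- Weighted NLL uses a weighted mean; a weighted sum would tie the loss
  scale to sequence length.

## Known limitations

- Real-cohort results (accuracy 0.888 / recall 0.780 / AUC 0.897 at full
  scale) cannot be reproduced here: the 285-infant clinical dataset is
  private. Synthetic-cohort metrics characterize the implementation, not
  the clinical method.
- CRIB-II scores are consumed as given integers; computing the score from
  its raw clinical components is out of scope.
- The chained-equation imputers see only the concurrent signals of one
  infant, not global variables.
- Full-scale training (S = 960, n_h = 64, 60 epochs) runs on the NumPy
  backend but is slow on a single CPU; the configuration validates and
  executes, and all quantitative claims in this repository are made at
  the scaled conditions above.
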