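# Methods

`nirscnn` implements a channel-wise classification approach to region-of-
interest (ROI) selection for functional near-infrared spectroscopy
(fNIRS) group studies.  The idea: if a classifier trained on a single
channel's oxy-hemoglobin (oxy-Hb) time series can tell two subject groups
apart, that channel's cortical site carries a group difference.  Training
one small convolutional network per channel and ranking channels by their
leave-one-out cross-validated (LOOCV) identification rate turns ROI
selection — normally a subjective choice — into a measurable, repeatable
procedure, while keeping the temporal information that summary statistics
discard.

## The classifier

Each channel's input is a 1×N feature vector (N = 200 by default, one
value per second over a 200 s analysis window).  The network is the
minimal convolutional architecture:

1. **Convolution** — K = 9 learnable kernels of length m = 10, stride 1,
   no padding ("valid"), giving K feature maps of length N − m + 1:
   `u_k[i] = Σ_a x[i+a] · w_k[a]`.
2. **Activation** — elementwise logistic sigmoid (default) or rectifier.
3. **Max pooling** — width 2, stride 2 (non-overlapping), halving each
   map; the maximum of each block is kept and gradients route to the
   block's argmax (first position on ties).
4. **Fully connected softmax output** — two neurons, one per group; the
   outputs are the class probabilities.  Flattening is kernel-major, so
   the dense weights feeding a given kernel's pooled units are a
   contiguous slice (useful for interpretation).

Training minimizes softmax cross-entropy (one-hot MSE selectable) with
full-batch gradient descent and classical momentum

    v ← momentum·v − lr·∇L;  w ← w + v

at learning rate 0.05 and momentum 0.998 for 5000 epochs — the
configuration this method is defined with.  Per-sample updates
are selectable.  Initialization is uniform, fan-in scaled
(±1/√fan-in), seed-controlled; biases start at zero.

### The momentum-0.998 regime, collapse, and restarts

Momentum 0.998 with lr 0.05 is an extreme heavy-ball setting: the
steady-state displacement per unit gradient is lr/(1−momentum) = 25, and
the velocity's decay time constant is ~500 epochs.  The transient is
violent — weights routinely swing to magnitudes of 10–20 before settling.
Two consequences, both verified against finite-difference-checked
gradients (so they are properties of the dynamics, not bugs):

* With a **rectifier** activation the swing regularly drives *every*
  convolution pre-activation negative at once.  The gradient then
  vanishes identically and permanently; only the output bias keeps
  learning, so the network degenerates to a class-prior classifier.
  Under LOOCV the training fold's majority class is always the class the
  held-out subject does *not* belong to, so a prior classifier scores
  systematically *below* chance (≈0.1–0.2).  This absorbing state is why
  the logistic sigmoid is the default activation here.
* With the **sigmoid**, saturation of all units is still an absorbing
  state (all pooled outputs ≈ constant), and some random initializations
  coast into it — or are simply still oscillating when the epoch budget
  ends.  Whether a given run interpolates its 21 training subjects or
  stalls is effectively chaotic in the seed.

`train()` therefore applies the standard remedy for chaotic non-convex
fits: **random restarts**.  A run whose final training loss never beat
the trivial level of predicting the class frequencies (cross-entropy
> 0.55; MSE > 0.35) is discarded and retried from a fresh initialization
whose seed is derived deterministically from the base seed, up to
`max_restarts` (default 10) times; the last attempt is returned
regardless, and the loss is evaluated on the weights actually returned
(the final momentum step can jump far from the last mid-training
measurement).  Partially-fit networks are deliberately *not* accepted:
they carry the majority-class lean described above and would bias LOOCV
accuracies downward.  Everything remains exactly reproducible: restart
seeds are pure functions of the base seed.

### Reduced-epoch profile

`CNNConfig.fast()` (200 epochs) is the profile used by the test suite,
the acceptance script and the examples; the full 5000-epoch default is
the faithful setting for real use.  In this regime 200 epochs is not a
proportionally weaker fit: when a run converges at all it usually
interpolates well before epoch 200, so the profile mainly trades restart
probability for time.

### Fold-batched LOOCV training

`loocv_channel` trains all n leave-one-out models of a channel
simultaneously: parameters carry a leading fold axis, the held-out
sample of each fold gets weight 0 in that fold's gradient, and every
step is a batched matrix product in single precision, with the width-2
pooling forward pass fused (numba).  Because the activation is monotone,
pooling is applied to the pre-activations and the activation only to the
block winners.  Fold dynamics are fully independent and match the
reference per-fold float64 `train()` to ~1e-4 in the weights; the
per-fold path remains the reference implementation that the oracle and
gradient tests exercise, and is used automatically for configurations
the batched path does not cover (per-sample updates, overlapping
pooling).

## LOOCV, ranking and ROI selection

Every subject serves once as the held-out test case; the model is
re-initialized each fold with a seed derived from (base seed, channel,
fold), so any fold can be reproduced alone.  A channel's identification
rate is the mean 0/1 correctness over folds.  Channels are ranked by
identification rate (ties broken by channel order), and the ROI is
either the top-k channels (default k = 5; ties at the boundary are all
included) or all channels above an accuracy threshold.  Min–max
normalization is per subject and per channel, so no preprocessing
statistic can leak between training and test folds.

Predicted probabilities are retained per fold but unused in ranking.  A
probability tie predicts class 0 (documented tie-break).

## Preprocessing

Fixed order: zero-phase Butterworth low-pass (1.0 Hz cutoff, order 4,
applied forward–backward so response peaks are not shifted) → centered
10 s moving average with shrinking edge windows → non-overlapping 1 s
window means starting at the analysis-window start (a 10 Hz → 1 Hz
reduction) → per-channel min–max to [0, 1].  A constant window maps to
all 0.5 with a warning rather than an error, so noise-free null
simulations pass through.  The chain is invariant to affine rescaling of
the raw signal, which is the appropriate property for fNIRS: optical
path-length differences make absolute amplitudes incomparable across
subjects and sites.

Which 200 s of the 390 s session to analyze is exposed
(`start_s`/`duration_s`, default: 200 s from task onset).  Note that the
default group-effect window of the simulator occupies the latter half of
the task period (195–360 s), so an analysis window targeting the effect
should start later (the examples and the recovery protocol use
`start_s=160`).

## The synthetic cohort generator

No public fNIRS recordings accompany the method, so the generator
provides ground-truth cohorts:

* **Task drive** — a block design (30 s rest; 30 trials of 3 s memorize
  / 1 s retain / 7 s respond; 30 s rest; 390 s at 10 Hz) with
  phase-dependent neural amplitude (1.0 / 0.6 / 0.8), convolved with a
  double-gamma hemodynamic response (peak 6 s, undershoot 16 s, ratio
  1/6, peak-normalized; area-normalized before convolution so a
  sustained drive plateaus at the task amplitude, default 1.0).
* **Group effect** — on the discriminative channels (default {5, 20})
  the task response carries ±effect_amplitude/2 (group 0 positive),
  ramping linearly over `effect_window` (default the latter half of the
  task period), so the designed group-0 − group-1 difference equals
  `group_effect_template(config)` exactly.  Default amplitude 0.6.
* **Confounds** — additive white noise (sd 0.2), a slow sinusoidal
  drift (amplitude 0.3, period 300 s) and sinusoidal cardiac (1.1 Hz),
  respiratory (0.3 Hz) and Mayer-wave (0.1 Hz) components (amplitudes
  0.10/0.10/0.15), each with per-subject, per-channel random phase.
  Amplitudes are relative to the unit task response.  The 1.0 Hz
  low-pass removes the cardiac component; the 10 s moving average
  exactly nulls the 0.1 Hz Mayer waves (a uniform window of width T has
  spectral zeros at multiples of 1/T).

Inter-subject variability comes entirely from the noise draws (no
per-subject gain), so with noise off the group difference equals the
designed template sample-for-sample — the property the recovery tests
rely on.  Per-subject seeds derive from the cohort seed; identical
configurations give bit-identical cohorts.

What the generator does **not** emulate: motion artifacts, superficial
(scalp) hemodynamics, spatially correlated noise across channels,
inter-subject anatomical variability, or any optical forward model.
Passing tests on this data therefore demonstrate the *procedure* —
calibration under the null and recovery of planted effects — not
performance on real recordings.

## Canonical studies (`nirscnn.study`)

* **Null calibration** — zero-effect cohorts at the standard geometry
  (22 subjects × 24 channels, 200-epoch profile).  Mean identification
  rate across cohorts sits within 0.45–0.55 and no channel deviates
  beyond a few binomial standard errors: the ranking is unbiased when
  there is nothing to find.
* **Planted recovery** — one *noise-free* cohort with effect amplitude
  4.0 on channels {5, 20}, analysis window 160–360 s.  With no noise,
  all subjects of a group share the identical feature vector, so a fold
  that interpolates its training set is guaranteed to classify the
  held-out duplicate correctly: planted-channel LOOCV accuracy 1.0 is a
  structural consequence of fitting, not a statistical outcome, and the
  protocol raises the restart budget (25) so interpolation is ensured.
  Channels without the effect become exactly constant after min–max
  (the degenerate-0.5 path); restarts are skipped for them — identical
  training inputs make every initialization equivalent — and their
  bias-only classifiers score at or below chance, well clear of the
  planted channels.  Top-2 selection returns exactly {CH5, CH20}.
  Noisy regimes were deliberately not used for this check: under the
  chaotic optimizer an interpolating model's decision boundary is
  untamed away from the training points, and even at effect-to-noise
  ratios of ~100 an atypical held-out subject is occasionally
  misclassified with high confidence.  That behavior is worth knowing
  about when reading real-data identification rates.

Problem sizes here (cohort counts, the 200-epoch profile) are the
package's standard quick-evaluation settings; `scripts/acceptance.py`
recomputes both studies from scratch.

## Interpretation outputs

From a trained model and a dataset: the learned kernels (K × m), the
class-mean pooled activations per kernel (K × 2 × P), the pooled
activations multiplied elementwise by the dense weights feeding a chosen
output neuron, and the class-mean inputs.  "Which kernel discriminates
most" is made reproducible by a separation score: the sum over pooled
positions of |class-mean difference| of the weighted pooled output
(symmetric under label swap; ties to the lowest kernel index).  The
score definition is this package's own formalization of what is
otherwise a judgment by eye.

## Numerical choices and degenerate inputs

* Valid convolution means a 200-sample input yields a 191-length map and
  a 95-length pooled vector; the often-quoted "200 → 100" halving
  describes the pooling operator alone.
* Overflow-safe softmax (max-shift); cross-entropy log clamped at 1e-300.
* Rectifier derivative at exactly 0 is 0; pooling ties route gradients
  to the first position.
* min = max feature windows normalize to 0.5 + warning; probability ties
  predict class 0; `learning_rate=0` returns the untouched
  initialization (and disables restart logic, which could otherwise
  never succeed).
* Model serialization is a single JSON document (config + base64-encoded
  little-endian float64 weights): text-only and bit-exact on round trip.

## Known limitations

* The optimizer regime is inherited, not chosen: with momentum 0.998 the
  fit is a race between interpolation and saturation, and the restart
  mechanism papers over — but cannot change — the chaotic dependence on
  initialization.  Anyone using this package on real data should also
  try conventional settings (e.g. momentum 0.9, more epochs).
* Identification rates from 22 subjects have wide binomial bands
  (±0.21 at 95% around chance); single-channel accuracies should not be
  over-read, which is why the studies aggregate over cohorts.
* No statistical test accompanies the ranking (none exists in the
  original procedure); a permutation-based chance-level estimate would
  be the natural extension.
* The simulator's confound model is deliberately minimal (see above).
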