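# Methods

## Pipeline overview

The package authenticates a person from two simultaneously usable signals:
event-related potentials (ERPs) evoked by a self-/non-self-face RSVP
stream, and eye-blink waveforms from the frontal Fp1 electrode. Per user, a
system is trained from the user's session plus sessions of enrolled
imposters watching the *same* stimulus stream; at login a fused score
decides accept/reject. The stages, in order: filtering and epoching →
electrode/time-point selection → sparse ERP feature maps → blink
segmentation and morphology features → class balancing (SMOTE) → CNN and
NN match scorers → least-squares power-series score fusion → ACC/FAR/FRR
evaluation.

## Preprocessing

* EEG low-pass: Chebyshev type I, 40 Hz passband edge, 49 Hz stopband
  edge, 0.5 dB passband ripple, 40 dB stopband attenuation. The filter
  order is the minimum meeting the template, bumped to odd so a ripple
  peak (unit gain) sits at DC. Applied forward–backward (`sosfiltfilt`)
  for zero phase: the discriminability statistic is latency-sensitive, so
  filter delay must not shift component latencies. The effective ripple
  and attenuation are therefore doubled (1 dB / 80 dB).
* Blink band-pass: same design, 1–40 Hz passband (0.25 / 49 Hz stop
  edges). Blink energy concentrates below ~15 Hz; the wider 40 Hz upper
  edge is retained as the canonical setting and is configurable. Both
  filters require the stop edge below Nyquist, i.e. a sampling rate above
  98 Hz.
* Downsampling 2400 → 600 Hz averages four consecutive samples (an
  anti-alias boxcar plus decimation in one step); a trailing remainder is
  dropped and logged.
* Epochs span −200..1000 ms around stimulus onset (720 samples at
  600 Hz); the −200..0 ms mean is subtracted per trial and channel.
  Baseline correction is idempotent.
* Blink segmentation: positive peaks above +100 μV followed by a negative
  peak below −50 μV. Boundaries are found by scanning from each peak to
  the first sample of opposite (or zero) sign — integer indices, no
  interpolation, so duration features stay integral in samples. Several
  supra-threshold positive peaks before one negative peak collapse to the
  largest (earliest on ties). All segmented blinks of a session are
  normalized by the single largest absolute peak across the session, so
  the global maximum is exactly 1 and relative amplitudes across blinks
  are preserved.

## Discriminability map and selection

P_i(n) = √(N₁N₂)/(N₁+N₂) · (M_i^SF(n) − M_i^NSF(n))/S(n), with S(n) the
population SD over all trials of both classes. With this prefactor the
statistic *is* the Pearson correlation between single-trial voltage and a
0/1 class indicator, which the test suite exploits as an independent
oracle. Points with S(n)=0 get P=0 with a logged warning.

Point ranking uses |P| (the sign of the self/non-self difference is
subject-specific; magnitude carries the discriminability); channel ranking
uses the mean of P² over each channel's 200 selected points. Ties break
toward the lower index at both levels. Selected indices need not be
contiguous in time: windows are formed over the sorted selected indices
(20 consecutive blocks of 10), not over raw time, because rank selection
cannot guarantee contiguity.

The sparse 20×20 expansion places compact row c at expanded row 4c
(rows 0, 4, 8, 12, 16). The layout is a named, fixed strategy —
classification is layout-sensitive, so it is part of the model contract.

Feature maps are built from self-face-onset epochs only, with adjacent
trials averaged pairwise (200 single trials → 100 averaged trials at full
scale) to raise single-trial SNR. Imposter samples are the imposter's
epochs at the same self-face onsets of the user's stimulus stream, through
the user's stored selection mask — at login time the mask is part of the
frozen model.

## Blink morphology features

Twenty features per normalized blink (energy: Ap, An, Ep, En; position:
Pp, Pn, Dp, Dn; slope: S1–S6; derivative: D1–D6). Decisions where the
definitions are under-specified:

* Positions and durations are in **seconds** from the blink start, making
  features sampling-rate independent.
* Slopes are amplitude per second (tan θ on an amplitude-vs-seconds
  plot), signed: S2/S4 carry the negative pulse's sign.
* Dispersions are population σ over the pulse samples divided by the mean
  of signed samples (positive pulse) or of absolute samples (negative
  pulse — avoids near-zero-mean blowups).
* En is reported as an area magnitude (positive); polarity lives in An.
* Derivatives are first differences scaled by the rate; a zero crossing
  is a strict sign change, with zero samples inheriting the preceding
  sign.

On the generator's piecewise raised-cosine template these have closed
forms (e.g. Ep = pos_amp·(rise+fall)/2 after normalization), which the
acceptance tests check to within one sample period.

## Scorers

No deep-learning framework is used; both networks are small enough that a
direct numpy implementation is the simplest dependable choice, and it
keeps training bit-reproducible from a seed.

* CNN for 20×20 ERP maps: conv 6 maps @5×5 (valid) → maxpool 2 → conv 12
  maps @3×3 → maxpool 2 → flatten (derived size 108) → fully connected
  2-unit output. Sigmoid activations everywhere, mean-squared-error loss,
  plain SGD with learning rate 1, batch size 100, 500 epochs — the
  classic sigmoid/MSE ConvNet recipe those hyperparameters come from.
  Pooling ties share gradient equally.
* NN for 20-dim blink vectors: 20-5-5-5-2, sigmoid, full-batch gradient
  descent, learning rate 0.1, 2000 epochs.
* Inputs are standardized with statistics frozen from the training set
  (scalar mean/SD for maps, per-feature for blink vectors); sigmoid/MSE
  training is not scale-invariant, and the blink features span orders of
  magnitude.
* Weight init is uniform Glorot from the spec seed; batch shuffling uses
  the same generator, so identical data + spec ⇒ identical scores.
* The match score is the user-class output unit (in [0,1]); no softmax
  across the two outputs.

SMOTE balances the user class: each synthetic sample lies on the segment
from an original to one of its K = 5 nearest neighbours (Euclidean),
x_new = x + u·(x̃ − x), u ~ U(0,1). The historically printed variant with
the segment direction reversed (an *extrapolation*, x − x̃) is available
as `as_printed=True` for reproduction, but interpolation is the default —
the tests verify interpolants stay inside the minority convex hull and
the printed variant escapes it.

## Fusion

The design matrix row for a score vector is [1, s₁, …, s_N, …, s₁^M, …,
s_N^M] (modality-major within each power); λ is fitted by
`numpy.linalg.lstsq` — numerically stabler than forming (gᵀg)⁻¹gᵀy and
identical to it whenever gᵀg is nonsingular (asserted to 1e−8 in tests),
with the minimum-norm pseudo-inverse behaviour on rank-deficient designs.
M defaults to 2, the smallest order where fusion is nonlinear in the
scores; N = 2 modalities. The decision threshold defaults to 0.5 (targets
are 0/1); a tie at the threshold accepts. One authentication attempt pairs
the i-th (seeded-shuffled) EEG score with the i-th blink score; the
surplus of the longer list is dropped.

## Evaluation protocols

Closed set, per user: select channels/times from the user's self/non-self
contrast, build user and imposter maps and blink vectors, split
train/test, train scorers, fit fusion on training scores, evaluate held
out. Open set: fresh imposter profiles drawn from the same subject
distribution are scored against the frozen models; only FAR is
meaningful. Permanence: the user's profile is perturbed (multiplicative
amplitude jitter exp N(0, 0.1), additive latency jitter N(0, 10 ms) by
default) to emulate a repeat session ~30 days later; only FRR is
meaningful. The exact count identity
ACC·(n_user+n_imposter) = (1−FAR)·n_imposter + (1−FRR)·n_user holds on
every run. ROC curves sweep the decision threshold over all unique
scores; accept iff score ≥ threshold.

Three evaluation-hygiene choices deviate from the most literal reading of
the classical protocol and are deliberate:

1. **Split before SMOTE.** Originals are split per class first and only
   the training minority is oversampled. Scoring synthetic interpolations
   of training samples inflates accuracy — measured on a null cohort
   (identical templates for every subject) the literal
   oversample-then-split order yields ~78% "accuracy" where chance is
   50%. With 100 user originals, 15 imposters and a 10% split the
   canonical arithmetic is preserved exactly: 90·15 = 1350 training and
   150 held-out samples.
2. **Selection excludes held-out trials.** The discriminability map is
   part of the trained system; computing it on epochs that later appear
   in the test set lets selection memorize their noise (measured: pushes
   the null cohort far from chance in either direction).
3. **Balanced held-out sets.** User and imposter attempt counts are
   trimmed to equal size so ACC is interpretable against the 50% chance
   level; otherwise any scorer bias moves null-cohort ACC away from 0.5
   even with zero discrimination.

All protocol randomness flows from a master seed through a counter scheme
(`derive_seed`, a SeedSequence over (master, stage, user, item) tuples,
yielding values below 2³¹).

## Synthetic data: what it does and does not emulate

Per subject the generator draws: ERP latency U(200, 350) ms, width (FWHM)
U(40, 80) ms, self-response peak magnitude U(5, 9) μV and non-self
magnitude U(1, 3) μV on smooth random topographies concentrated over
parieto-occipital electrodes (negative polarity, N250-like); blink
positive amplitude U(150, 300) μV, undershoot U(−120, −60) μV, rise/fall
U(60, 110) ms, undershoot duration U(100, 170) ms. No authoritative
quantification of across-subject ERP variability exists for this
paradigm; these ranges are package choices, documented here and fixed.

The ERP template is a Gaussian-windowed deflection truncated to the
post-stimulus second — smooth, with latency/width directly controllable,
and exactly reproduced by zero-noise epochs (an oracle the tests use).
The blink template is piecewise raised-cosine (rise/fall/undershoot), so
areas, peak positions and slopes have closed forms. Background noise is
1/f ("pink") by default — EEG-like — with a white option. An imposter
watching a user's stream responds to every image with their own non-self
template.

Emulated: subject-specific latency/amplitude/topography, self/non-self
contrast, the 1:9 stimulus ratio and 300 ms SOA (epochs of neighbouring
stimuli overlap, as in real RSVP), supra-threshold biphasic blinks with
subject-specific shape, session-long 1/f background.

Not emulated: trial-to-trial ERP latency jitter and habituation, eye
movements and non-blink artifacts, electrode impedance drift, inter-trial
dependence of blink shape, fatigue/attention effects. Passing tests
therefore show the *pipeline* recovers identities under its stated
assumptions — not that real recordings would reach the same numbers; the
reference full-scale human-subject accuracies are not reproducible at
desk scale because those recordings are not deposited.

Known limitation worth flagging: the pink-noise option deliberately
violates within-session exchangeability (slow 1/f drifts act as a session
signature and interact with 200-point selection at small trial counts).
The chance-level null check therefore uses the white-noise option, whose
trials are exchangeable across subjects and sessions; the pink default
remains the realistic condition for the strong-effect protocols.

## Problem sizes

`CohortSpec()` carries the full acquisition sizes (15 users, 15 enrolled
+ 10 unseen imposters per user, 2000 stimuli → 100 averaged trials, 100
blinks, SMOTE to 1500, 50 permanence logins, CNN 500 epochs).
`CohortSpec.small()` is the package's scaled-down study condition used by
the test suite and the acceptance script: 5 users, 2 enrolled + 2 unseen
imposters per user, 300 stimuli (30 self-face epochs → 15 averaged
trials), 12 blinks, 600 Hz acquisition, 2 μV pink noise, CNN 150 / NN 600
epochs, 10 permanence logins — about 7 s per cohort on one CPU, with the
structural arithmetic (108, 1350/150, 1500, …) still checked at the full
sizes where it is cheap to do so.
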