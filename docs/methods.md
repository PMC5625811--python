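# Methods

`emofuse` implements a two-channel emotion recognizer — an EEG channel and
a facial-expression channel — combined at the decision level, plus a
synthetic trial generator and an evaluation harness that mirrors a
twenty-subject, forty-trial-per-subject experimental protocol. This note
records the model, the parameter choices, the numerical conventions, and
what the synthetic data does and does not establish.

## Labels

Four emotion states (regions of valence–arousal space) with codes
1 = happiness, 2 = neutral, 3 = sadness, 4 = fear, and three emotion
intensity levels with codes −1 = weak, 0 = moderate, +1 = strong. Score
vectors are always ordered (happiness, neutral, sadness, fear) and
(weak, moderate, strong). Every argmax in the package breaks ties toward
the lowest index; this single convention makes all decisions deterministic.

## EEG channel

**Features.** A single-channel segment is cut into consecutive,
non-overlapping 1-s windows (trailing partial window discarded). Each
window is Hann-tapered and Fourier-transformed; the one-sided power
spectrum at 1 Hz bin spacing is averaged over the bins of eight bands —
delta 1–3, theta 4–7, alpha1 8–10, alpha2 11–13, beta1 14–20, beta2 21–30,
gamma1 31–40, gamma2 41–50 Hz (band edges inclusive; at 1 Hz resolution
the bands do not overlap) — and then over windows, giving one 8-vector
x = (DELTA, THETA, ALPHA1, ALPHA2, BETA1, BETA2, GAMMA1, GAMMA2).

Conventions worth stating:

* Band powers are integrated directly from the windowed spectra; no
  time-domain filter bank is applied first (a zero-phase 4th-order
  Butterworth band-pass is available separately for visualization). The
  two operations are redundant for this feature set, and spectral
  integration is exactly testable against a direct DFT oracle.
* Spectra use "spectrum" scaling — power divided by the squared window
  sum — so a unit sinusoid contributes the same band power at any sampling
  rate, and scaling the signal by c scales every feature by c².
* Bins are *averaged* within a band (not summed), so wide and narrow bands
  are comparable; linear power, not log.
* With a Hann taper, a tone on an exact bin spreads over exactly three
  bins with power fractions 1/6, 2/3, 1/6. Band features inherit this main
  lobe: a 10 Hz tone leaves 1/6 of its power in the 11 Hz bin just outside
  alpha1. Tests assert the exact 5/6 / 1/6 split rather than pretending the
  band capture is total.
* Sampling rate is configurable with a 512 Hz default (a typical consumer
  single-electrode headset rate); the minimum accepted is 128 Hz so the
  gamma2 band stays below Nyquist.

**Classifiers.** Two one-vs-rest linear SVMs on the same 8 features: a
four-class state classifier and a three-class intensity classifier. The
per-class decision values w·x + b are the channel's raw scores s2 (states)
and s2′ (intensities); the state scores are min–max normalized downstream,
the intensity decision is a plain argmax. Features are z-scored with
training-set statistics; the scaler is part of the serialized model.
The regularization weight defaults to C = 1. The fit uses a deterministic
primal solver, so refits are bit-identical and independent of sample
order. Each subject gets an independently fitted pair of classifiers with
shared hyperparameters.

## Face channel

**Preprocessing.** Frames are converted to grayscale (Rec. 601 luma),
optionally cropped by a pluggable face detector (any callable returning a
bounding box; a brightest-blob stub ships for synthetic frames — training
a real face-detection cascade is out of scope), resized bilinearly to
48 × 48 and scaled to [0, 1].

**PCA.** The top-D principal components of the flattened training images,
computed by SVD of the centered data matrix. Components are orthonormal
and sign-fixed (largest-magnitude coordinate positive), so fits are
deterministic. D > rank raises rather than returning zero-variance
directions.

**Network.** D inputs → one hidden layer of N logistic units → 4 logistic
outputs. Training is per-sample stochastic gradient descent on the squared
error 0.5‖o − t‖² against one-hot targets, samples visited in a seeded
shuffled order each epoch, weights initialized from U(−0.05, 0.05).
Squared-error loss, the init range and the epoch count (default 200 at
full scale; smaller in the bundled experiments, see below) are this
package's choices; the architecture, sigmoid activations and learning rate
follow the method being implemented. The raw output activations are the
face scores s1; the decision r1 is the argmax of their min–max normalized
version.

**Grid search.** Exhaustive search over
D ∈ {121, 144, 169, 225} × N ∈ {150, 200, 250, 300} ×
R ∈ {0.001, 0.01, 0.1, 1} (64 combinations), maximizing validation
accuracy; ties break toward smaller (D, N, R). PCA is fitted once per D
and shared across the (N, R) cells. When the search is skipped the default
is (D, N, R) = (169, 200, 0.1). The validation set is the caller's; the
CLI uses a seeded stratified 80/20 split of the training images.

## Fusion

**Normalization.** ŝ = (s − min s)/(max s − min s). When all scores are
equal the formula divides by zero; the package defines the output as all
zeros, which makes a non-informative channel the neutral element of the
sum rule (the fused decision then falls back to the other channel).

**Sum rule.** sumⱼ = ŝ1ⱼ + ŝ2ⱼ, decision argmaxⱼ sumⱼ.

**Production rules.** Twelve IF–THEN rules mapping (face state r1, EEG
intensity r2′) to a final state. The table is data, not code: it ships as
a packaged CSV, is validated for totality (every one of the 4 × 3
antecedents exactly once), and users may substitute their own. The default
table's structure: *strong* shifts the face decision one step toward the
intense neighbour on the mildness axis neutral–happiness / sadness–fear
(neutral→happiness, sadness→fear), *weak* one step toward the milder
neighbour (happiness→neutral, fear→sadness), *moderate* is the identity.

## Synthetic data

The generator reproduces the *information structure* the method assumes,
not the physiology or the optics:

* EEG: eight band-center sinusoids whose amplitudes follow a
  state-specific template — each state boosts one signature band
  (happiness → alpha1, neutral → theta, sadness → beta2, fear → gamma2) —
  with the boost scaled by intensity (0.5× / 1.0× / 1.5× the moderate
  contrast) plus 1/f background noise (default SD 0.3 against a 0.2
  baseline / 1.4 peak oscillator amplitude). Intensity affects only the
  EEG, faces depend on state only, matching which channel is assumed to
  carry which label.
* Faces: a parametric 48 × 48 face whose mouth encodes the state
  (upturned / flat / downturned / open oval), pixel noise SD 0.05.
* Trials: states balanced within a subject; intensity drawn per trial
  (uniform by default). Per channel and per trial, the observed label may
  be corrupted: the face channel confuses happiness↔neutral with
  probability 0.5 on those trials; the EEG channel swaps the state for a
  uniformly random other state with probability 0.45 and the intensity
  with probability 0.10. A corrupted channel renders the wrong label into
  70% of its images/windows, so its trial-averaged score vector tilts
  wrong but keeps graded mass on the truth — the regime where score-level
  fusion of channels that err on *different* trials recovers most
  single-channel errors. All randomness flows from one seed via
  `SeedSequence((seed, subject, trial, stream))`.

`complementary_config()` bundles the shipped experiment conditions. It
replaces the uniform intensity draw with a state-conditional distribution
concentrated away from the four rule-remapped (state, intensity) pairs
(e.g. happiness is rarely weak). This is deliberate: under a uniform
intensity draw the production rules remap a third of the truth pairs and
rule fusion *cannot* beat the face channel even with perfect inputs; the
aligned distribution encodes the same reading of the rules that motivates
them — a weak happiness genuinely is closer to neutral. The corruption
rates above were chosen so the single channels land near the mid-70s
(face) and mid-60s (EEG) accuracy regimes that motivated the fusion
design; under them (20 subjects, seed 7) the run prints face 79.6%,
EEG 65.5%, sum fusion 88.6%, rule fusion 83.4%.

What passing on this data shows: the pipeline recovers the planted
spectral/geometric structure, and both fusion rules exploit
cross-channel complementarity exactly as designed. What it does not show:
robustness to real EEG nonstationarity, artifacts, inter-subject spectral
variability, head pose, illumination, or genuinely ambiguous expressions —
real faces are not four prototypes, and real band-power/emotion coupling
is far weaker than the planted templates.

## Evaluation

Per subject: a seeded, state-stratified half/half split of the trials
(emulating a train-experiment / test-experiment protocol); the face
network (+PCA) and both SVMs are fitted on the training half; the four
detectors are scored on the held-out half. Trial-level pooling — the
protocol collects many images and EEG windows per trial but scores one
decision per trial — averages *normalized* face score vectors over a
trial's images before the argmax, and averages *raw* EEG decision values
over a trial's windows before normalizing (state) or argmaxing
(intensity). Accuracy is 100 × correct/total; column summaries are mean
and sample SD (n−1), reported half-up to 2 decimals; detector pairs are
compared with classical paired two-tailed t-tests (α = 0.05), which raise
a flagged error when the paired differences are constant.

The bundled experiments and the reproduction script run a desk-scale
version of the protocol: 80 trials per subject (40 train / 40 test after
the split), 6 images and 10 EEG windows per trial at 128 Hz, network
epochs 25 — sizes chosen so a 20-subject end-to-end run completes in well
under a minute while every classifier still sees all classes with
comfortable margins. The per-trial counts of the emulated acquisition
protocol (100 images, 200 windows, 40 trials) remain the `SubjectConfig`
defaults.

A packaged CSV carries the per-subject accuracy table reported for the
original twenty-subject study; `summarize`/`t_test_table` recompute its
summary row and significance pattern. Two of the published SD cells
(sum-rule 9.47, production-rule 5.19) do not recompute from the published
per-subject rows themselves (recomputation gives 9.48 and 5.31); the
package reports the recomputed values and the test suite marks the
discrepancy explicitly rather than adjusting either side.

## Known limitations

* The synthetic generator's class structure is far cleaner than real
  recordings; absolute accuracies on it say nothing about field
  performance (orderings, not levels, are the tested claim).
* The face detector stub assumes a bright face on a dark background; real
  deployments should plug in a trained frontal-face cascade.
* Linear SVM scores are uncalibrated margins; min–max normalization makes
  them commensurable with network outputs only in rank, which is all the
  sum rule uses.
* Intensity ground truth drives only the EEG synthesis; if a future data
  source ties intensity to facial geometry too, the generator's
  independence assumption must be revisited.
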