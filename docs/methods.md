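# Methods

This package is a closed-loop, desk-scale simulator of personalized
speed adaptation (PSA) for teleoperated robots: a policy-gradient
controller that reads an operator's EEG/EOG-derived mental state and
adapts the robot's speed level to the individual. A synthetic operator
stands in for human subjects, so every study the package runs is a
simulation study; the sections below state exactly what is modeled,
what is calibrated, and what passing results do and do not show.

## Signal model and preprocessing

The simulated acquisition device provides 30 EEG channels in 10–20
montage order plus 2 EOG channels at 1000 Hz, in µV. Preprocessing is
three steps per channel, in order:

1. **Baseline removal** — subtract the least-squares polynomial trend
   (degree 1 by default, configurable).
2. **Band-pass** — 4th-order Butterworth, 0.5–45 Hz for EEG and
   0.1–30 Hz for EOG; zero-phase (forward–backward) application by
   default since each round is processed from a buffer. A causal
   single-pass mode exists for strictly online use.
3. **Down-sampling** — polyphase resampling to 256 Hz (EEG) and 128 Hz
   (EOG); the preceding band-pass provides the anti-aliasing margin.

Per round, a 60 s buffer is cut into 50 sliding windows of 2000 ms;
the stride is `floor((L − W)/(n − 1))` samples (≈1183 ms at 256 Hz),
the unique uniform tiling for the stated counts. In the closed loop the
operator instead emits one 2000 ms segment per control step (50 per
round), which preserves causality; windows never span rounds.

## Mental-state features

Each 512-sample EEG window is decomposed by a 5-level discrete wavelet
transform (Daubechies-5) and reconstructed per level into the five
rhythm bands. At 256 Hz the dyadic bands are A5→delta (0–4 Hz),
D5→theta (4–8), D4→alpha (8–16), D3→beta (16–32), and D2+D1→gamma
(>32 Hz). Keeping D1 inside gamma makes the five band series sum back
to the window exactly (perfect reconstruction); the content above
45 Hz is negligible after the band-pass anyway.

Four candidate per-band features are implemented:

* **Sample entropy (SE)** `−ln(B^{v+1}/B^v)` with Chebyshev template
  matching, self-matches excluded; defaults `v = 2`,
  `eta = 0.2·std(x)`.
* **Differential entropy (DE)** `½·ln(2πe·σ̂²)` with `σ̂²` the mean
  squared deviation — the Gaussian closed form, exact for the
  band-limited Gaussian signals the generator emits.
* **Band power (BP)** mean of squares; **band energy (BE)** sum of
  squares (`BE = BP·n`). Time-domain definitions; both are exposed as
  plain replaceable functions.

Candidates are ranked by plug-in mutual information against discrete
(or midpoint-binarized) arousal/valence labels, continuous features
binned into 8 **equal-width** bins. Equal-width binning is deliberate:
it is scale-sensitive, so the log-compressed DE genuinely spreads
heavy-tailed band amplitudes over the histogram while raw BP/BE pile
into few bins — this is precisely why DE ranks highest and why an
equal-frequency (quantile) scheme, being invariant to monotone
transforms, would render the whole ranking vacuous (DE is a monotone
function of per-window BP). Quantile binning remains available via
`strategy="frequency"`.

The **EOG power ratio (PR)** is the Welch-estimated power in
(0, 1.5] Hz divided by that in (1.5, 30] Hz. Welch segments are 2 s
Hann windows at 50% overlap (clipped to the window length): a 1 s
segment has 1 Hz resolution and cannot represent the low band at all —
with 1 s segments a 0.5 Hz tone leaks enough power above 1.5 Hz to cap
the measured ratio near 10 where the analytic value is 10⁴.

The state vector is 152-dimensional: 30 channels × 5 bands of the
selected EEG feature (DE by default) in channel-major montage/band
order, then one PR per EOG channel. Vectors are min–max normalized to
[0, 1] per dimension. Normalization statistics are seeded from the
pretraining table, keep accumulating through the practice rounds, and
**freeze when practice ends**: formal training, testing and control all
see one fixed feature map. (Letting the map drift through the formal
rounds demonstrably moves even a frozen policy's behavior — the
heavy-tailed PR maxima keep expanding the range — and injects a
spurious trend into a no-learning control run.)

## Policy network and learning rule

The state-to-action mapping network is fully connected 152–80–4 with a
tanh hidden layer and softmax output: `p_θ(a|s) = softmax(W₂·tanh(W₁s +
b₁) + b₂)`. The four outputs are dimensionless speed levels with
multipliers {0.5, 1.0, 1.5, 2.0} (level 1 is the unadjusted speed).
Gradients of `ln p_θ(a|s)` are analytic (hand-derived backprop), so
they can be validated against central finite differences; no autodiff
framework is involved.

One task round is one episode τ of k = 50 (state, action) pairs sharing
the round's scalar reward R(τ). The update is REINFORCE with baseline,

    ∇R̄ ≈ (1/N) Σₙ Σᵢ (R(τⁿ) − b) ∇ ln p_θ(aᵢⁿ|sᵢⁿ),   b ≈ E[R(τ)],

with N = 1 (one update per episode) and b the running mean of the
formal-episode rewards observed so far, including the current one (the
first episode therefore has zero advantage). Parameters ascend by ADAM
with β₁ = 0.9, β₂ = 0.999, lr = 0.001, bias-corrected. The optimizer
state continues from the pretraining phase.

**Pretraining.** Before reinforcement learning the same network is
trained as a 4-way softmax classifier (cross-entropy, the standard
pairing) on a synthetic affect table: signals emitted at the four
(valence, arousal) corner states, passed through the real
preprocessing/feature pipeline, with a per-channel log-normal gain
jitter (σ = 0.4) frozen per dataset that emulates the inter-subject
domain shift of a public affect corpus relative to the operator at
hand. Class indices map directly onto output neurons in the
conventional quadrant enumeration (HVHA, HVLA, LVHA, LVLA); no
quadrant-to-speed semantics is assumed — learning the individually
correct mapping is the reinforcement phase's job. The closed-loop
default is 50 epochs on 25 vectors/class: on this small shifted set,
longer supervised training overfits and collapses the policy's entropy,
leaving no exploration for the 15-episode reinforcement phase. The
`pretrain` function's own default (10,000 epochs) suits larger tables.

## Task environments and rewards

Both tasks live on a continuous 2-D plane in dimensionless units with
a 2 s step clock (one feature window per control step) and a 50-step
round cap.

* **Trajectory tracking.** A preset polyline (straight; a ramp with
  entry/exit direction changes; or a two-period sine) of arc length 50.
  Per step the robot moves by the operator's intent times the current
  speed multiplier (magnitude-capped), and the distance to the nearest
  polyline segment is accumulated; the final segment is treated as
  extending past the finish so overrun along the path is not deviation.
  Reward: `R_t = 1/(Σ|Yₘ−Oₘ| + ε) + g·t + offset`.
* **Target positioning.** A bullseye re-randomized each round; the
  sight must stay within the enclosure radius continuously for T = 4 s
  (the lock timer resets on exit). Reward: `R_p = g·t + offset` on
  success.

The time-gain coefficient defaults to g = −0.004 with offset 1.0, so
quality falls with completion time and stays positive for feasible
rounds; setting g > 0 and offset 0 recovers the literal increasing-in-
time form. Operational quality is reported on the same positive scale
for every controller arm. Unfinished tracking rounds are scored on the
projected completion time `t·L/progress`; failed positioning rounds on
twice the elapsed time.

Difficulty ordering (straight < slope < curve) is a property of
direction changes, not incline: under an isotropic noisy controller a
pure inclined line is statistically identical to a horizontal one, so
the slope task is a kinked ramp, and the reference controller used to
verify the ordering carries direction momentum (human-like lag).

## The synthetic operator

The operator is the invented component that closes the loop; every
link it encodes follows a direction reported for human subjects, with
gains that are calibration knobs of the simulator, not empirical
claims.

**Latent state** (arousal, valence, fatigue, stress ∈ [0,1]):
first-order updates — fatigue grows saturating with time on task and
drops on rest events; stress jumps on "nervous" prompts and decays
with a 30 s half-life; valence steps on positive/negative prompts and
mean-reverts; arousal is a baseline minus 0.7·fatigue plus bounded
noise. Rounds start from a stationary re-baseline (fatigue 0.12,
stress/valence mostly reverted): the between-round micro-rest. This
stationarity is what makes a no-learning control run flat; an earlier
scheme that carried a fraction of the previous round's fatigue
converged slowly enough to create a systematic quality drift.

**Signal generation**: each EEG channel is a sum of five band-limited
Gaussian noise processes (spectral synthesis with exact Parseval
normalization of each band's variance). Modulations: fatigue scales
all band amplitudes down (factor 1 − 0.45·fatigue), with an extra
1 − 0.30·fatigue over the occipital/parietal/prefrontal group; stress
scales temporal-channel amplitudes up (1 + 0.8·stress); valence scales
beta amplitude (1 + 0.6·(valence − 0.5)) — this last link is invented
to make the four pretraining quadrants separable, the others mirror
reported directions. EOG is a low-frequency component whose amplitude
grows as arousal falls (1 + 3·(1 − arousal)) plus a fixed
high-frequency component. All links are verified through the full
preprocessing + feature pipeline, not on generator internals.

**Control**: intent aims along the task guidance vector at a rate that
partially compensates the speed gain (progress and noise both scale as
√multiplier), with Gaussian noise whose scale is
`base·(1 + fatigue)·(1 + 1.2·|applied − preferred|)`. The
mismatch-dependent term is the minimal mechanism by which a wrong speed
level degrades operational quality — the premise that makes speed
adaptation worth doing. The preferred level is the profile's base level
(aggressive 3, conservative 1 by default), reduced under heavy fatigue
or stress. Aggressive profiles also draw wider intent magnitudes
(relative spread 0.45 vs 0.15), which is what widens their realized
robot-velocity distributions.

## Experimental protocol

`run_protocol` mirrors the three-session design: training (18 rounds,
first 3 practice without updates), testing (15 rounds, frozen
parameters), control (15 rounds under the conventional method), with
testing and control facing identically seeded operators. The
conventional arm's mental-state indicator is the window's mean EOG
power ratio; its warning threshold is the 80th percentile of the
indicator over practice-scale data (a warning threshold that fired on
half of all windows would caricature the baseline), and it switches
between the unadjusted level 1 and the reduced level 0. The comparison
cohort is 2 aggressive (preferred level 3) and 4 conservative operators
with preferred levels {2, 2, 2, 1}: exactly one member's preference
coincides with the conventional level, so the expected outcome
structure is a 5-of-6 win for personalization.

Convergence is declared when the coefficient of variation of the last
5 episode rewards is below 0.15 **and** the modal action level lies
within ±1 of the operator's preferred level in at least 80% of those
episodes' steps — a quantification of "stable reward plus
operator-satisfying action pattern"; the paper-style criterion is
qualitative and these two constants are this package's defaults.

## What the simulations show — and what they cannot

Passing studies show that the implemented pipeline and learning rule
are internally sound: features carry the encoded state information,
the policy gradient is exact, learning improves operational quality
under the operator model's assumptions, and personalization beats a
fixed threshold rule whenever individual preferences differ from the
fixed level. They cannot show anything about real cortical signals
(the generator is stationary band-limited Gaussian noise without
artifacts, nonstationarity, volume conduction or blinks), about real
motor behavior, or about human-subject effect sizes; no human-derived
number is reproduced here.

Problem sizes used by the test suite and the acceptance script (18/15/
15 rounds of 50 steps, 20-seed learning studies, a 10-seed null
control, a 6-profile cohort, 25 pretraining vectors per class) are the
package's desk-scale study conditions, chosen once and documented
here.

## Numerical notes

* All randomness flows from named `SeedSequence` substreams of one
  master seed; every study is bit-reproducible.
* Wavelet gamma is computed by subtraction (window minus the four
  reconstructed lower bands), making perfect reconstruction exact by
  construction.
* The EOG PR saturates at 10¹² instead of dividing by a vanishing high
  band; sample entropy returns `inf` when no template pair matches at
  length v+1; DE raises on zero variance rather than returning −∞.
* Degenerate comparisons (identical sessions) report t = 0 rather than
  the 0/0 form.
* The minimal EDF writer emits one data record of 16-bit samples with
  per-channel physical scaling; round-trips are verified against an
  independent reader (mne). Quantization error is bounded by the
  channel amplitude range divided by 2¹⁵.

## Known limitations

* The operator model's gains are calibrated so the documented
  qualitative contracts hold at desk scale; they are not fitted to any
  human data.
* Episode-level uniform credit assignment (one scalar reward for 50
  steps) learns coarse action preferences in 15 episodes, not
  state-conditional switching policies; per-seed training improvement
  holds in ~85% of seeds, not all.
* The conventional-method arm depends on two documented defaults (its
  fixed levels and threshold percentile) that the source experiment
  left unspecified.
* EDF support targets the minimal subset needed for round-trips (one
  record, integer-second-free duration encoding); it is not a general
  EDF+ implementation.
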