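# Methods

This note documents the models, simulators and numerical choices behind
`errpnav`, and what the synthetic experiments do and do not establish.

## 1. Synthetic ErrP EEG

**What is emulated.** EEG recorded while a person watches a robot act.
Every observed action evokes a small shared action-onset response; observed
*errors* additionally evoke an error-related potential (ErrP): a
frontocentral negativity near 200 ms (N200) followed by a delayed positivity
near 300–600 ms.

**Model.** The error-minus-correct template is a sum of two Gaussian bumps
in time,

    d(t) = a_N exp(-(t - l_N)^2 / 2 w_N^2) + a_P exp(-(t - l_P)^2 / 2 w_P^2),

with defaults `l_N = 0.20 s, w_N = 0.045 s, a_N = -5 µV` and `l_P = 0.45 s,
w_P = 0.09 s, a_P = +6 µV`, jittered per trial by a Gaussian latency shift
(SD 20 ms).  The template projects onto the scalp through per-channel
*frontocentral weights* in [0, 1] (maximal at Fz/Cz, falling off toward
temporal/occipital sites).  Background noise is channel-independent 1/f
noise (spectrally shaped white noise, SD 6 µV); a white-noise option exists.
Error trials are scheduled by *fixed count* — exactly `round(n·f)` of `n`
trials — and shuffled, reproducing exact protocol totals (100 of 500 at
20%).

**Free parameters.** Single-trial ErrP amplitudes and noise levels are not
published anywhere we could anchor them; the defaults above were chosen once
so that single-trial decoding lands in the plausible range for this kind of
signal (held-out CNN ROC-AUC above 0.8 on a 400-trial calibration set, the
other families in the 0.7–0.9 band).  They are generator settings, not
empirical claims.  Everything downstream treats them as the study
conditions.

**What the simulator does not model.** Volume conduction (channels share
signal only through the weight vector, not a forward model), ocular/muscle
artifacts, electrode drift and impedance differences between gel and dry
hardware, inter-subject topography differences.  Passing tests therefore
show the *pipeline* is correct and well-calibrated on its stated
assumptions, not that any particular AUC would be obtained on real
recordings.

## 2. Preprocessing

Chain, in order, on the continuous recording: linear detrend; zero-pad 1 s
per side; 50 Hz notch (4th-order Butterworth band-stop, 49–51 Hz); 1–10 Hz
band-pass (4th-order Butterworth); unpad; common average reference;
downsample to 250 Hz (polyphase) when recorded faster; epoch to
[-0.2, 1.0) s around action onset; subtract the per-trial/channel mean of
[-0.2, 0) s.  Decoding uses the [0.2, 0.8) s window (150 samples at
250 Hz).

Choices the pipeline description leaves open, fixed here:

- filters are applied zero-phase (forward–backward), preserving component
  latencies in offline analysis; the attenuation figures quoted in tests are
  for the squared (two-pass) response;
- "4th order" is the overall filter order (SciPy design order 2 for
  band-stop/band-pass);
- sample windows are half-open `[start, stop)` so sample counts are exact;
- baseline correction is applied to the full epoch *before* the interest
  window is cut.

## 3. Classifiers

Four families, all fitted strictly inside training folds:

1. **Features + LDA** and **features + RBF-SVC**: five per-channel
   statistics of the interest window (mean, skewness, kurtosis, sample SD,
   peak-to-peak), standardized, PCA keeping the minimal component set with
   ≥ 95% summed explained variance, then a 5-fold grid search (LDA solver ∈
   {svd, lsqr, eigen}; SVC C ∈ 10^-2…10^3, γ ∈ 10^-4…10^1, six points each,
   log-spaced).  Skew/kurtosis of a constant channel are 0 by convention.
2. **Riemannian tangent space**: per-class xDAWN spatial filters (4 per
   class, generalized eigenvalue problem between evoked-response and
   full-data covariance), trials reduced to the 8 filtered components and
   stacked with the filtered class prototypes; sample covariance with 1%
   shrinkage toward the scaled identity (SPD guarantee on 150-sample
   windows); tangent-space projection at the Riemannian geometric mean of
   training covariances (fixed-point iteration, Frobenius tolerance 1e-10);
   LDA (svd solver, untuned).
3. **Compact CNN**: temporal convolution (8 filters, kernel = rate/2 = 125,
   no bias), batch norm, depthwise spatial convolution over channels (depth
   2, max-norm 1.0), batch norm, ELU, average-pool 4, dropout 0.5;
   separable convolution (depthwise kernel 16 + pointwise to 16 maps),
   batch norm, ELU, average-pool 8, dropout; dense softmax (max-norm 0.25).
   2,042 trainable parameters at 20 channels × 150 samples.  Training:
   categorical cross-entropy, Adam at 0.01, batches of 16, learning rate
   ÷10 after 5 epochs without validation improvement, best-validation
   weights restored.  The network and its backpropagation are implemented
   directly in NumPy; the long temporal convolution runs in the frequency
   domain (exact FFT convolution).

**Evaluation protocol.** Outer repeated stratified k-fold (5 splits; 10
repeats at full scale, 3 at desk scale), per-fold train/test ROC-AUC
(decision scores: LDA/SVC decision function, error-class probability for
the CNN), percentile bootstrap of the score distribution (5,000 iterations,
quantiles Bonferroni-corrected when several models/montages are compared in
one report).  BCI calibration uses a stratified 70/15/15
train/validation/test split (280/60/60 at 400 trials); the held-out test
ROC-AUC is the decoder's quality figure.

**Desk-scale training budget.** Cross-validated CNN fits cap training at 12
epochs with early stopping after 5 non-improving epochs — on this
generator's data, validation loss plateaus well within that budget; the
full-protocol cap of 300 epochs is the config default for standalone fits.

## 4. Navigation environment

A 21 × 21 × 11 cell grid (x, y, z); six unit moves
(left/right/forward/backward/down/up).  A full-width wall sits at the middle
y-plane, blocked from the floor to z-index 5 (of 10), so the agent must
climb over.  Starts are sampled uniformly from a 6 × 11 floor rectangle on
the near side; the goal lies on the floor beyond the wall.  Observation:
the three coordinates normalized by (dim − 1) plus five laser readings
(free cells before the first obstacle along −x, +x, −y, +y, −z, divided by
a 5-cell max range, clipped to [0, 1]).  Collisions (moves into blocked
cells or out of bounds) leave the agent in place and do not end the episode
(a flag makes them terminal); reaching the goal yields reward 1 and ends
the episode; episodes cap at 160 steps.  An optional distance-shaped
("rich") reward exists for baselines.

The *optimal action* at any cell is the first move of an A* shortest path
(Manhattan heuristic, deterministic tie-breaks by action index) — the
"green arrow" a human observer judges actions against.

**Assumptions made explicit** (the published description leaves them open):
wall geometry and height, laser directions and range, sparse-reward
magnitude, non-terminal collisions, 0-based cell coordinates.  All sit
behind constructor arguments.

**Goal persistence.** The observation carries no goal information, so the
goal is sampled once per world lifetime (per training run / per seed) and
only the start is re-randomized each episode; with a per-episode goal the
task would be unobservable to a memoryless policy.  A `resample_goal` flag
restores per-episode goals.

## 5. Human-feedback policy

Feedback channels: perfect oracle (label = action equals the A* action);
noisy keyboard (label flipped with probability p, default 0.3); simulated
BCI (2 × 2 confusion channel; a stated decoder AUC maps to a balanced
accuracy via the equal-variance binormal model, acc = Φ(Φ⁻¹(AUC)/√2), e.g.
0.77 → 0.70); and the full loop (synthesize one EEG epoch conditioned on
the action's correctness, preprocess, classify with the calibrated CNN).

The HF policy is an 8 → 32 (ReLU) → 6 softmax network whose outputs
estimate each action's probability of positive feedback.  Online training:
the agent acts ε-greedily on the improving policy (ε linear 1.0 → 0.1 over
the 1,000-label budget; a pure-random mode exists), every executed action
is labelled through the channel and appended to an append-only replay
store; batches of 20 are stratified to 10% collision / 90% non-collision
events when available; the executed action's softmax output is trained
toward its binary label with binary cross-entropy (a one-vs-all sigmoid
variant sits behind a flag) using Adam at 1e-3, 8 gradient steps per
feedback event.  Batch size, learning rate and steps-per-event are free
optimization parameters chosen for reliable convergence within the label
budget.

## 6. Guided deep RL

Discrete-action DDPG: actor 8 → 64 → 64 → softmax over 6 actions; critic
(8 + 6) → 64 → 64 → 1 taking one-hot actions for stored transitions and the
actor's soft output for the policy gradient.  γ = 0.9, τ = 0.005 (Polyak
target updates after every gradient step), Adam learning rates 0.003
(actor) and 0.001 (critic), 20 updates per environment step at full scale,
each on a freshly sampled batch.  Replay is reward-prioritized: the
ceil(10%) of each batch with the highest stored reward (ties broken by
recency), remainder uniform without replacement.  Exploration: ε decays
linearly from 1 to 0 at a fixed global step count (125,000 at full scale);
while ε fires the action comes from the HF policy's greedy choice (uniform
random for the sparse baseline); otherwise the agent *samples* from the
actor's softmax during training (argmax at evaluation) — a stochastic
discrete policy needs on-policy action diversity for the critic to rank
alternatives.  The actor loss carries a small entropy bonus (β = 0.01);
without it the softmax saturates early on critic noise and its gradient
vanishes permanently.  Both choices are this package's adaptation
decisions for the discrete-softmax actor.

**Evaluation.** Per-episode SPL = S·ℓ/max(p, ℓ) with ℓ the A* shortest-path
length from the episode's start and p the executed moves *including*
collision-blocked attempts (collisions cost path length).  Runs are
compared by resampling whole runs: pointwise bootstrap band (1,000
iterations) and a final-window summary (mean SPL over the last 500 episodes
at full scale, last 50 at desk scale) bootstrapped across runs.  Bootstrap
CIs that do not overlap are read as strong evidence of a difference,
overlapping CIs with both means outside the other interval as moderate
evidence.

**Desk scale.** The full protocol (10 models × 8,000 episodes × ≤160 steps
× 20 updates/step) is far beyond a single-core desk budget.  The shipped
desk configuration uses a 9 × 9 × 5 world, 250 episodes of ≤ 40 steps, 4
updates per step, batch 32, ε ending at 3,500 steps, 5 seeds per mode.  On
the desk world the wall is raised to leave only the top z-layer clear, so
undirected exploration crosses it about as rarely as in the full-size task;
with the default half-height wall the small world is easy enough for a
lucky random walk to solve, which erases the contrast the comparison is
designed to measure.  Desk-scale results establish the *ordering*
(HF-guided above sparse) and the machinery, not the full-scale SPL values.

## 7. Known limitations

- The synthetic EEG generator's amplitude/noise defaults are free
  parameters; absolute AUC levels track them directly.
- Desk-scale RL runs have high seed-to-seed variance; conclusions are
  drawn only from run-level bootstrap CIs, and only about ordering.
- The NumPy networks are deliberately small; no GPU path exists (none is
  needed at these sizes).
- The full-scale SPL reproduction (8,000 episodes × 10 models) is runnable
  via `errpnav run-rl --scale full` but takes hours per mode on one core
  and is not exercised by the test suite.
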