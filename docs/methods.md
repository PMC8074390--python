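# Methods

This document describes the algorithms implemented in `semgintent` and the
conventions that connect them. The package re-implements, on synthetic data,
an online-adaptive pipeline for predicting lower-limb motion intention from
surface electromyography (sEMG): a convolutional autoencoder (CAE) compresses
raw sEMG windows into features, recurrent predictors map features plus recent
motion to future knee angles and to the time of the next heel strike, and a
learned (meta-trained) optimizer adapts a small parameter subset of each
network online when the signal distribution shifts.

## 1. Signals and rates

| stream | rate | role |
|---|---|---|
| sEMG, 9 channels | 10000/9 Hz ≈ 1111.1 Hz | muscle activity |
| motion (IMU-derived knee angle), 7 values/sample | 4000/27 Hz ≈ 148.1 Hz | kinematics |

The rate ratio is exactly 15 : 2 — 15 sEMG samples and 2 motion samples both
span 13.5 ms. All windowing arithmetic in `preprocessing` is built on this
rational ratio, never on floating-point resampling.

`synthetic_gait` generates paired streams from a gait-cycle model: a stride
clock with controlled period jitter drives per-muscle activation envelopes
(rectified, low-pass shaped bursts at muscle-specific gait phases), which
multiply band-limited carrier noise to produce sEMG; the same clock drives a
smooth knee-angle trajectory and heel-strike (initial contact, IC) event
times. Subject individuality = per-channel gain vectors + cycle statistics;
distribution shift = amplitude gain, spectral (carrier-band) compression
simulating fatigue, and envelope timing jitter.

## 2. Windowing and alignment (`preprocessing`)

* sEMG images: 9×200 windows (180 ms), stride 15 samples (13.5 ms).
* Motion blocks: 13 consecutive motion samples, stride 2 (13.5 ms),
  decimated to 7 values → a 7×5 block.
* Pairing: image *i* ends at sEMG sample 15·i + 200, i.e. at time
  13.5·i + 180 ms. The first motion-sample boundary at or after that instant
  is sample 2·i + 27, so image *i* is paired with the motion block ending at
  motion sample 2·i + 27 (`ALIGN_END = 27`). The residual gap lies in
  [0, 6.75) ms for every window — under one motion-sample interval.
* Labels: future knee angles at horizons {1, 5, 10, 15} motion samples =
  {6.75, 33.75, 67.5, 101.25} ms past the window end, and the time to the
  next IC in ms (`time_to_ic`).

## 3. Muscle synergies and channel rearrangement (`synergy`)

Envelopes (|x| then 4 Hz zero-phase Butterworth low-pass) of the 9 channels
are factorized with rank-5 non-negative matrix factorization, V ≈ W·H, using
Lee–Seung multiplicative updates. These updates are implemented by hand
because their monotone-objective property is itself a tested contract; the
per-iteration Frobenius error history is stored on the fitted model.

Each synergy row of H ranks the 9 channels by contribution (stable descending
argsort). The CAE's third encoder layer produces 80 maps; they are split into
5 groups of 16, and within group *g* the maps are rearranged by synergy *g*'s
channel order. This injects synergy structure between encoder stages, as the
adaptable layer that follows sees synergy-grouped inputs.

## 4. Convolutional autoencoder (`cae`)

Encoder (valid convolutions, stride 1, ReLU):

| layer | kernel | maps | output |
|---|---|---|---|
| conv1 (Single-Kernel) | 1×105 | 20 | 20 @ 9×96 |
| conv2 (Single-Kernel) | 1×55 | 40 | 40 @ 9×42 |
| conv3 (Single-Kernel) | 1×30 | 80 | 80 @ 9×13 |
| — synergy rearrangement of the 80 maps — |
| conv4 (adaptable) | 4×4 | 40 | 40 @ 6×10 |
| conv5 | 4×4 | 40 | 40 @ 3×7 |

The decoder mirrors the encoder with transposed convolutions. The temporal
extent after the Single-Kernel stack is 200−104 → 96−54 → 42−29 = **13**
(acceptance target t4). The 40×3×7 code is reshaped time-major into a 7×120
feature matrix — column index = 40·row + map — giving feature width **120**
(target t5). Reconstruction fidelity is tVAF = 1 − SSE/SST.

The 1-D temporal kernels are evaluated in the frequency domain
(`scipy.fft`, correlation theorem), which is ~27× faster than im2col at
these kernel lengths; gradients likewise. Inputs are normalized by the
training-set RMS (`CAE.input_scale`), and reconstructions are scaled back.

## 5. Motion-intention predictors (`predictor`)

Per window: the 7×120 feature matrix passes row-wise through FC1(120→100)+ReLU
and FC2(100→1), giving 7 scalars (the squeeze is linear — a ReLU on a single
scalar can die permanently during training); concatenated with the 7×5 motion
block → a 7×6 sequence consumed by a 3-layer, 200-unit LSTM; the last hidden
state passes FC3(200→100)+ReLU and FC4(100→1). Separate predictors are
trained per angle horizon and for time-to-IC.

Conditioning: motion inputs are z-scored with training-set statistics stored
on the predictor (raw angles and angular rates saturate the LSTM gates), and
targets are z-scored during training with predictions de-standardized. The
angle heads regress the *change* from the current angle (the last motion
sample) and add it back at predict time; the event head regresses
log1p(time-to-IC) — uniform *relative* precision for a non-negative
time-to-event quantity, so absolute error shrinks as the contact approaches. Features are treated as constants (detached): predictor
gradients never reach the CAE.

## 6. Online adaptation (`adaptation`)

Only two small subsets are tuned online:

* predictor FC3, even rows (1-based) of the 200×100 weight matrix plus the
  100 biases → 100·(100+1) = **10,100** parameters;
* encoder conv4, input channels with 1-based index divisible by 4 (20 of 80)
  plus the 40 biases → 20·40·4·4 + 40 = **12,840** parameters.

A coordinatewise learned optimizer proposes increments: per coordinate the
input is (θᵢ, preprocessed gradient pair) → FC(3→40)+Tanh → 3-layer 40-unit
LSTM (shared weights φ, per-coordinate state) → FC(40→1), scaled by 0.1.
The output layer starts at zero, so the untrained optimizer is exactly a
no-op and meta-training moves it away from identity only where the
meta-loss provides signal.
Gradients are preprocessed with p = 10: |g| ≥ e⁻ᵖ → (log|g|/p, sign g),
else (−1, eᵖ·g).

φ is meta-trained on the training population: batches are grouped by
subject; the optimizer is unrolled for several steps; the meta-loss is the
sum of post-update losses; backpropagation into φ uses the first-order
approximation (gradient inputs treated as constants), which gives
dL/dΔθ_t = Σ_{s≥t} ∇loss(θ_{s+1}) — each term is already computed as the
next step's optimizer input. Tuned parameters are reset to their trained
values every `reset_every` epochs. The CAE (reconstruction loss) and the
predictor (prediction loss) get independent optimizer networks and are
adapted independently.

## 7. Evaluation protocol (`evaluation`)

Leave-one-subject-out: group A (8 desk-scale training subjects) trains, in
order, synergies → CAE → predictors → adaptation optimizers. A held-out
group-B subject is generated with a calibrated shift (spectral compression
as the main driver — amplitude gain alone is nearly invisible to a ReLU
network, which is scale-equivariant up to biases). Half of B's stream updates
the tuned subsets through the learned optimizer (one pass = one adaptation
iteration); the other half is the test half.

Reported metrics:

* tVAF intra (group-A held-out segments), inter (B before adaptation),
  adapted (B after adaptation), and the recovered fraction of the drop
  (adapted − inter)/(intra − inter);
* mean max-stride knee-angle error per horizon, before/after adaptation;
* event advance: per stride, the largest time-to-IC T such that every
  prediction with label ≤ T is within 6 ms;
* event error near IC (last 20% of the stride) vs far from IC (earliest
  20%) — near should be smaller.

Two schedules share all code paths: the full reference schedule
(SGD, batch 100, 340/340/550 epochs with the stated step decays) and the
desk scale (`TrainConfig.desk_scale`, Adam, reduced epochs and data caps)
sized to run in minutes on one CPU. Desk scale uses Adam because plain SGD
measurably cannot traverse the CAE's ill-conditioned loss surface in the
reduced step budget.
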