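# Methods

## Signals

A pose sequence `P` is a `T × J × 3` array of joint coordinates in metres.
Supervision signals derived from it:

- **Reference pose flow (RPF)** `F_t = P_t − P̄`, with `P̄` the temporal mean
  pose. The mean is computed as `P_0 + mean(P − P_0)`; the shift improves
  conditioning and makes the flow of a temporally constant sequence exactly
  zero instead of ~1e−16 summation noise.
- **Consecutive pose flow (CPF)** `F_t = P_{t+1} − P_t`. The difference has
  `T−1` rows; the last row is repeated so every flow shares the sequence
  shape consumed by the decoders (the alternative, a leading pad, is
  equivalent up to a one-frame shift; trailing was chosen and is used
  consistently).
- **Decoupling** `F = M · O`: `α = ‖F‖₂` per entry and unit vectors `F/α`.
  Orientation is undefined at zero motion; entries with `α ≤ eps`
  (`eps = 1e−8` m, far below sensor noise) carry a zero vector and a False
  validity flag, and the orientation loss averages only over valid targets.

## Normalization

The recipe removes nuisance variation in this order: null (all-zero) frames
are padded with the nearest preceding valid frame (leading nulls take the
first valid frame); the spine-mid joint of every frame is translated to the
origin; one rotation built from the reference frame maps the hip→spine bone
to +z and the right→left shoulder direction to +x; sequences are resampled
to exactly 50 frames (evenly spaced `round(linspace)` indices when longer,
repeat-last padding when shorter, so batches are rectangular).

Joint indices follow the Kinect-V2/NTU convention (0 spine-base, 1
spine-mid, 4 left shoulder, 8 right shoulder), all configurable. The
rotation is computed **once per sequence** from the first valid frame: a
per-frame rotation would cancel body-orientation changes over time, which is
precisely the signal the orientation flow is meant to carry. Per-frame mode
(`rotation_reference="per_frame"`) exists for ablation. The composed
transform is idempotent and invariant to global translations and proper
rotations of the input; these are tested properties.

Multi-body recordings are reduced to the single most active track: the track
maximizing the sum over joints and axes of the temporal coordinate variance
over non-null frames, ties to the lowest body id. Any deterministic
reduction would do; motion energy picks the performing actor rather than a
bystander.

## Networks

All four variants share one topology. The encoder is a single-layer LSTM
(optionally two layers) over per-frame flattened coordinates (`T × 75` for
25 joints); its last-step output `Z` (width `C`, default 256) is the action
representation. Each decoder tiles `Z` to every time step, runs a
single-layer LSTM, and applies a per-frame linear map. The explicit variant's
magnitude head emits unconstrained reals (MSE against nonnegative targets
needs no positivity transform; a softplus could be added but changes
nothing tested) and its orientation head normalizes each 3-vector to unit
length so the cosine term is bounded. The implicit/generalized variants emit
pose-shaped variables and derive magnitude/orientation through the RPF +
decoupling pipeline inside the computation graph.

Weights are initialized uniform `±1/√C` with a +1 forget-gate bias offset,
from a recorded seed. Differentiable norms use the smooth surrogate
`sqrt(‖v‖² + eps²)`, which agrees with the exact norm to within
`eps²/(2‖v‖)` and keeps gradients finite at zero motion.

## Objectives

"MSE" throughout is the mean of squared element differences, so printed loss
values are comparable across batch sizes and sequence lengths. The
orientation loss is `(1 − O·Ô)/2 ∈ [0, 1]`, averaged over valid target
entries. The baseline total is the mean (not sum) of its two decoders' pose
MSEs. The adaptive multi-task combination is parameterized by
`s_k = log δ_k²`, giving `Σ_k [exp(−s_k) L_k / 2 + s_k / 2]` —
unconstrained in `s`, and exactly the Gaussian-likelihood form
`Σ L_k/(2δ_k²) + log Π δ_k` of homoscedastic uncertainty weighting. Each
weighted term of the implicit/generalized losses gets its own `s_k` (3 and 4
terms respectively). Fixed weights default to 1; adaptive mode is the
default for the multi-task variants.

## Training and evaluation

Adam (β = 0.9/0.999), learning rate 1e−3 decayed ×0.1 after every 80
epochs, batch 128, up to 100 epochs; all shuffling and initialization
derive from the config seed, so a run is bit-reproducible on one device.
The decay interval is interpreted in epochs (a per-step decay would collapse
the rate within one pass at realistic dataset sizes); a per-step unit is
selectable. A non-finite loss aborts with the offending term named.

Evaluation uses only the trained encoder. Each test representation takes
the label of the most cosine-similar training representation; ties break to
the lowest training index. Representations are not L2-normalized first —
cosine similarity is already scale-free. Accuracy, a confusion matrix
(rows = true class) and per-class recall are reported.

The overfit harness (`training.overfit`) is a capacity sanity check: 500
full-batch Adam steps at a fixed 1e−3 rate (no decay — six decays in 500
steps would freeze the optimizer and test the schedule, not capacity),
reporting fixed-weight initial and final losses.

## Synthetic data

Sequences are `template + shape_offset + amplitude · g(d · s · t/T) + noise`
with `g` the identity (ramp) or `sin(2πu)` (sine), `d = ±1` the time
direction, `s > 0` the speed scale, and isotropic Gaussian joint noise
(default σ = 1 cm, the order of Kinect joint jitter). The 25-joint template
is a fixed anatomical standing posture satisfying the alignment
preconditions. Per-joint amplitude directions are fixed draws from a
constant-seeded generator with row norms spread over 0.05–0.25 m.

The default benchmark has four classes — `ramp_up`/`ramp_down` differing
only in direction, `sine_slow`/`sine_fast` differing only in speed — with
10 train + 10 test sequences per class. Ramp profiles give closed forms
used as oracles: a direction flip preserves CPF/RPF magnitudes exactly and
negates orientations (cosine distance 1); doubling the speed doubles CPF
magnitudes exactly. For sine profiles the speed scale enters the phase, so
the doubling is approximate there; the exact-ratio checks use ramp twins.

`capacity_probe_dataset` is a separate 8-sequence fixture for overfit
checks: noiseless, with heterogeneous amplitudes, profiles, directions and
speeds per sequence. It is clean by design — a capacity check should ask
whether the networks can represent motion signal, not whether they can
memorize per-frame noise directions within a step budget.

What the generator does not emulate: bone-length rigidity during motion
(offsets are applied per joint directly), realistic kinematic chains,
viewpoint-dependent occlusion, or tracking dropouts beyond all-zero null
frames. Passing tests therefore demonstrate the correctness of the
pipeline's math and the learnability of direction/norm contrasts under
joint jitter — not performance on real mocap distributions.

## Problem sizes for desk-scale checks

The representation width for trained checks is 64 (256 remains the library
default) and the benchmark harness trains 100 epochs at batch 16 with 3
seeds per variant; these sizes keep the full check suite in the minutes
range on one CPU while leaving the qualitative ordering
(`pdf_g ≥ baseline > chance`) stable.

## Known limitations

- The implicit variant (`pdf_i`) converges markedly more slowly on the
  orientation term than the other variants in small fixed-dataset runs.
  The failure mode is crisp: a minority of entries settles exactly
  antiparallel to their target orientation, which is a stationary point of
  the cosine loss, and the only anchors available — the decoder-agreement
  constraint and the magnitude term — penalize the pose excursion needed to
  flip a high-magnitude entry's sign. The generalized variant's
  pose-reconstruction anchor resolves the sign directly, and in every
  experiment here `pdf_g` trains to a far lower loss and at least as good a
  1-NN accuracy — the same ordering that motivates preferring the
  generalized model.
- The NumPy autograd engine is single-threaded per BLAS call and has no GPU
  path; it is sized for datasets of tens-to-hundreds of sequences, not 40k.
- The 1-NN protocol stores all training representations; for very large
  training sets an approximate index would be needed.
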