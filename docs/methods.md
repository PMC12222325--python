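# Methods

## Scope and model

`pestfsod` implements a two-stage few-shot detector in which three
components interact: a feature aggregation module (FAM) that enriches
query RoI features with support-set features via scaled dot-product
cross-attention; a supervised contrastive branch (SCL) that shapes the
RoI embedding space with inverse-class-frequency weights; and a
multi-task objective `L_total = L_cls + L_reg + λ₁ L_agg + λ₂ L_SCL`
combining focal classification, smooth-L1 regression and an attention
regulariser. The protocol is the standard fine-tuning FSOD recipe:
train on base classes with abundant data, then extend the classifier to
novel classes and fine-tune on a balanced K-shot set drawn from base and
novel classes alike.

Everything differentiable is written in numpy with hand-derived
backward passes (linear algebra only); the test suite checks every
gradient against central finite differences at relative tolerance 1e-4.

## Detector architecture (desk scale)

* **Backbone/FPN.** A four-stage convolutional pyramid (channels
  12/24/48/64, stride-2 stem, 3×3 convolutions + ReLU + 2× pooling)
  produces C2–C5; a top-down FPN with 1×1 lateral and 3×3 smoothing
  convolutions yields P2–P6 at a common width D = 64. The backbone and
  FPN are *frozen at their Kaiming initialisation*. This is a deliberate
  design choice, not an approximation of convenience only: random
  convolutional pyramids preserve colour and coarse shape statistics,
  which are exactly the cues that separate the procedural pest classes,
  and freezing them keeps every trainable part a linear/MLP head with an
  exact analytic gradient. A deeper trainable backbone can be swapped in
  behind the same `ModelConfig` surface for photographic data.
* **RoI features.** Boxes are assigned to a pyramid level by the
  standard area heuristic (canonical size 48 px), RoI-Aligned to a 7×7
  grid (one bilinear sample per bin), average-pooled to a 3×3 spatial
  grid and flattened to a 576-vector, then per-row standardised.
  Retaining a coarse spatial grid rather than a global average is what
  lets the box regressor see where an object sits inside its proposal;
  with a fully pooled vector, localisation saturates near the proposal
  grid resolution.
* **Proposals.** An RPN-lite scores five square anchors (10–38 px) per
  P3 location with linear objectness/delta heads (binary cross-entropy +
  smooth-L1, 32+32 sampled anchors per image); at prediction time the
  top 50 proposals after NMS (IoU 0.65) are classified and refined. Two
  `proposal_source` alternatives bypass the RPN for controlled
  experiments: `groundtruth` and `jittered_groundtruth` (GT boxes with
  scale noise 0.65–1.5 and centre shifts up to ±0.3 of the box size,
  plus random background boxes). During training the RoI head sees
  jittered GT boxes *and* live RPN proposals, so it learns from the same
  hard negatives it will face at test time.
* **Heads.** Classification (576→96→C+1 softmax) and class-agnostic
  regression (576→96→4) MLPs with dropout 0.1 on their input during
  training. Regression targets use the standard (dx, dy, dw, dh)
  log-space encoding, scaled by (10, 10, 5, 5) so smooth-L1 gradients on
  small offsets are not vanishingly weak. Prediction applies the
  regressor twice (`refine_passes = 2`): the refined box is re-pooled
  and refined again, which measurably tightens localisation at
  negligible cost.

## FAM

Projections W_Q, W_K, W_V are bias-free maps from the RoI feature dim to
d_k (default: the FPN width, 64); scores are scaled by √d_k and
row-softmaxed; the aggregated value matrix is mapped back by an output
projection W_O (identity-initialised, exactly the identity when
d_k equals the feature dim) and gated into the residual sum by a
learnable scalar α, initialised at 0.5 (mid-way between ignoring and
fully trusting the support set). Support rows are per-instance pooled
RoI features, not class prototypes. At fine-tuning time the K-shot set's
ground-truth RoIs form a fixed support bank; the same bank is kept as
the permanent support set at inference, since a deployed few-shot
detector has nothing else to condition on.

The attention regulariser is `L_agg = (1/N_q) ΣΣ a_ij log a_ij +
(1/N_q) ΣΣ |s_ij|`. The first term is the *negative* entropy, so
minimising the combined loss simultaneously spreads attention across
support samples and shrinks raw score magnitudes; the two pulls oppose
each other at 1:1 scale. The formulation in the source literature is
self-contradictory on the entropy sign (its standalone definition of the
entropy term would concentrate attention when minimised, contradicting
its stated goal of even coverage); we implement the combined form
verbatim and expose `entropy_sign` to flip the reading. `L_agg` is
bounded below by −log N_s.

## SCL

The projection head is a one-hidden-layer MLP (D→96→64) followed by L2
normalisation; it exists only during training. Membership in the
contrastive batch is gated by the shot-specific IoU threshold
(0.6/0.7/0.8 for 3/5/10 shots): only RoIs overlapping a ground-truth box
at least that much enter, labelled by that ground truth. Class counts
N_y for the weights w_y = 1/N_y are taken from the fine-tuning support
set, not the mini-batch — at K-shot scale batch counts would be noise.
Rows without positives are skipped (the 1/|P(i)| factor is undefined for
them); weights are used raw, with overall scale absorbed into λ₂.

An important protocol point: the shot-specific IoU thresholds gate *only*
the contrastive branch. Detection target assignment keeps the standard
0.5 foreground threshold in both stages; using 0.8 for assignment at
10-shot labels nearly every proposal background and collapses
fine-tuning (we measured base-class AP falling from ≈0.86 to ≈0.09).
This matches the contrastive-proposal-encoding convention of the method
lineage the loss comes from.

## Losses

* Focal: `−mean_i α_t (1−p_t)^γ log p_t`, γ = 2 by default, α_t =
  inverse class frequency normalised to mean 1 (background weight 1);
  with γ = 0, α = 1 it reduces exactly to cross-entropy. True-class
  probabilities are clamped at 1e-12 with a warning.
* Smooth-L1: quadratic within β = 1 of zero, linear outside (the two
  branches meet with matching value and slope at β = 1); summed over the
  four delta components, mean over boxes.
* Total: `L_cls + L_reg + λ₁ L_agg + λ₂ L_SCL`, an exact arithmetic
  identity in the returned bundle. λ₂ per shot is {3: 0.2, 5: 0.5,
  10: 0.5}; λ₁ defaults to 0.5 for all shots (the literature conflates
  the two weight symbols in a single triple, leaving λ₁ unpinned). NaN
  in any component aborts with the component named.

## Training schedule

SGD with momentum 0.9, weight decay 1e-4, batch size 4. The reference
protocol values (base LR 0.02, 18 000 iterations, evaluation every
3 000, fine-tune LR 0.001) are the `TrainConfig` defaults. The
desk-scale configuration compresses this to 300 base and 150 fine-tune
iterations on 96×96 scenes; because the fine-tune stage is compressed
~100×, its LR is raised to 0.01 — at 0.001 the freshly added novel-class
classifier columns barely move in 150 steps. Step decay (×0.1 at 2/3 of
iterations) is the default; cosine annealing is available. Base training
keeps FAM and SCL off by default (flags exist to enable them): the base
stage is plain two-stage detection, with the few-shot machinery
introduced at fine-tuning. When a validation manifest is supplied the
best-by-validation-mAP checkpoint is returned; checkpoints bundle
weights, optimizer state and current LR in a single pickle archive, and
a save/load round-trip reproduces predictions bit for bit. Training
divergence (non-finite loss) reverts to the last good state.

## Synthetic scenes: what they emulate, and what they do not

`generate_scene` renders procedural "pests" — ellipses, rectangles,
triangles and star-convex blobs with per-class hue, texture-noise
amplitude and aspect jitter, each fitted inside a circle of the sampled
diameter — on low-frequency textured backgrounds with pixel noise.
Placement is rejection sampling (50 retries) under a pairwise-IoU cap;
infeasible objects are skipped with a warning, never looped forever.
Boxes are tight mask bounding boxes, COCO-style (x, y, w, h), always
fully inside the image. Each generated image contains instances of a
single class (1–3 by default; the source benchmark is dominated by
single-species images), which makes requested per-class image counts
exact. A `hard_background` knob blends object colour toward the
background to emulate camouflaged pests; it is off by default. The
default 20-class profile reproduces the published per-class training
image counts (92–400, total 5076), and `pestdet20_profile(scale)`
shrinks it proportionally.

What passing tests on these scenes shows: that the pipeline's
*mechanics* — episode construction, aggregation, contrastive shaping,
loss assembly, optimisation, evaluation — behave as specified, and that
the few-shot protocol transfers to novel classes when classes are
separable in principle. What it does not show: robustness to
photographic nuisance (pose, lighting, occlusion, fine-grained
inter-species similarity), for which the frozen random backbone would
also be inadequate; absolute APs on real pest imagery are out of reach
of this desk-scale stand-in and are not claimed.

## Evaluation

A detection is a true positive when its IoU with an unmatched same-class
ground truth strictly exceeds 0.5 (configurable to ≥); matching is
greedy in descending score and one-to-one. AP uses all-points
interpolation (the integral of the monotone precision envelope over
recall). bAP/nAP/mAP are unweighted means over base/novel/all evaluated
classes; classes with zero ground truth in the query set are excluded
from the means with a warning, which can occur in small synthetic runs.
The identity mAP = (N_B·bAP + (N−N_B)·nAP)/N holds to 1e-9 by
construction and is asserted in tests. Confusion matrices assign each
ground truth the class of its best-IoU unused detection above threshold
(class-agnostic matching, score threshold 0.5 by default); both raw
counts and row-normalised views are available, as the normalisation
convention in published figures of this kind is typically unstated.

## Numerical choices and edge cases

* Softmax and log-sum-exp are computed with max-shifting; 0·log 0 := 0
  in entropy terms; attention rows must sum to 1 within 1e-4 on entry to
  the regulariser.
* Ties: NMS breaks score ties by original index; target assignment
  resolves equal-IoU ground truths to the lower index; detections are
  sorted stably.
* Degenerate inputs: zero-area boxes get IoU 0 with a warning;
  zero-norm embeddings raise naming the row; empty support sets make
  attention an error rather than a silent no-op.
* All arrays are float64: gradient checks at 1e-4 relative tolerance
  are not meaningful in float32.
* Determinism: every stochastic step draws from an explicit
  `numpy.random.Generator`; identical spec + seed reproduce scenes
  bit-identically and annotation JSON byte-identically, and the CPU
  pipeline is deterministic end to end for a fixed config and seed.

## Known limitations

* The frozen random backbone is a feature prior, not a learned one; it
  is the right tool for colour/shape-separable procedural scenes and the
  wrong one for fine-grained real imagery.
* The RPN-lite operates on a single pyramid level with square anchors;
  extreme aspect ratios would need anchor shapes the desk-scale scenes
  do not produce.
* The published class splits ship as fixtures; the shuffles that
  produced them are not reproducible because their seeds were never
  published.
* Fine-tuning keeps the K-shot support bank fixed; support features are
  not refreshed as the FAM parameters train (the bank holds pre-FAM
  pooled features, so this is consistent, but a trainable-backbone
  variant would need to recompute it).
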