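# pestfsod

Few-shot object detection for agricultural pest monitoring, built around
three ideas from the recent pest-detection literature: cross-attention
**feature aggregation** from a support set, **class-weighted supervised
contrastive learning** on detection proposals, and a **multi-task loss**
combining focal classification, smooth-L1 regression and an
attention-entropy/sparsity regulariser. The package targets researchers
who want to study these components quantitatively on a desk (one CPU, a
few minutes) rather than on a GPU cluster: a procedural scene generator
reproduces the statistical structure of the PestDet20 benchmark — 20
imbalanced classes (92–400 training images each), small multi-scale
targets, cluttered backgrounds, 15 base / 5 novel class splits — so every
stage of the pipeline is testable without the original photographs.

## The method

Support-set RoI features enrich query RoI features through single-head
scaled dot-product attention:

```
Q = F_query W_Q,   K = F_support W_K,   V = F_support W_V
A = softmax(Q Kᵀ / √d_k)            (row-stochastic attention)
F_agg = A V
F_enhanced = F_query + α · F_agg    (α a learnable gate)
```

Enhanced features feed a projection head `z_i = Normalize(Head(F_enhanced,i))`
and the class-weighted supervised contrastive loss

```
L_SCL = Σ_i  (w_{y_i} / |P(i)|) Σ_{p∈P(i)} −log( exp(z_i·z_p/τ) / Σ_{a∈A(i)} exp(z_i·z_a/τ) )
```

with `w_y = 1/N_y` correcting class imbalance. Training minimises

```
L_total = L_cls + L_reg + λ₁ L_agg + λ₂ L_SCL
```

where `L_cls` is the focal loss `−Σ α_t (1−p_t)^γ log p_t`, `L_reg` the
smooth-L1 box loss, and `L_agg` adds the negative attention entropy to an
L1 penalty on the raw scores. The protocol is two-stage: base training on
abundant base-class data, then K-shot fine-tuning (K ∈ {3, 5, 10}) over
base + novel classes with shot-specific settings (contrastive IoU
threshold 0.6/0.7/0.8, τ = 0.2, λ₂ = 0.2/0.5/0.5). Evaluation reports
per-class AP (all-points PR interpolation at IoU 0.5) and its means over
base (bAP), novel (nAP) and all classes (mAP).

All neural components — the frozen convolutional FPN backbone, RPN-lite,
RoI heads, attention module and projection head — are implemented in
numpy with analytic gradients, checked against finite differences in the
test suite.

## Worked example

```python
import numpy as np
from pestfsod import (SceneSpec, generate_dataset, split_train_test,
                      ModelConfig, TrainConfig, train_base, finetune,
                      evaluate_checkpoint)
from pestfsod.episodes import make_split, sample_kshot, ShotConfig

spec = SceneSpec(image_size=(96, 96), n_classes=6, size_range_px=(12, 36))
rng = np.random.default_rng(0)
data = generate_dataset(spec, {c: 20 for c in range(6)}, None, rng)
train, test = split_train_test(data, 0.8, rng)
split = make_split(list(range(6)), n_base=4, seed=0)

cfg = TrainConfig(iters_base=300, iters_finetune=150, eval_interval=100,
                  lr_finetune=0.01, seed=0)
base = train_base(train, split.base_classes, ModelConfig(), cfg)
support = sample_kshot(train, split, K=10, seed=0)
model = finetune(base, support, split, ShotConfig(K=10), cfg)
report = evaluate_checkpoint(model, test, split)
print(f"bAP50={report.bAP:.3f} nAP50={report.nAP:.3f} mAP50={report.mAP:.3f}")
```

prints (about a minute on one CPU):

```
bAP50=0.917 nAP50=0.791 mAP50=0.875
```

i.e. after seeing only 10 images of each novel class, the fine-tuned
detector finds novel-class pests at nAP50 ≈ 0.79 while keeping base-class
accuracy. The published per-class AP table of the PestDet20 benchmark
ships as package data, and its printed aggregate rows are reproduced by
the same `split_map` arithmetic the evaluator uses:

```python
from pestfsod import published_ap_table, split_map
from pestfsod.episodes import packaged_split
df = published_ap_table()
sub = df[(df.method == "OURS") & (df.shot == 10)]
bap, nap, m = split_map(dict(zip(sub.class_id, sub.ap)), packaged_split(3))
print(f"OURS 10-shot: base {bap:.1f}  new {nap:.1f}  all {m:.1f}")
# OURS 10-shot: base 83.8  new 79.2  all 82.6
```

The `pestfsod` console script exposes the same pipeline from a shell
(`synth`, `split`, `train-base`, `finetune`, `eval`, `predict`,
`run-experiment`, `report`); `run-experiment` loops shots × seeds and
summarises mAP with t-based confidence intervals.

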