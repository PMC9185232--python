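# nucleiguide

Nuclei-guided two-branch attention network for grading H&E pathology
tiles, with a seeded synthetic-histology generator so the entire
pipeline — training, ablation, metrics and Grad-CAM explanation — runs in
minutes on one CPU.

Tumour grade is largely a statement about nuclei: their number, size and
boundary irregularity. A plain CNN trained on tiles is free to attend to
anything; this package implements a network that is *told* where the
nuclei are and rewarded for using them. It is aimed at researchers in
computational pathology who want a compact, fully inspectable testbed for
mask-guided attention: every mechanism is implemented on a small NumPy
autodiff core, checked against independent straight-line references, and
exercised end to end on synthetic data with exact ground truth.

## Model

The network takes two inputs from the same tile: the RGB image `I_main`
and the nuclei-only image `I_nuclei = S ⊙ I_main`, where `S` is a binary
nuclei mask (ground truth, or a classical Otsu/morphology segmenter).
Both pass through VGG-style convolutional branches of identical layout
and independent weights. Two mechanisms couple them:

* **NGA (nuclei-guided attention)** — per stage `m`, guide features
  produce an attention map via a 1×1 convolution and a per-channel
  spatial softmax, which reweights the main features with a residual:
  `F_fuse^m = F_main^m ⊕ (F_main^m ⊗ A^m)`.
* **NGF (nuclei-guided fusion)** — at the deepest stage both maps become
  token sequences and pass through `L = 3` cross-attention layers,
  `V ← V + softmax(Q_nuclei K_main^T / √d_k) V_main`, with queries from
  the guide tokens.

A two-layer MLP head yields grade probabilities; training minimises
categorical cross entropy with RMSProp. Six ablation variants (`full`,
`no_nga`, `no_ngf`, `no_nga_no_ngf`, `image_only`, `nuclei_only`) share
one protocol. Evaluation reports a confusion matrix, one-vs-rest
accuracy/sensitivity/specificity per class and macro, and one-vs-rest
ROC-AUC. See `docs/methods.md` for the full account.

## Worked example

```python
import nucleiguide as ng

# 150 synthetic 64 px tiles whose grade is encoded purely in nuclear
# count/size/irregularity, buried under nucleus-like distractor clutter
model = ng.NucleiGuidedGradingModel.from_synthetic(
    ng.SynthConfig.distractor_task(seed=7, n_per_grade=50)
)
res = model.fit(ng.TrainConfig.desk(epochs=15, batch_size=32,
                                    clip_norm=0.5, seed=1))
print(res.summary())
```

```
Nuclei-Guided Grading Network Results
==============================================
variant:           full
stages / fusion L: 3 / 3
channels:          (8, 16, 32)
parameters:        150939
train / test n:    120 / 30
epochs:            15  (final loss 0.1467)
----------------------------------------------
test accuracy:     0.900
macro sensitivity: 0.900
macro specificity: 0.950
mean OvR AUC:      1.000
confusion (rows true, cols predicted):
[[10  0  0]
 [ 3  7  0]
 [ 0  0 10]]
```

The fit trains on a stratified 80 % split and reports held-out metrics:
27 of 30 test tiles graded correctly, with the errors confusing
neighbouring grades (row 2: three grade-2 tiles predicted grade 1) — the
same failure mode real graders show. `res.grad_cam(i)` returns a [0,1]
heatmap for tile `i` whose mass should sit on nuclei;
`ng.run_ablation(...)` trains all six variants under one seed and emits a
machine-readable table.

The same pipeline is scriptable from the shell:

```sh
nucleiguide generate --out data/ --n-per-grade 50 --seed 7
nucleiguide train    --data data/ --out fit --epochs 15 --seed 1
nucleiguide ablate   --data data/ --out ablation.json
nucleiguide explain  --data data/ --model fit --index 0 --out maps/
```

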