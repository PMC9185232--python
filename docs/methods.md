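# Methods

## Problem and model

`nucleiguide` grades H&E-stained tumour tiles into three classes with a
two-branch convolutional network in which nuclear morphology explicitly
steers the classifier. Histological grade is driven largely by nuclear
features — how many nuclei there are, how large they are, and how
irregular their boundaries look — yet a plain CNN is free to attend to
anything in the tile. The network therefore takes two inputs derived from
the same tile:

* `I_main` — the RGB tile itself;
* `I_nuclei = S ⊙ I_main` — the tile with everything outside the binary
  nuclei mask `S` zeroed (elementwise product per channel).

Both inputs pass through VGG-style branches of identical layout but
independent parameters: per stage, `convs_per_stage` 3×3 same-convolutions
with ReLU, then 2×2 max pooling. Two mechanisms couple the branches.

**Per-stage attention gating (NGA).** At the end of stage `m` the guide
features pass through a channel-preserving 1×1 convolution and a softmax
taken over spatial positions independently per channel, giving an
attention map `A^m ∈ (0,1)` whose per-channel mass sums to 1. The main
features are reweighted and added back:

    A^m      = softmax(conv1×1(F_nuclei^m))
    F_guide^m = F_main^m ⊙ A^m
    F_fuse^m  = F_main^m ⊕ F_guide^m

The softmax axis is configurable (`spatial` default, `channel`
alternative); spatial normalisation matches the mechanism's purpose of
*locating* nuclei.

**Cross-attention fusion (NGF).** At the deepest stage both maps are
flattened to token sequences (one token per spatial position, row-major;
token dimension = channel count). A stack of `L = 3` single-head
cross-attention layers follows, with queries projected from the fixed
guide tokens, keys projected from the running main sequence, and the
running sequence itself as values, plus a residual:

    V^{l+1} = V^l + Att(Q_guide W_Q^l, V^l W_K^l, V^l),
    Att(Q, K, V) = softmax(QK^T / √d_k) V.

`V` is the only quantity updated across layers; `W_Q^l, W_K^l` are learned
square projections and `V` enters unprojected so the residual is
well-typed. There is no positional encoding: token identity is positional
by construction, and the stack is equivariant to consistent permutations
of both sequences. All softmaxes are computed with max-subtraction and are
stable for arbitrarily extreme logits.

The fused sequence is flattened and a two-layer MLP produces class
logits; training minimises batch-mean categorical cross entropy with
probabilities clipped to `[1e-7, 1]` before the log.

**Ablation variants.** `full`, `no_nga`, `no_ngf`, `no_nga_no_ngf`,
`image_only`, `nuclei_only`. Without NGF, fusion is token-wise
concatenation of the two sequences ("simple fusion"); the single-branch
variants are the plain VGG-style classifier on one input. All variants
share output dimensionality and the training protocol.

## Mask sources

Training defaults to ground-truth masks (from the generator or the
dataset manifest). A classical segmenter is provided for images without
annotations: grayscale mean → Otsu threshold (dark side) → binary opening
(disk 1) → removal of components smaller than `min_area` px (default
20) → one dilation. The final dilation deliberately over-segments
slightly, including the nuclear rim, which is more useful to the guide
branch than a tight contour. Masks persist as {0,255} 8-bit PNG and load
by thresholding at 128. Masks are strictly binary; soft probability maps
are not supported.

## Synthetic data generator

The generator renders 64 px RGB tiles that emulate a graded tile
collection at desk scale: dark hematoxylin-like nuclei (base RGB
0.36/0.22/0.54 with per-nucleus shade jitter) on an eosin-pink background
(0.91/0.76/0.84) with Gaussian texture noise (sd 0.05 default). Nuclei are
ellipses (minor/major ratio 0.75–1.0) with a sinusoidal radial
perturbation; the perturbation amplitude is the model of nuclear atypia.
Grade `g ∈ {1,2,3}` sets three quantities from disjoint ranges, so the
label is recoverable from the realized parameters by binning any one of
them:

| grade | count | radius (px) | irregularity |
|-------|-------|-------------|--------------|
| 1     | 2–3   | 2.6–3.2     | 0.00–0.06    |
| 2     | 4–6   | 3.6–4.2     | 0.12–0.20    |
| 3     | 7–9   | 4.6–5.2     | 0.28–0.38    |

Placement must be non-overlapping so that the mask's 8-connected
components equal the nucleus count. Uniform rejection sampling jams below
the requested count at grade-3 density, so centers are drawn on a
jittered grid: candidate positions are random cells of a
`⌈√count⌉ × ⌈√count⌉` grid plus a jitter that anneals to zero across
rejection rounds, with every candidate checked against the pairwise
minimum distance (sum of maximal boundary radii + 2 px moat). At zero
jitter the plain grid satisfies the constraint for the default
morphology, so generation cannot fail there; infeasible custom configs
raise a placement-overflow error carrying the achieved count.

Each sample is keyed by `(dataset seed, grade, index)` through NumPy
`SeedSequence` spawn keys, so samples are order-independent and datasets
are bit-reproducible; images are quantized to the 8-bit grid at render
time so PNG round trips are exact.

**The distractor task** (`SynthConfig.distractor_task`) is the evaluation
condition for the guidance mechanisms: background texture sd 0.15 plus
4–10 nucleus-like elliptical distractor blobs per tile (RGB
0.52/0.36/0.50, radius 2–4 px), drawn beneath the nuclei, never in the
mask, and with grade-independent statistics. The grade signal lives only
in nuclear morphology; the clutter gives an unguided classifier something
to be wrong about.

**What the generator does not model:** tubule/gland topology, mitotic
figures, stain deconvolution, overlapping nuclei, and scanner artefacts.
Passing tests show the mechanisms work when the label is genuinely
nuclear; they do not certify performance on real H&E tiles, where grade
also depends on tubule formation and mitoses.

## Optimisation

The reference protocol is RMSProp (ρ = 0.9, ε = 1e-7), learning rate
2e-5, 300 epochs, stratified 80/20 train/test split — kept as
`TrainConfig`'s defaults. Desk-scale runs use `TrainConfig.desk()`:
learning rate 1e-3 (the common Keras default for RMSProp; 2e-5 over tens
of epochs barely moves a freshly initialised tiny network) and global
gradient-norm clipping at 0.5. Clipping matters: the residual fusion
stack roughly doubles token magnitude per layer (a single token through
L = 3 layers comes out exactly 8×), and unclipped RMSProp steps
periodically spike and knock a converged model off its solution.

Initialisation: He-normal convolutions; attention projections uniform
`±0.05/√d` so pre-softmax logits start O(1); the MLP's first layer is
He-normal divided by `2^L` for NGF variants to compensate the stack's
amplification; the output layer starts near zero so the first loss sits
at ~ln 3. Inputs are rescaled from [0,1] to [−1,1] at the network
boundary — uncentred inputs make deep-stage activation scale strongly
seed-dependent. Batch shuffling derives from the training seed; with a
single thread, training is bit-reproducible.

Network defaults are desk-scale: three stages of 8/16/32 channels, one
convolution per stage, 64 px inputs (8×8 = 64 tokens of dimension 32),
hidden width 64. `ModelConfig.paper_like()` gives the five-stage
VGG16-width layout. One NGA gate sits at the end of every stage.

## Evaluation

Per-class metrics come from the one-vs-rest collapse of the
row-true/column-predicted confusion matrix: sensitivity TP/(TP+FN),
specificity TN/(TN+FP), per-class accuracy (TP+TN)/n. Macro values are
unweighted means over classes present in the test set; absent classes
are reported as NaN and logged, never averaged. AUC is the rank-based
(midrank-tied) one-vs-rest area per class, with the mean AUC their
unweighted mean. The ablation harness trains all six variants under one
split and one seed so rows differ only by architecture.

## Grad-CAM

Explanations hook the post-NGA fused feature map of a chosen stage
(default: the deepest). Channel weights are the spatial mean of the
target-class logit's gradient with respect to that map; the map is the
ReLU of the weighted channel sum, bilinearly upsampled to input size and
max-normalised (identically zero when nothing contributes positively).
The default target is the predicted class. The overlay artefact uses a
fixed jet palette at α = 0.4.

## Test and experiment scales

The suites run on one CPU: oracle-equivalence tests at ≤4 channels/
tokens (100 randomized instances per mechanism, tolerance 1e-6, verified
against loop-based references); the overfit sanity run on 30 noiseless
samples for 20 epochs; the guidance ablation on the distractor task with
n = 300 tiles, three seeds, 15 epochs, comparing the median test accuracy
of `full` against `image_only` and `no_nga_no_ngf`; Grad-CAM nucleus
focus on the 60 held-out tiles of that task. `scripts/acceptance.py`
re-runs the same pipeline under a caller-supplied seed.

## Numerical and engineering choices

The package carries its own minimal reverse-mode autodiff on NumPy
(`nucleiguide.autodiff`): broadcasting arithmetic, batched matmul, 3×3
same-convolution via im2col, 2×2 max pooling (tie gradients split
evenly), fused-backward softmax, reductions and reshapes. Gradients
accumulate on every node, so intermediate feature maps can be read after
`backward()` — which is exactly what Grad-CAM does. All arithmetic is
float64; every operator is verified against central finite differences.

Known limitations: no GPU path, so paper-scale configurations train
slowly; the fusion stack's magnitude growth makes depths L ≫ 3
numerically awkward without normalisation layers (deliberately not
added); the generator's grade cues are redundant (count, size and shape
all move together), which makes the synthetic task easier than real
grading; the full variant's optimisation is noticeably less stable than
its ablations at desk scale — the gradient-clipped protocol above is the
configuration under which the documented results hold.
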