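# Methods

`wavedet` implements an end-to-end set-prediction detector for grayscale
radiographs with two distinguishing components: a **wavelet-transform
projection** (WTP) neck between the CNN backbone and the transformer
encoder, and a **hierarchical hybrid matching** (HHM) training criterion
that matches each prediction layer against a duplicated copy of the ground
truth. This note records the model, the choices made where the design was
genuinely open, and what the synthetic experiments do and do not show.

## Architecture

An input image `I ∈ R^{3×H×W}` (grayscale, channel-replicated) passes
through a strided CNN backbone producing a four-scale pyramid
`{F_0..F_3}` at strides 4/8/16/32. The reference contract uses channels
(256, 512, 1024, 2048); tests and the smoke study use a narrower 4-stage
stand-in with the same stride/channel *structure*. Each scale is projected
to 256 channels by a 1×1 convolution and passed through the WTP block, then
flattened; the concatenated tokens (with sinusoidal 2-D positional
encodings plus a learned per-level embedding) feed `N` deformable
self-attention encoder blocks. An encoder detection head scores every
token; boxes are predicted as offsets, in inverse-sigmoid (logit) space,
from a uniform anchor grid (one anchor per token at its spatial center,
base size `0.05·2^level`). The top-`K` (default 300) proposals by maximum
class confidence seed the decoder queries. Each of `M` decoder layers runs
dense self-attention, deformable cross-attention into the encoder memory
(reference point = the sigmoid of the current box center), and an FFN;
`M+1` unshared detection heads (a 3-layer MLP for the four box offsets and
a linear layer for class logits) serve the encoder and each decoder layer.

Box refinement follows the *look-forward-twice* gradient contract: the
boxes layer `i` reports are built from the **undetached** refinement of
layer `i-1`, while the box passed onward is detached. A box loss at layer
`i` therefore updates refinement parameters of layers `i` and `i-1` only —
verified by an autodiff probe in the test suite.

Inference keeps the final layer's `K` candidates, thresholds at a class
probability of 0.3, and never applies NMS.

## Wavelet transform projection

The 2×2 orthonormal Haar bank (entries ±1/2; LL average, LH horizontal
high-pass, HL vertical high-pass, HH diagonal) decomposes a feature map by
stride-2 **depthwise** cross-correlation into four half-resolution
subbands. Each subband passes through its own depthwise kernel-5 learnable
convolution; a separately parameterized synthesis bank (stride-2 depthwise
transposed convolution, summed over bands) maps back to full resolution.
The block output is the residual fusion

    F' = F_conv(F) + IWT(F'_conv(WT(F)))

with `F_conv` a depthwise kernel-5 convolution on the identity path. For
`levels > 1` the transform recurses on the (already convolved) LL band and
the deeper level's output replaces that band before each synthesis step.
All learnable convolutions initialize at unit impulses, so an untrained
block computes exactly `2F`; both banks initialize at the Haar filters, and
four trainability modes (NO / WT / IWT / ALL) select which banks receive
gradients. The default, IWT, freezes analysis and trains synthesis.

Open points resolved as package decisions:

* **Depthwise everywhere.** Per-channel filters are the only reading
  consistent with a projection that *reduces* parameters relative to a
  dense 3×3 block and with the wavelet-convolution lineage the design
  follows.
* **Linear band convolutions.** The residual formula shows a pure sum, so
  no nonlinearity is inserted inside the block; the composed network
  supplies nonlinearity elsewhere.
* **Per-scale, per-level weights.** Each pyramid scale owns its WTP weights
  (a config flag can share them); each level owns its bank and band
  convolutions.
* **Odd spatial dims** are edge-replicated up to the next multiple of
  `2^levels` before analysis and cropped after synthesis.
* The convolution convention is cross-correlation; the worked 2×2 example
  in the tests pins the LH/HL sign convention.

## Hierarchical hybrid matching

With `p_i` the predictions of layer `i` (index 0 = encoder head) and `g`
the targets, training minimizes

    L = Σ_{i=0}^{M-1} (1/w_i) · L_Hungarian(p_i, copy(g, w_i))
        + L_Hungarian(p_M, g)

where `copy(g, w)` tiles the target list `w` times and the reference
schedule is `w = [12, 10, 8, 6, 4, 2]`. `L_Hungarian` combines a
sigmoid-focal classification term (α = 0.25, γ = 2), an L1 box term and a
GIoU term with weights (2, 5, 2) — the set-prediction lineage convention,
since the criterion's classification form is otherwise unspecified.
Assignment minimizes the analogous focal/L1/GIoU pairwise cost with the
Hungarian algorithm (`scipy.optimize.linear_sum_assignment`).

**Normalization.** Per-layer losses are normalized by the *original*
target count `G`, not the duplicated `w·G`. Only this choice gives the
intended semantics of the `1/w_i` weight: the sum over `w·G` matched pairs
grows linearly in `w`, and `1/w` cancels it exactly, so on a separable
instance where every copy attracts an equally good query a `w=2` layer and
a `w=4` layer contribute identically, and an all-ones schedule reduces to
the plain per-layer auxiliary sum. (Normalizing by `w·G` would instead
silently down-weight shallow layers by `1/w` twice.) Images with no
targets contribute the background classification term only.

The encoder head shares the decoder layers' cost weights. Denoising-query
training is deliberately out of scope.

## Training and evaluation

The reference recipe (AdamW, lr 1e-4, backbone lr 1e-5, decay ×0.1 at
epochs 10 and 30, weight decay 1e-4, dropout 0, batch 2, 50 epochs) is
stored as the default config; desk-scale runs override it freely.

Metrics follow the COCO protocol: greedy score-descending matching per
class and image (each ground truth consumed once), 101-point interpolated
AP, mAP50 and mAP50-95 (IoU 0.50–0.95 in 0.05 steps), macro averaging over
classes; classes with zero ground truth in a split are excluded from macro
means. AP and AUC are computed over the **full** candidate list; the 0.3
confidence threshold defines the precision/recall/F1 operating point only.
Detection AUC is not a standard notion: here each class's detections,
labeled TP/FP at IoU 0.5 across the full score range, form a binary
ranking problem scored by the Mann-Whitney rank statistic. This reading is
a package convention; treat cross-paper AUC comparisons with care.
Cohen's d with the unbiased pooled SD, and labels small/medium/large at
0.3/0.5/0.8, are provided for comparing repeated runs.

The robustness protocol re-initializes a trained model by adding
elementwise Gaussian noise with sd equal to 5% of each parameter's
magnitude (seeded, frozen buffers exempt — in particular the fixed Haar
analysis filters).

A patient-leakage audit computes, over max-pooled backbone features, the
fraction of images whose cosine-nearest neighbor shares their patient
(group) id, excluding self-similarity.

## Synthetic fixtures

The generator emulates the statistics this detector family is trained on,
at desk scale: 16-bit grayscale images, a dark noisy background
(level 0.10, Gaussian noise sd 0.02), bright anti-aliased shapes (bars,
ellipses, rings, striped "text" blocks) with intensities 0.65–0.95, tight
boxes recorded from each shape's half-intensity support, optional strongly
overlapping same-class pairs, and a group (synthetic patient) id over
images. The imbalance preset mirrors the reference dataset's class
distribution: two dominant classes at 50.00% and 38.13% of instances, the
remaining seven sharing the rest equally. The easy preset (two classes,
bars vs ellipses, 1–2 objects of 16–28 px on 64×64 images) defines the
smoke-training task: 200 training and 50 test images.

What passing the synthetic studies shows: the wavelet algebra is exact,
the criterion and matcher have the specified structure, gradients flow per
contract, and the full pipeline — backbone through decoder through loss —
can be trained end-to-end to high accuracy on a separable task. What it
does not show: performance on real radiographs, robustness to anatomy,
projection and exposure variation, or any clinical claim; the reported
full-scale numbers require the 20k-image public wrist dataset and GPU
training, both outside this package's test scope.

## Numerical choices and limitations

* All tensors are float32; the autodiff engine (`wavedet.autograd`) is a
  compact reverse-mode tape over numpy written for this package, with
  hand-written adjoints for convolution (strided-view einsum) and the
  fused deformable-sampling kernel, each verified against central finite
  differences. It targets CPU; there is no GPU path.
* Perfect-reconstruction and energy checks use tolerances 1e-5 / 1e-4
  (single-precision accumulation).
* Assignment ties are resolved arbitrarily; tests assert optimal total
  cost, never specific pairs.
* The desk-scale smoke study uses a tiny configuration (2 encoder and 2
  decoder layers, hidden 64, 8 heads, 2 sampling points per head and
  level, K = 20 queries, duplication schedule [4, 2], AdamW lr 2e-3 with
  backbone lr 2e-4, batch 20, up to 60 epochs with early stop once the
  target quality is comfortably exceeded) chosen so the full study —
  training plus both ablations — completes in minutes on one CPU core.
* Sampling locations outside a feature map contribute zero (zero-padded
  bilinear sampling); gradients at the clamped border are approximate.
* `predict` emits at most K candidates and never applies NMS; duplicate
  suppression is learned, so an undertrained model can emit near-duplicate
  boxes.
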