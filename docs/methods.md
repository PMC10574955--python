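# Methods

## Problem and approach

Single-leaf photographs taken in natural settings mix one target leaf with a
large, cluttered background; long petioles and bar-shaped blades additionally
defeat models whose receptive field or pooling geometry is tuned to compact
blobs. `leafseg` implements a two-stage answer. Stage one is any detector
that returns leaf bounding boxes (the package defines only the interface and
readers for YOLO-format detections, plus a ground-truth-box oracle for
experiments). Stage two crops each detection with a padding margin, segments
the crop with an encoder–decoder network, and pastes the predicted mask back
into the full frame. Cropping first means the segmentation model spends its
capacity on leaf-vs-leaf-boundary decisions, not on background suppression.

## Segmentation network

The encoder head combines two mechanisms aimed at long-range and
thin-structure context:

**DenseASPP.** A cascade of atrous convolution layers with strictly
increasing dilation rates; layer *l* convolves the channel-concatenation of
the backbone feature map and all earlier layer outputs, and the module output
concatenates everything, giving C + n·mid_channels channels. A single K-tap
atrous layer has receptive field R(K, d) = (K−1)d + 1; a parallel pyramid
tops out at max_d R(K, d) while the dense cascade reaches
Σ_d R(K, d) − (n−1). Both numbers are exposed (`aspp_rf`, `denseaspp_rf`)
and verified in the tests against an empirical gradient-support oracle: the
set of input positions receiving nonzero gradient from one output position
of a 1-D cascade has exactly the predicted width.

**Strip pooling.** Row and column means of the high-level feature map are
expanded along the pooled axis by kernel-3 1-D convolutions, broadcast,
summed positionwise, passed through a 1×1 convolution and a sigmoid, and
multiplied elementwise onto the input. The H×1 / 1×W pooling windows make
the gate sensitive to structures that span an entire row or column — bar
leaves and petioles — at a cost of two 1-D convolutions. The gate is
contractive (|output| ≤ |input|) and preserves zeros.

A plain parallel ASPP head is retained behind `head="aspp"`, and the strip
pooling gate behind `use_sp`, so the four-way ablation
{ASPP, DenseASPP, SP, DenseASPP+SP} builds from one config. One divergence
from the usual presentation of the parallel baseline: its branch outputs are
fused by concatenation + 1×1 projection (the standard DeepLabv3+ form)
rather than elementwise summation. A second: batch normalization is omitted
on the global-pooling branch, where batch statistics over a single spatial
position are degenerate and would zero that branch's gradients.

### Defaults and parameters

| parameter | default | why |
|---|---|---|
| DenseASPP rates | (3, 6, 12, 18) | small bottom rate preserves local detail; the (6, 12, 18, 24) schedule used in the receptive-field worked example is equally valid via `DenseASPPConfig` |
| mid_channels | 64 | per-layer output width; cascade input widths grow as C + l·64 |
| SP placement | before the pyramid | gating the raw high-level features; `sp_position="after"` gates the fused features instead |
| backbone | `tiny` (4 stages, widths 16/24/32/48, output stride 16) | CPU-scale; any backbone exposing a stride-4 and a stride-16 tap can be registered in `BACKBONES` |
| decoder | bilinear ×4, low-level projected to 48 ch, two 3×3 refine convs | DeepLabv3+ decoder convention |
| crop padding `pad_frac` | 0.1 | detection boxes are tight; a margin keeps blade edges inside the crop |
| letterboxing | aspect-preserving, top-left anchored | square resizing would distort slender petioles |

Training uses mean pixelwise cross-entropy, SGD with momentum 0.9, weight
decay 1e-4, initial learning rate 0.01, batch size 8, 200 epochs (the
`TrainConfig` defaults), under a polynomial learning-rate decay of power
0.9. The pasted region's classes come from the segmentation argmax, not the
detector's class label, so the segmentation stage carries classification
end-to-end.

## Numerical engine

All layers run on `leafseg.nn`, a compact reverse-mode autodiff engine on
float32 numpy arrays: dilated/strided convolution (per-tap tensordot with an
exactly symmetric backward), batch normalization, bilinear resizing
(half-pixel convention), channel concatenation, axis means, sigmoid/ReLU
gates and softmax cross-entropy, plus SGD with momentum. Single-threaded
numpy makes every forward, backward and training trace bit-reproducible for
a fixed seed. Gradients of every operation are checked against central
finite differences in the test suite, with tolerances sized to the float32
noise floor.

## Synthetic data

The generator emulates the photograph types the method targets: one blade
(rounded superellipse with seeded radial perturbation, lobed variant, or a
bar/strip with aspect ratio ≥ 6), a slender petiole 1–3 px wide hanging from
the blade, optional dark lesions (density per 1000 px² of foreground) and
withering (color interpolated toward brown), over a background of smoothed
noise and non-green distractor ellipses (any distractor that would cover
≥ 30% of the leaf is skipped). Each species has a deterministic base color
inside a fixed green hue band, placed on a low-discrepancy sequence — the
cue by which the segmentation stage can classify species. Masks, tight
boxes and YOLO labels are emitted in the package's standard formats, split
8:1:1 with per-species stratification.

What this does and does not show: passing tests demonstrate mechanism
correctness — geometry of crop/paste, learnability, the two-stage advantage
under background clutter — not photorealistic performance. Withering
deliberately erodes the inter-species color cue, so species confusion on
withered leaves persists in held-out evaluation; real leaves carry richer
cues (venation, margin shape) that the procedural shapes omit. Absolute
mIoU values on synthetic data therefore say nothing about any real dataset.

## Metrics

Segmentation metrics pool one global confusion matrix over the evaluated
images (robust to images whose leaf covers few pixels) and report mean IoU
and mean per-class pixel accuracy over the N+1 classes including background;
classes absent from both prediction and ground truth are excluded from the
means (0/0). Per-class pixel accuracy is (TP + TN)/total — the printed form
of the method this package realizes, which counts true negatives — with the
recall-style TP/(TP + FN) available via `include_tn=False`. Detection AP
uses greedy confidence-descending matching (one match per ground-truth box,
IoU threshold 0.5 by default) and all-points interpolation; mAP averages
over species and optionally over the 0.50:0.05:0.95 threshold grid.

## Problem sizes

The shipped experiments are sized for a single CPU: 64×64 images, the tiny
backbone, 200 optimization steps. The mechanism checks are (a) overfitting
8 training images to mIoU ≥ 0.90, and (b) a paired comparison on 50
synthetic samples showing two-stage inference with ground-truth boxes beats
single-stage full-image inference with the same crop-trained weights — the
direction, not the magnitude, of the improvement the two-stage design
claims. Typical runs give ~0.95 overfit mIoU and a two-stage gain of
+0.15–0.30 mIoU.

## Known limitations

* The detector itself is out of scope; stage one is an interface.
* One leaf per image; overlapping placements resolve by confidence order,
  but multi-leaf scenes are untested territory.
* BatchNorm uses batch statistics; very small batches at evaluation scale
  rely on the running estimates accumulated during training.
* The numpy engine is CPU-bound and desk-scale by design; it is not a
  training framework for the full-resolution problem.
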