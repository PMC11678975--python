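# Methods

This note records the models, conventions and experimental conditions the
package implements, and the design choices made where more than one
reasonable option existed.

## Box losses

All geometry is continuous (no pixel quantization) in center format; corner
conversion is exact arithmetic. Guards: ε = 1e-9 is added to the union and
to the enclosing-box diagonal c² before division, and IoU is defined as 0
whenever the union is ≤ ε (degenerate boxes are therefore valid inputs with
IoU 0 against everything). The α weight of the aspect term is computed as
υ / max((1 − IoU) + υ, ε), which makes α = 0 exactly when υ = 0, including
the 0/0 corner at IoU = 1.

Inner (auxiliary) boxes share their parent's center with width and height
scaled by `ratio`; their raw intersection can be negative for disjoint
auxiliary boxes and is clamped at zero, as an area must be. In AICI the
center-distance term ρ²/c² is always computed on the **original** boxes
(the auxiliary scaling cancels out of a relative distance, and using the
originals keeps the reduction to CIoU exact); α is computed from the
inner IoU by default, for consistency with the replaced IoU term — a switch
(`alpha_from_inner=False`) uses plain IoU instead. ψ acts as a
multiplicative weight on αυ, mirroring τ on the distance term: the two
parameters regulate the two penalty terms symmetrically.

ψ and τ must stay nonnegative (negative penalty weights would reward
inconsistency). When learnable, they are stored unconstrained and mapped
through softplus; reported values are always the constrained ones.

Subgradients: IoU-family losses are piecewise smooth; `max`/`min` route
their gradient to the first argument on exact ties. Tied configurations are
measure-zero and only matter for finite-difference comparisons in tests.

## Double coordinate attention

Each of the two serial stages pools the H×W×C map along one spatial axis
(mean), applies a 1×1 channel reduction C → ⌈C/r⌉ (default r = 16, clamped
so at least one channel remains), hard-swish, a 1×1 expansion back to C,
and a sigmoid; the input is multiplied by the resulting gates. The first
stage keeps height-position information (pool over width), the second —
applied to the first stage's output with its own independent weights —
keeps width-position information. No batch normalization follows the
reduction: the forward chain is exactly convolution + activation. Gates lie
strictly in (0, 1), so the block can only attenuate, never amplify, and
output shape always equals input shape.

## HEC preprocessing

Histogram equalization maps level k to floor(255 · CDF(k)). The mapping
uses the (L−1) = 255 factor: the printed-L variant would map the top level
to 256, outside 8-bit range; with 255 the mapping is monotone,
255-preserving, and idempotent up to one quantization level. A constant
image maps to constant 255 (its CDF jumps straight to 1).

Canny is implemented from scipy primitives (Gaussian filter restricted to
the configured window, Sobel gradients, direction-quantized non-maximum
suppression, dual-threshold hysteresis via connected components). The NMS
comparison is strict toward the preceding neighbour and non-strict toward
the following one, so a gradient ridge exactly between two pixel columns
thins to a single column — a library implementation that keeps both tied
pixels would report a two-pixel-wide edge on a centered step. σ is derived
from the window size by σ = 0.3·((window−1)/2 − 1) + 0.8 (σ = 1.1 for the
default 5×5 window); thresholds apply to the Sobel gradient magnitude of
the 0–255-scale image.

HEC fuses by **saturating addition** (clip at 255): edge pixels saturate,
non-edge pixels keep their equalized value, so HEC ≥ HE holds pixel-wise.
Enhancement is applied at native resolution, before any resizing. CLAHE is
a comparator only and is delegated to scikit-image (tiles of 1/8 the image
side, normalized clip limit 0.02).

## Metrics

Recall is TP/(TP+FN). Matching is greedy in descending score order;
each detection claims the unmatched same-class ground truth of highest IoU
if that IoU ≥ 0.5. Score ties keep input order; IoU ties go to the lowest
ground-truth index. AP uses all-point (precision-envelope) interpolation,
the convention of modern detection tooling; 11-point interpolation is
available behind a flag. mAP@0.5 averages per-class APs over classes with
at least one ground truth; classes with detections but no ground truth are
excluded and logged. Cross-class matches are never allowed.

## Synthetic angiograms

The generator emulates what matters for these components: dark curvilinear
tubes (cubic-spline centerlines, disk-stamped rasterization, softened by a
1-px Gaussian) of slowly varying half-width on a brighter background with
smooth low-frequency "tissue" blobs and additive Gaussian noise; contrast
polarity matches X-ray angiography. A stenosis is a raised-cosine width dip
to `stenosis_factor` (default 0.45) over an arc of about four vessel
diameters, at most one per vessel; its bounding box covers the deeper half
of the dip, padded by the healthy half-width. Default scene parameters
(640-px frames, half-widths 4–8 px) make stenosis boxes span roughly 3–8%
of the image side — small targets. Per-image seeds in `generate_dataset`
derive deterministically from the base seed, so datasets regenerate
bit-identically.

The phantom deliberately omits projection geometry, motion blur, contrast
washout, branching trees and multi-lesion taxonomies. Passing tests on it
demonstrate that the losses, attention, enhancement and metrics behave as
specified and that the training loop can exploit them — not clinical-grade
detection performance.

## Autodiff engine and micro-detector

Training runs on a small reverse-mode automatic-differentiation engine over
numpy arrays (elementwise ops, matmul, strided conv2d, reductions, and the
clamp/arctan/sigmoid/softplus primitives the losses need) with an Adam
implementation; gradients are verified against central differences in the
test suite. It is sized for desk-scale models and deliberately has no GPU
or threading support.

The micro-detector is a single-scale stride-8 grid detector: three strided
3×3 convolutions (1→16→32→64 channels, hard-swish), one stride-1 3×3
context stage at grid resolution (so a cell's receptive field spans a
stenosis arc plus healthy shoulders), and a 1×1 head emitting, per cell, an
objectness logit plus (dx, dy, log w, log h) offsets relative to the cell
center with base box size 2×stride. Optional DCA blocks sit before the
second and third down-sampling stages (reduction r = 4 at these small
channel counts). The cell containing a ground-truth center is the
objectness positive (binary cross-entropy, positive weight 8); box offsets
are additionally supervised on that cell's 3×3 neighbourhood — adjacent
cells share most of the positive cell's receptive field, so they cannot be
driven to zero objectness, and training their offsets onto the same box
lets NMS (class-wise greedy, threshold 0.45) merge them instead of leaving
high-scoring strays. Inference thresholds objectness at 0.25.

Training uses Adam at learning rate 0.002 with seeded shuffling and seeded
dihedral (flip/transpose) augmentation; with ~200 training scenes the
augmentation is what closes the train/test gap. With the AICI loss, ψ and
τ are trained jointly with the network weights (same optimizer and learning
rate, no weight decay), through the softplus map that keeps them positive.

## Experiment conditions

**Box-fitting study.** Unit-coordinate field; targets span 5–10% of the
field; the initial box is a 0.5–0.8× scaled copy displaced past tangency by
a 10–50%-of-target gap (plain IoU starts exactly at 0). Fixed-step gradient
descent, lr = 2e-4, up to 3000 steps, ψ = τ frozen at their configured
values so the three losses see identical geometry and step sizes.
Convergence is the first step with true IoU ≥ 0.9. The learning rate is the
largest tested value at which descent is monotone away from the optimum;
IoU-family losses have a gradient-magnitude kink (~2/w) at zero error, so
fixed-step descent *always* oscillates terminally — trajectories are
monotone over at least the first 40% of every path at this rate, and the
terminal jitter is a step-size artifact, not a property of the losses.

Measured under these conditions (200 paired trials): inner-CIoU (ratio 1.1)
reaches IoU 0.9 in fewer median steps than CIoU, robust at the 95% paired
bootstrap level. AICI with ψ = τ frozen at 0.5 converges ~30% *slower* in
raw gradient-descent steps than CIoU: its only driving term before contact
is the half-weighted distance penalty, and fixed-step descent — unlike an
adaptive optimizer, which normalizes gradient scale, with ψ, τ free to
adapt — directly feels that scaling. The package reports this honestly; the
frozen-weight fixed-step analogue is informative about loss *shape*, not
about adaptive-training wall-clock.

**Detection experiments.** Scenes are generated at 128 px (half-widths
5–7 px, stenosis factor 0.45, noise σ 5, two vessels) and the detector runs
at 64-px input — sizes chosen so the full suite trains in minutes on one
CPU core. The width band is deliberately narrow enough that a stenosed
segment (≤ 0.45× width) is unambiguously thinner than any healthy segment;
with a wider band the label depends on width *relative to the local
nominal*, which this deliberately tiny detector cannot resolve. The
memorization probe (8 images, 600 steps, mAP@0.5 = 1.0) uses single-vessel
scenes: with two vessels, two stenoses can overlap past the NMS threshold
or share a grid cell, capping recall for reasons unrelated to capacity.
The generalization run (200 train / 40 test, HEC + DCA + AICI, 120 epochs)
clears mAP@0.5 ≈ 0.6–0.75 across seeds — a sanity level for these
conditions, not a clinical claim.

## Known limitations

- The phantom's simplicity means preprocessing/attention ablations here
  cannot rank variants the way clinical data would.
- The numpy autodiff engine is single-threaded; scaling any experiment up
  by ~10× in pixels or epochs leaves the desk-scale envelope.
- Strict monotonicity of fixed-step descent trajectories near convergence
  is mathematically unattainable for kinked IoU losses (see above); tests
  assert monotonicity away from the optimum instead.
- Greedy matching and greedy NMS are the field's standard conventions but
  not globally optimal assignments.
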