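# Methods

## The classification model

The classifier is a capsule network: the feature stack turns an input B-scan
into a grid of *primary capsules* (8-dimensional activity vectors), and a
routed *class-capsule* layer produces one 16-dimensional capsule per disease
class. A capsule's Euclidean length encodes the probability that its entity
is present; the argmax length is the predicted class. The assumptions this
encodes are (i) lesion evidence is local and pose-structured, so it is better
summarised by vectors than by pooled scalars, and (ii) agreement between
low-level predictions and a class capsule is informative, so coupling
coefficients are refined iteratively (routing-by-agreement) rather than
learned as static weights.

Layer-by-layer, the full model is: CLAHE enhancement of the input
(48×48×3), three ReLU convolutions (256 channels each: 5×5 stride 2 →
22×22, 3×3 stride 2 → 10×10, 1×1 stride 1 → 10×10), a second CLAHE layer on
the 10×10 feature maps, a convolutional primary-capsule layer (9×9 stride 3,
same padding → 4×4 spatial positions × 36 capsule types = 576 capsules of
8-D), and the routed class layer (k × 16-D). A three-layer fully connected
decoder (512 → 1024 → 6912, sigmoid output) reconstructs the input from the
class capsules with all but one capsule masked to zero — the true class
during training, the predicted class at inference — acting as a pose
regulariser. The single-convolution baseline (conv 256@9×9 stride 1 →
primary caps 32×8-D@9×9 stride 2, softmax coupling, original squash, no
CLAHE) is retained for ablations.

One printed description of the primary-capsule layer is internally
inconsistent (576 capsules cannot equal 4×4×16); this implementation uses
36 capsule types at 4×4 positions, which is the unique reading consistent
with 576 eight-dimensional capsules and the 10×10 input under a 9×9/stride-3
same-padded convolution.

## Capsule math

* **Squash.** `v = (‖s‖²/(1+‖s‖²))·s/‖s‖` maps any vector to its own
  direction with norm in [0,1), monotone in ‖s‖. The **power squash**
  `v = (‖s‖ⁿ/(1+‖s‖ⁿ))·s/‖s‖` (default exponent n = 3, configurable)
  reduces to the original at n = 2 and, for n > 2, grows more slowly below
  ‖s‖ = 1 — suppressing small activations in the primary-capsule layer.
  The concrete algebraic form was an open choice; this one is the minimal
  power generalisation that preserves the [0,1) range, monotonicity, and
  the n = 2 coincidence. Every norm carries an epsilon of 1e-7 so the zero
  vector maps to (numerically) zero without dividing by zero.
* **Coupling.** Routing logits `b_ij` (zero-initialised per forward pass,
  never learned) become couplings either by softmax over parent capsules
  (each lower capsule's couplings sum to 1) or elementwise sigmoid (each in
  (0,1), not competing across parents). Sigmoid is the default for the
  CLAHE model; the baseline uses softmax.
* **Routing.** r iterations (default 3, the conventional choice) of:
  couple, weighted-sum the prediction vectors `û_j|i = W_ij u_i`, squash,
  and add the agreement `v_j·û_j|i` to the logits. Gradients propagate
  through the final weighted sum; earlier iterations use detached
  predictions (the standard stop-gradient treatment, which keeps the
  backward graph linear in r).
* **Margin loss.** Per class,
  `l_k = T_k max(0, m⁺−‖v_k‖)² + λ(1−T_k) max(0, ‖v_k‖−m⁻)²` with defaults
  m⁺ = 0.9, m⁻ = 0.1, λ = 0.5 (the conventional values; the margins were not
  specified by the source experiments), summed over classes and averaged
  over the batch. The reconstruction term is the per-sample sum of squared
  errors times `recon_weight` (default 5e-4), reconstructing the raw —
  not CLAHE-enhanced — input.

## CLAHE, standalone and in-network

CLAHE partitions the image into a tile grid (default 8×8), histograms each
tile (default 256 bins; bin = nearest of n levels spanning [0,1]), clips
each histogram at `clip_limit` times the uniform height (default 2.0) and
redistributes the excess, forms CDF lookup tables, and blends the ≤4
neighbouring tile LUTs bilinearly at each pixel (edge pixels use the reduced
neighbour set). Images are padded by reflection so tiles partition evenly.
None of these values were prescribed by the source experiments; the defaults
are the conventional ones and all are exposed in `ClaheParams`.

Redistribution is capacity-aware: excess mass is shared uniformly among the
bins still below the clip threshold and iterated until absorbed (only at
clip_limit = 1 can every bin saturate, in which case the remainder spreads
uniformly). This conserves total mass to floating-point precision and makes
the clipped histogram exactly uniform in the fully saturated case. With one
tile and no clipping the operator degenerates to global histogram
equalization, which the tests verify against an independently coded oracle.

As a network layer, CLAHE is parameter-free and applied per channel:
arbitrary-range feature maps are min–max normalised to [0,1], enhanced, and
rescaled to the channel's original range (constant channels pass through).
Because the histogram mapping is piecewise constant, its true Jacobian is
zero almost everywhere; the layer therefore passes gradients through
unchanged (straight-through identity), without which the mid-network layer
would stop all upstream learning. The mid-network layer defaults to a 2×2
grid with 32 bins — an 8×8 grid on a 10×10 map would make tiles degenerate.
Since the input layer is deterministic, the training loop applies it once
per dataset rather than once per step; the result is identical (a tested
equivalence).

The command-line `clahe-apply` uses absolute-intensity CLAHE (full-range
output) rather than the in-network rescale-back policy, which is what one
expects of an image-enhancement tool.

## Training recipe

Adam with first-moment coefficient β₁ = 0.9 (β₂ = 0.999), learning rate
1e-4, batch size 32, 100 epochs, and per-step learning-rate decay
`lr/(1 + 1e-6·t)` — the Keras-style decay matching the published recipe's
"momentum 0.9, descent rate 1e-6" under an Adam optimizer. No data
augmentation. Weight init is fan-in-scaled uniform for conv/dense layers and
N(0, 0.01) for the routing transformation tensors; everything (init, batch
order) is driven by one seed, and two runs with the same seed produce
identical losses. When a validation split is present, per-epoch validation
accuracy is logged and the best-validation weights are restored after
training (the model-selection rule; the source protocol does not state one).

Because no GPU autodiff backend is assumed, the network runs on a compact
numpy reverse-mode engine bundled with the package (`capsoct.autodiff`);
convolution uses im2col with explicit col2im gradients, and every operator's
backward pass is validated against central finite differences.

## Synthetic data

The generator emulates the geometry of retinal OCT B-scans: a bright,
smoothly curved horizontal band (the retinal layer complex, default
intensity 0.75 over a 0.12 background, thickness 28% of image height,
sinusoidal curvature of amplitude 4%) with class-specific lesions — CNV: one
wide dome elevation (height 18% of image height) with a bright sub-band
mass; DME: 1–3 dark elliptical cysts inside the band (darkness 0.55); DRUSEN:
2–5 small bumps (height 10%) extending the band's lower boundary; NORMAL:
the unmodified band. Multiplicative log-normal speckle (σ = 0.15, the noise
regime of coherent imaging) is applied last and the grayscale scene is
replicated to three channels. Defaults render 48×48 images, matching the
network's input contract; sizes are configurable for toy tests.

Every image derives its RNG from (seed, split, class, index), so datasets
are byte-reproducible and individual images are stable when counts change.
The generator reproduces geometry and speckle only — it does not emulate
real scans' intensity statistics, device artefacts, shadowing, or anatomical
variability — so passing tests demonstrate that the pipeline learns and
evaluates correctly on learnably distinct classes, not that the model
reaches any particular accuracy on real OCT data. A linear-probe test keeps
the generator honest in the other direction (classes must be separable from
raw pixels, i.e. not degenerate).

## Evaluation

Confusion matrix (rows true, columns predicted); per-class one-vs-rest
sensitivity SE = TP/(TP+FN), precision PR = TP/(TP+FP), specificity
SP = TN/(TN+FP), and accuracy ACC = (TP+TN)/total; one-vs-rest ROC and
precision–recall curves with AUC by the midrank statistic. Overall metrics:
OA = correct/total, and OS/OP as *unweighted (macro) means* of per-class SE
and PR — the natural reading for a balanced test set; the source tables'
overall columns are not self-consistent, so the definitions used here are
documented rather than reverse-engineered. Because parts of the applied
literature print recall in an "ACC" column, both `acc_ovr` and `se` are
emitted under unambiguous names. Zero-denominator ratios are reported as 0
and flagged; degenerate AUCs (a class with no positives or no negatives)
are reported as null and flagged.

## Problem sizes used by the test suite and acceptance script

The full 256-channel architecture is built and audited (construction is
cheap); training-dependent checks run the `tiny` scale — conv widths
32/32/32, 8 primary-capsule types (128 capsules), decoder 128/256/6912,
identical kernels, strides, routing and losses — on the balanced synthetic
set of 100 train / 25 test / 25 val images per class at 20 epochs, the
package's desk-scale preset for single-core reproducibility. Under those
conditions the median test overall accuracy over three seeds exceeds 0.90.
The comparison (ablation) table is exercised at reduced epoch counts, which
verifies the paired-run protocol and table schema; the full-scale published
accuracies on the real 36k-image dataset are out of scope.

## Known limitations

- The real-data experiments (36,496-image public OCT dataset, GPU-scale
  training) are not reproduced here; synthetic results do not transfer.
- The straight-through CLAHE gradient is a heuristic; it preserves learning
  but is not the true (zero) Jacobian.
- Sigmoid coupling removes the competition constraint among parents; with
  very many lower capsules the summed inputs can be large, which the power
  squash mitigates but does not eliminate.
- The numpy engine is single-threaded except where BLAS parallelises GEMMs;
  full-scale (256-channel) training is impractical without a GPU backend.
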