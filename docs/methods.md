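# Methods

## Problem and approach

`segqa` studies whether the uncertainty of a deep segmentation model can be
used for quality assurance: flagging pixels that are probably segmented
wrongly, and flagging whole scans the model should not be trusted on at all.
The setting mirrors contour QA for pelvic radiotherapy: a four-class 2D
segmentation problem (background, a CTV-like target, a bladder-like and a
rectum-like organ), a model trained on one image distribution, and a second
cohort with different contrast and anatomy on which the model was never
trained.

Uncertainty is estimated with Monte Carlo dropout: dropout stays active at
inference and the input is passed `T` times through the network, giving
per-pixel softmax samples `p_{c,t}` that approximate draws from a Bayesian
posterior predictive distribution. Three quantities are derived per pixel
(all in nats):

- **Predictive entropy (PE)** `H = -Σ_c p̄_c ln p̄_c` with
  `p̄_c = (1/T) Σ_t p_{c,t}` — total (epistemic + aleatoric) uncertainty.
- **Mutual information (MI)** `I = H + (1/T) Σ_{c,t} p_{c,t} ln p_{c,t}`,
  i.e. PE minus the expected per-sample entropy — epistemic uncertainty
  only; exactly zero when the samples agree.
- **Per-class PE** `-p̄_c ln p̄_c`, the class-c summand of PE, bounded above
  by `1/e ≈ 0.368` at `p̄_c = 1/e`. Natural logarithms are used throughout;
  this is what makes the 0.30–0.36 threshold sweep meaningful — the sweep
  deliberately brackets the upper end of the per-class range.

Pixels are stratified per class into TP/TN/FP/FN against ground truth, and a
per-class PE threshold splits them into a *certain* group (PE ≤ threshold)
and an *uncertain* group (strictly above). Each group's Dice is computed
from its TP/FP/FN counts as `2TP/(2TP+FP+FN)`; TN pixels never enter a Dice.
If uncertainty tracks correctness, the certain group's Dice stays high while
the uncertain group's collapses as the threshold rises. For scan-level QA,
the mean MI over all voxels of a scan (no body masking) is a one-number
out-of-distribution score; cohort separation is reported as the best
single-threshold accuracy over an exhaustive threshold scan, with the margin
`min(OOD) − max(ID)`.

## Synthetic data

The clinical MR scans behind this design are not publicly deposited, so the
package generates its own phantoms and treats them as the study conditions:

- 64×64 grayscale slices, 8 slices per scan, 10 scans per cohort. Each scan
  draws per-structure ellipse parameters once (rejected until the three
  structures are pairwise disjoint with a safety margin and each covers
  ≥ 1% of the image) and perturbs them slightly per slice, mimicking
  through-plane coherence.
- In-distribution (ID) intensities (background, CTV, bladder, rectum) =
  (0.20, 0.60, 0.90, 0.40) with additive Gaussian noise σ = 0.05: a bright,
  large bladder, as in T2-weighted pelvic MR.
- The out-of-distribution (OOD) cohort shifts both axes the clinical OOD
  data shifted: contrast — intensities (0.45, 0.65, 0.15, 0.30), inverting
  the bladder/background ordering — and anatomy — bladder semi-axes shrunk
  by about a third (patients follow a drinking schedule; volunteers do not)
  and a wider rectum-size spread. The shift magnitude is exposed as a single
  `ood_shift` factor (1 = the default gap above, 0 = identical to ID).

A model-free ensemble simulator complements the generator so every
downstream stage is testable without training: per-class logits are the
signed Euclidean distance into each class region divided by an *aleatoric*
softening length (clipped to ±10 so entropy concentrates at boundaries), an
*epistemic* zero-mean jitter is added per sample, and a softmax produces the
ensemble. MI is identically zero at zero jitter and increases monotonically
with it; PE is controlled by the softening length.

What the phantoms do **not** emulate: MR physics (bias fields, coil
profiles, partial volume), 3D anatomical continuity beyond slice jitter,
observer variability in the ground truth, and pathological anatomy. Passing
tests therefore show that the uncertainty machinery behaves as designed
under controlled shifts — not that the specific thresholds transfer to
clinical images.

## Network and training

The predictor is a 2D U-Net: two 3×3 convolutions per stage, leaky ReLU
(slope 1e-2), 2×2 max pooling, nearest-neighbour upsampling with skip
concatenation, and a 1×1 softmax head. After **every** convolution in
encoder and decoder sits a spatial concrete-dropout layer: whole feature
channels are dropped through a continuously relaxed Bernoulli mask
`z = σ((logit p + logit u)/t)`, `u ~ U(0,1)`, temperature `t = 0.1`, with
one learnable dropout probability per layer (parameterized through a
sigmoid, so `p ∈ (0,1)` is guaranteed throughout training). The layer's
regularizer `λ_w‖W‖²/(1−p) + λ_d·K·(p ln p + (1−p)ln(1−p))` (defaults
`λ_w = 1e-6`, `λ_d = 1e-5`, `K` = channel count) lets each layer trade
dropout rate against fit. The network and its backpropagation are
implemented directly on NumPy (im2col convolutions; the gradient of every
layer, including the relaxed dropout mask and its probability, is
hand-derived and verified against finite differences in the development
process).

Two configurations are named. The full-scale architecture is 5 levels ×
30 base channels (480-channel bottleneck) with Adam at 1e-4 — the published
design. The desk-scale default, used by all tests and analyses, is
**3 levels × 28 base channels** (112-channel bottleneck) trained with Adam
at 3e-3, constant schedule, keeping the parameter state of the epoch with
the lowest validation loss (a scan-level validation split is always held
out). Three desk-scale choices deserve justification:

- *Wide rather than deep.* Channel-wise dropout in very narrow layers makes
  single Monte Carlo samples lose entire features, which caps the confidence
  of the ensemble mean no matter how well the network fits; keeping ~28
  channels per layer restores the redundancy the method needs. Depth is less
  important here because the phantom classes are separable by intensity and
  coarse position.
- *Class-weighted cross-entropy.* The rectum occupies 1–2% of pixels; at the
  desk scale (200 optimizer steps: 80 slices × 20 epochs / batch 8) plain
  cross-entropy reliably leaves it unlearned. The desk default weights class
  `c` by `1/sqrt(freq_c)` (normalized to mean 1 over pixels); the plain loss
  remains available and is the full-scale default. Stronger
  inverse-frequency weighting over-segments the small structures.
- *Best-validation selection.* With a constant step size and only 200 steps,
  the final epoch can land on a poor optimization step; keeping the
  best-validation-loss epoch within the 20 trained epochs stabilizes the
  model's confidence across training seeds. `selection="final"` restores
  the last-epoch behaviour.

Training uses batch size 8 for 20 epochs with left–right flips (p = 0.5),
a scan-level train/validation split (slices of one scan never straddle the
split), and aborts on non-finite loss. The learned dropout probabilities
settle around a mean of ~0.08–0.09.

## Inference and analysis defaults

`T = 50` stochastic passes (the point where accuracy estimates stabilize);
the mean prediction is binarized by per-pixel argmax with ties broken toward
the lowest class index (background wins an all-way tie — deterministic and
conservative for flagging). The threshold sweep is 0.30–0.36 in steps of
0.01; "above the threshold" is read strictly, so equality stays certain.
Group Dice is reported two ways: per-image with cohort mean ± sd, and from
counts pooled over the cohort (the pooled variant is used for the headline
comparisons; per-image means are noisy when a group nearly empties). A group
with `2TP+FP+FN = 0` reports an undefined Dice (NaN), never 0 or 1.

Surface metrics: HD95 is the 95th percentile (linear interpolation) of the
pooled symmetric set of nearest-boundary distances, MSD its mean; the
boundary of a mask is its pixels with at least one non-mask 4-neighbour
(image-edge pixels count). Pixel spacing enters as physical coordinates, so
both metrics scale linearly with anisotropic spacing.

Numerical conventions: `0·ln 0 := 0` by masked evaluation (no epsilon), MI
clipped at zero from below with any excursion beyond −1e-9 treated as an
error, ensembles validated to sum to 1 per pixel within 1e-5, and identical
samples short-circuited to an exactly zero MI map.

## Known limitations

- Desk-scale findings are qualitative analogues: at 64² the structure
  boundary band is a far larger pixel fraction than at clinical resolution,
  which depresses the fraction of "confident correct" pixels relative to a
  full-scale study.
- The OOD score uses an unmasked global mean; scans dominated by empty
  background dilute it (a masked variant exists behind a flag).
- One OOD mechanism (contrast inversion + shape shift) is tested; nothing is
  claimed for other shift types.
- Nearest-neighbour upsampling can produce 2×2-blocky uncertainty textures;
  this does not affect the pooled statistics.
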