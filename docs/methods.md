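# Methods

## The model

The detector treats AMD screening as novelty detection in a learned
feature space.  Two components:

1. **Embedding.** A CNN backbone maps a B-scan to a raw descriptor
   f(x) ∈ ℝᵈ, which an L2-Norm + Scale head projects onto the sphere of
   radius α: z = α · f(x)/‖f(x)‖₂.  During training a final affine layer
   (weights W ∈ ℝ^{d×C}, biases b) produces logits and the loss is the
   softmax cross-entropy of z — the "L2-constrained softmax".  With the
   norm fixed, the only way to reduce the loss is to rotate same-class
   features together and different-class features apart, so the angular
   geometry, not the norm, carries the class information.  At inference
   the affine layer is never applied.

2. **LOF scorer.** Normal training features form the reference set.  A
   query's local reachability density (lrd) is the inverse mean
   reachability distance to its k-distance neighborhood (ties included,
   so |N_k| ≥ k); its LOF is the mean ratio of its neighbors' lrd to its
   own.  Queries are scored in *novelty mode*: they never join the
   reference set, so batch results are order-independent.  *Fit mode*
   (leave-self-out scoring of the reference points themselves) exists for
   threshold calibration and for the symmetry diagnostics.

### Assumptions

- Normal anatomy is dense and relatively homogeneous in embedding space;
  pathology is sparse or absent there.  LOF needs the first, not the
  second — the classifier head may have seen AMD, but the scorer never
  does.
- Euclidean distance on the α-sphere is a faithful dissimilarity.  Since
  all features share one norm, Euclidean and cosine distances induce the
  same neighbor ranking (a property test); cosine is available as a
  config option.

## Parameters

| parameter | default | meaning |
|---|---|---|
| α (`TrainConfig.alpha`) | 5 | feature-sphere radius; the softmax temperature-like scale |
| M (`batch_size`) | 12 | mini-batch size |
| `learning_rate` | 0.001 | Adam step size |
| `epochs` | 30 | full-scale default; desk-scale runs use 2–8 |
| `input_size` | 224×224×3 | loader contract; grayscale replicated to 3 channels, bilinear resize |
| `train_frac` | 0.8 | stratified, seeded train/validation split |
| k (`LOFParams.k`) | 20 | neighborhood size of the LOF scorer |
| τ (`LOFParams.threshold`) | `"auto"` | decision threshold; `"auto"` = quantile calibration |
| `LOFParams.quantile` | 0.99 | quantile of normal calibration scores used for τ |

The decision threshold is deliberately *not* a fixed constant: τ is the
0.99 quantile of LOF scores of normal calibration features — the
validation split's normals scored in novelty mode against the reference
when at least 5 are available, else the reference set's own fit-mode
scores.  A fixed numeric τ can be supplied instead.  The quantile rule
reads as "call AMD anything less normal than the top 1% of normal
scans", which adapts to however tight the trained embedding happens to
be.

## Backbones

`tiny_cnn` (default) is a dependency-free numpy CNN: channel-averaged
input, average-pool downsampling to ~56 px, two 3×3 conv + ReLU + 2×2
maxpool blocks (8 and 16 channels), and a dense layer to d = 64.  All
layers carry hand-derived reverse-mode gradients (including through the
L2-Norm/Scale head, where the backward pass removes the radial gradient
component) and train with Adam.  The classification layer starts at zero
so the initial loss is exactly ln C — a useful integrity check.  The
backbone trains to >95% validation accuracy on the easy synthetic
conditions within minutes on one CPU.

`resnet50` is registered as the full-scale configuration (2048-d
penultimate features, optionally from generic pretrained weights); it
requires torch/torchvision at runtime and is not exercised by the test
suite.  Whether to initialize it from pretrained weights is left as an
option, since transfer learning is standard for this task but either
initialization is defensible.

## Synthetic study conditions

The generator emulates the morphology that distinguishes the classes in
real B-scans:

- **normal** — n_layers smooth bright bands (Gaussian vertical profile,
  shared tilt and gentle undulation) over a dark background;
- **dry AMD** — raised-cosine bumps (drusen) on the lowest band (the RPE
  surrogate); compact support guarantees the image differs from its
  noise-free normal baseline only inside the recorded lesion intervals;
- **wet AMD** — a raised-cosine dome lifts all bands and the pocket
  between the elevated RPE and its baseline is filled with dark "fluid";
- multiplicative speckle `pixel · (1 + σ·N(0,1))`, clipped to [0, 1].

Defaults (224×224 canvas, 5 bands, contrast 0.55, σ = 0.08, 3 drusen of
amplitude 12 px / width 18 px, fluid dome 40 px deep / 90 px wide, tilt
jitter 6 px) were chosen once to give lesions on the scale seen in real
scans relative to retinal thickness.  The end-to-end evaluation uses the
"easy" condition σ = 0.02 with 600 training / 200 test scans; unit and
property tests use a proportionally scaled 64×64 canvas (4 bands, 9 px
drusen, 15 px fluid) to keep the suite fast.  Per-image RNG streams are
split counter-style from one top-level seed (`SeedSequence(seed,
spawn_key=(class, index))`), so changing one class's count never
perturbs another class's pixels.

What the generator does *not* model: physical OCT speckle statistics
(real speckle is correlated and non-Gaussian), A-scan shadowing, vessel
artifacts, retinal curvature at the fovea, segmentation-hostile
low-quality scans, and non-AMD pathologies such as DME.  Passing the
synthetic recovery tests therefore demonstrates that the pipeline wiring
— embedding, reference construction, calibration, scoring, metrics — is
correct and that the embedding learns morphology rather than leaking
labels; it does not certify clinical performance, which requires the
full public datasets and a full-scale backbone.

## Numerical choices

- **Zero features.** An all-zero raw descriptor has no direction; the
  L2-Norm layer raises a typed error rather than epsilon-fudging, so dead
  backbones surface immediately.
- **LOF ties.** Neighborhoods include every point at distance ≤ the
  k-distance; |N_k| may exceed k under ties and the lrd/LOF denominators
  use the actual neighborhood size.
- **LOF duplicates.** If all reachability distances vanish (a point
  duplicated more than k times), lrd = +∞ with ratio conventions
  ∞/∞ := 1 and finite/∞ := 0.
- **Exact search.** Full pairwise distances, no approximate indices:
  reference sets are small enough, and the 1e-9 oracle-equivalence
  guarantee requires exactness.
- **Metric rounding.** Percentages are reported half-up at 2 decimals and
  AUC at 4, only at the reporting layer; internally per-class metrics are
  exact rationals.  Per-class "accuracy" follows the screening-table
  convention of the class's own recall; the support-weighted recall then
  equals global accuracy for binary problems.  Undefined metrics (zero
  denominators, single-class AUC) are reported absent, never as 0.
- **ROC.** Threshold sweep over unique scores (ties collapse to one
  operating point); trapezoidal AUC, which equals tie-corrected
  Mann-Whitney pair counting.

## Design choices that were genuinely open

- **Which feature feeds LOF:** the post-scale (on-sphere) feature, since
  the constrained loss defines its geometry there.
- **Reference purity:** the reference set is built only from
  NORMAL-labeled images of the training split; the validation split's
  normals serve calibration.  Corrupting the reference with AMD features
  measurably lowers sensitivity (a directional test).
- **Batch robustness:** per-image failures during prediction are
  recorded and skipped rather than aborting the batch, matching a
  screening workflow where one unreadable file must not kill a run.
- **Checkpoint format:** numpy `.npz` of all parameters plus a JSON
  sidecar (architecture, α, feature dim, training config) — native to
  the in-package framework and human-inspectable.

## Known limitations

- `tiny_cnn` is deliberately small; it saturates the synthetic task but
  is not representative of full-scale backbone capacity.
- Threshold calibration assumes enough normal calibration scans for a
  stable 0.99 quantile; with very few normals the fit-mode fallback is
  noisier.
- Only binary screening: the dry/wet distinction exists in the generator
  labels but no sub-classifier is provided.
- LOF cost is O(n·q) distances per batch (n references, q queries);
  fine for tens of thousands of references, unsuitable beyond that
  without indexing.
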