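# Methods

## Model

Each compound contributes one multimodal sample: an RGB molecular
electrostatic potential (MEP) surface image and the 8×8 gray-level
co-occurrence matrix (GLCM) of its reduced density gradient (RDG) diagram,
flattened to a 64-vector. Two branches encode the modalities:

* **CNN branch** (MEP): conv 3×3 → ReLU → 2×2 max-pool, three blocks with
  32/64/128 filters, then global average pooling → 128-d visual feature.
  Convolutions are stride-1 with same-padding; images are bilinearly resized
  to `input_size`² (default 64×64) and scaled to [0, 1].
* **MLP branch** (GLCM): 64 → 64 → 32 dense layers with ReLU → 32-d texture
  feature.
* **Projector**: the concatenated 160-vector passes through 160 → 128 → L
  dense layers (L = 128 by default) into the shared embedding space.

All weights are shared across triplet members (the Siamese assumption: a
single encoder, distances meaningful by construction). Training minimizes the
mean triplet loss `max(0, d(a,p) − d(a,n) + margin)` with Euclidean distance
and margin 1.0, using Adam at learning rate 10⁻³. Similarity is reported as
the inverse distance `d⁻¹ = 1/(1 + d)`, a strictly decreasing bijection from
[0, ∞) onto (0, 1] with unit diagonal by construction.

Triplets are mined statically from the Morgan-2048/radius-2 Tanimoto matrix:
for each anchor, positives are compounds with S_T ≥ `pos_thresh` (0.70),
negatives S_T ≤ `neg_thresh` (0.40), the triplet set being the per-anchor
Cartesian product in deterministic lexicographic order. The hard-triplet
regime (0.13/0.12) serves libraries where no compound is genuinely similar to
the anchor. Compounds strictly between the thresholds are discarded.

## Parameters that matter

| parameter | default | why |
|---|---|---|
| fingerprint size / radius | 2048 bits / 2 | the conventional ECFP4-like setting; chirality flags off by default, configurable |
| GLCM levels | 8 | one 8×8 matrix per diagram; output dimension 64 |
| GLCM offsets | (0,1),(1,0),(1,1),(1,−1), symmetric, normalized | the standard rotation-robust distance-1 set; offsets, symmetry, and background masking are all configurable |
| `input_size` | 64 px | with the in-package numpy backend this trains a 16-compound library in under a minute on one CPU while leaving the CNN three pooling stages of resolution; configurable for larger studies |
| embedding dim L | 128 | comfortable capacity for tens of compounds; distances are not normalized (see below) |
| margin | 1.0 | order-one margin on an unnormalized embedding scale |
| `normalize_embeddings` | off | unit-norm embeddings cap Euclidean distances near 2, which compresses d⁻¹ into [1/3, 1]; unnormalized embeddings let dissimilar pairs reach d⁻¹ well below 0.5, the informative regime for negatives |
| epochs / patience | 20 / 5 | libraries of this size converge within 20 epochs; validation-loss plateau (min-delta 10⁻⁴) stops earlier |
| `val_fraction` | 0.2 | triplet-level holdout; compound-level holdout is a possible stricter alternative for generalization claims |

## Numerical choices

* **Initialization**: He-scaled normal everywhere except the final
  projection layer, which is scaled down by 0.05. A near-zero final layer
  starts all embeddings at the origin, so the first epochs see every triplet
  active (loss ≈ margin) and the geometry is shaped by the loss rather than
  by a random far-flung projection, which can satisfy the margin by accident
  and produce zero gradient from the start.
* **Distance stability**: training-time distances add 10⁻¹² inside the
  square root so the gradient is defined at coincident embeddings; reported
  distances are exact.
* **Max-pool ties** split the gradient equally among tied winners, keeping
  the backward pass exact for the summed objective.
* **Both-empty fingerprints**: Tanimoto is 0/0; defined as 0.0 with a
  warning (no shared substructure evidence).
* **Grad-CAM scalar**: the model is a metric learner, so Grad-CAM is driven
  by −‖embed(sample) − reference‖²; high-attention regions are those pulling
  the sample toward the reference. Target layer is the last conv block's
  ReLU output (the standard choice); the channel-weighted, ReLU-rectified
  map is bilinearly upsampled and min–max normalized to [0, 1]. A map with
  identically zero gradient (e.g. the reference is the sample's own
  embedding) is returned as zeros with a warning instead of dividing by
  zero; a constant positive map normalizes to ones. Saliency over the
  texture branch is the normalized absolute gradient of the same scalar
  w.r.t. the 64 GLCM entries.
* **2-D projection** of embeddings is linear (PCA, 2 components), with each
  axis sign-fixed so its largest-magnitude coordinate is positive, making
  layouts reproducible.
* **Determinism**: every stochastic step (weight init, triplet split and
  shuffles, subsampling, generators) derives from explicit integer seeds;
  two runs with the same seed, config, and data are bit-identical.

## Synthetic benchmark

Real inputs are DFT-derived renderings; the generator emulates their visual
statistics only. A *family* couples (i) a MEP-like blob layout (smooth
Gaussian color fields; members jitter centers/widths by ~4%), (ii) an
RDG-like scatter page (white background, family-specific vertical point
spikes plus a diffuse band), and (iii) a curated SMILES scaffold series. The
two shipped families — linear alkanes C6–C13 and di- to nona-ethylene
glycols — are pre-validated so intra-family Tanimoto ≥ 0.70 and inter-family
≤ 0.40, guaranteeing a productive triplet set under the default thresholds;
the generator re-checks this contract and the GLCM family separation every
time it runs and refuses to emit a violating benchmark.

What passing the end-to-end test shows: the full pipeline (mining → training
→ inverse-distance scoring) can learn to separate visually-and-chemically
coherent groups from 16 compounds in 20 epochs on one CPU. What it does not
show: performance on real MEP/RDG renderings, whose within-group variation
(conformers, rendering choices, colormap conventions) is richer than the
generator's jitter, nor any claim about specific inhibitors or targets.

## Design choices where the design was open

* GLCM settings (offsets, symmetry, normalization, color handling) are not
  canonical for this use; the defaults (luminance, distance-1 four-direction
  symmetric accumulation, normalize-after-accumulate, no background masking)
  are declared choices, each overridable. Background masking is available
  because white pages dominate scatter diagrams, but off by default.
* The estimator surface follows scikit-learn (`fit`/`transform`,
  `get_params`); the network itself is an explicit-backprop numpy stack,
  which keeps the interpretability hooks (conv activations and their
  gradients, input gradients) one attribute away instead of requiring
  framework hooks.
* Per-epoch triplet subsampling (`max_triplets`) is off by default; the full
  Cartesian product is small at benchmark scale.
* Anchors default to "all" compounds; single-anchor studies pass an explicit
  anchor list.

## Limitations

* The package consumes *rendered images*; it neither computes electronic
  structure nor generates MEP/RDG surfaces, and contains no
  protonation/stereochemistry preparation.
* Inverse-distance values depend on trained weights, initialization, and the
  image corpus; absolute d⁻¹ values are not comparable across differently
  trained models, only orderings and contrasts within one model are
  meaningful.
* The CNN is deliberately small and trained from scratch; with libraries of
  hundreds of images a pretrained backbone would likely be preferable (out
  of scope here).
* Haralick scalar statistics are intentionally absent: the model consumes
  the raw normalized 8×8 co-occurrence matrix.
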