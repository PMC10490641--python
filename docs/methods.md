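# Methods

## Model

A CT slice is represented as a weighted region-adjacency graph. SLIC
superpixels are the atomic units: region *i* is a node with the single
feature f_i ∈ [0, 1], its mean windowed intensity. Regions sharing at
least one 4-connected pixel border are adjacent (a_ij = 1), and adjacent
nodes are joined by the Gaussian affinity w_ij = exp(−β d(f_i, f_j)) with
d the squared Euclidean distance — with one intensity channel,
d = (f_i − f_j)². The graph Laplacian consumes this weighted,
adjacency-masked matrix W (not the binary adjacency): L = D − W with
D_ii = Σ_j W_ij, the unnormalized (combinatorial) Laplacian.

Filtering is spectral: for the eigendecomposition L = U Λ Uᵀ, the graph
Fourier transform is x̂ = Uᵀx and a filter acts as y = U g(Λ) Uᵀ x.
The network never eigendecomposes; it uses the K-order Chebyshev
approximation on the rescaled operator L̃ = 2L/λ_max − I, whose spectrum
lies in [−1, 1]:

y = Σ_{k<K} θ_k T_k(L̃) x, with T_0 x = x, T_1 x = L̃x,
T_k x = 2 L̃ T_{k−1} x − T_{k−2} x.

λ_max is computed exactly per graph by a symmetric eigensolve. Two common
shortcuts are deliberately avoided: the λ_max ≈ 2 approximation is only
valid for the normalized Laplacian (the combinatorial Laplacian's λ_max is
unbounded), and each slice yields a different graph, so λ_max is
recomputed per sample.

The classifier is: affine lift 1→16 channels → [ChebConv → batch-norm →
ReLU] × 3 (16→16 channels) → ChebConv 16→2 → batch-norm → dropout →
per-node dense 2→2 → per-node softmax. The lift exists because each node
carries one feature while the first convolution operates on 16 input
channels; a learnable affine map is the minimal bridge that preserves the
[K, 16, 16] filter shape. The head is per-node rather than a flatten to a
fixed-length vector because the node count C varies across images; the
softmax is parameter-free. Parameter counts per layer are 256·K + 16 for
a 16→16 convolution (K·16·16 weights + 16 biases), 32 per 16-channel
batch-norm (scale + shift), and 32·K + 2 for the final 16→2 convolution.

## Training

The loss is an area-weighted soft Dice on the foreground probability:

loss = 1 − (2 Σ_i a_i p_i y_i + ε) / (Σ_i a_i p_i + Σ_i a_i y_i + ε),

with a_i the region's pixel count and ε = 10⁻⁶. Weighting by area makes
the superpixel-level loss approximate pixel-level Dice, which matters for
small tumors occupying few, small regions. Node labels come from
area-majority voting of the pixel mask (threshold 0.5, ties to
foreground — slightly favoring recall on small structures).

Optimization is Adam (lr 0.001, weight decay 5·10⁻⁴ applied to
convolution, lift and head weights but not to biases or batch-norm
parameters), dropout 0.2, one graph per optimization step. Batch
normalization statistics are computed over the nodes of the current graph
(variable C makes cross-graph batching ill-defined); running statistics
with momentum 0.1 are used at inference. Adamax, SGD with momentum,
RMSprop and Adadelta are available alternatives. Evaluation uses k-fold
cross-validation (default 10) with a deterministic seeded fold assignment,
so every sample is validated exactly once; a disjoint holdout split is used
for the final model. Tumor segmentation initializes from the liver model's
parameters and continues training on tumor node labels; the training
history is concatenated so the full convergence curve can be plotted.

The network and its backpropagation are implemented directly in numpy.
Graphs here have at most ~1000 nodes, so dense matrix algebra on one CPU
is fast (a full 60-phantom, 60-epoch study trains in seconds), and the
implementation keeps every gradient explicit and testable — the backward
pass is verified against numerical differentiation, and Chebyshev
filtering against the exact spectral route.

## Preprocessing

Raw HU values outside [0, 150] are replaced by 0 (the liver parenchyma
window), then divided by the window width 150 so intensities lie in
[0, 1]. The divisor is configurable; 150 maps the window's full dynamic
range onto [0, 1]. Masks use the 0/1/2 = background/liver/tumor label
convention; the liver binary mask includes tumor pixels, since tumor
tissue lies within the liver. Real 350×350-target resizing uses bilinear
interpolation for images and nearest-neighbor for masks (preserving
binarity); augmentation applies one shared transform (rotation uniform in
[0, 20]°, optional horizontal flip) to image and mask, filling rotation
borders with 0, the windowed background value.

Region count: the default for real 350×350 CT is 600 superpixels, the
count at which segmentation quality was found to peak in a 200/600/1000
comparison; an area-proportional alternative N = P·Q/1000 is exposed as
`regions_by_area_rule` but is not the default, since the two rules
disagree (122 vs 600 for 350×350) and the fixed count is the one tied to
the reported quality. The phantom studies use 300 regions on 96×96
slices, keeping the region scale relative to anatomy comparable. SLIC
runs on normalized intensities with compactness 0.1. β defaults to 10 on
[0, 1] intensities: a full-contrast step (Δf = 1) then maps to weight
e⁻¹⁰ ≈ 5·10⁻⁵ while liver-interior fluctuations (Δf ≈ 0.05) keep weights
near 1.

## Phantom generator

Each phantom emulates a windowing-ready liver CT slice: an elliptical
liver (mean 100 pseudo-HU), with probability `tumor_probability` an inset
tumor ellipse (mean 50) fully contained in the liver, `organ_count`
confounder ellipses outside the liver at mean 110 — deliberately within
one noise sd of the liver intensity, so intensity alone cannot separate
organ from liver — and background at −40, which the [0, 150] window
zeroes. Axes are drawn from ranges defaulting to fractions of the image
side (liver 0.18–0.30·min(H, W), tumor 0.06–0.11, organs 0.05–0.10);
tumor placement resamples until the tumor lies fully inside the liver
(bounded retries, then an error). Pixel noise is i.i.d. Gaussian with sd
`pixel_noise_sd` (default 5 pseudo-HU, mild clinical-CT-like noise); the
per-tissue sds scale this level relative to a reference of 10, so
`pixel_noise_sd = 0` yields an exactly piecewise-constant image.
Generation is deterministic per (spec, case seed); dataset case seeds are
`spec.seed + index`.

What the phantoms do *not* emulate: organ shape variability beyond
ellipses, CT texture, partial-volume and beam-hardening artifacts,
anisotropic spacing, 3-D context, or multiple/irregular tumors. Passing
the phantom studies therefore demonstrates that the pipeline and
optimization behave correctly end-to-end and that the graph formulation
can exploit spatial context; it does not certify clinical performance on
real CT, which requires evaluation on real volumes read through
`read_ct_volume`.

## Evaluation choices

Dice = 2|S∩T|/(|S|+|T|) and IoU = |S∩T|/|S∪T| are both defined as 1.0
when prediction and truth are empty and 0.0 when exactly one is.
Zero-denominator ratio metrics return 0 and set a warning flag rather
than raising. Sensitivity and recall are the same quantity TP/(TP+FN) and
are reported under both names. ROC curves sweep thresholds over the node
scores (delegated to scikit-learn) with trapezoidal area; tests
cross-check the area against brute-force Mann–Whitney concordance.

Noise robustness: SNR(dB) = 10·log₁₀(P_signal/P_noise) with P_signal the
mean squared intensity of the clean normalized image. Noise is added
after normalization and before superpixel clustering, and is *not*
clipped to [0, 1], so the embedding sees the true perturbation. The sweep
re-embeds every corrupted slice from scratch (new SLIC partition, new
graph, new λ_max). The default grid +40/+20/0/−10 dB spans near-clean to
noise-dominated regimes.

## Study sizes

The packaged study conditions are 60 phantoms at 96×96 with 300
superpixels, order-3 filters, 60 epochs, an 80/20 train/holdout split and
10-fold cross-validation inside the training split — sizes at which the
full study, including fine-tuning and a 3-seed noise sweep, completes in
well under a minute on one CPU while the graphs (C ≈ 220–260) remain
representative of the 600-region regime on real slices.

## Known limitations

- Single-channel node features (mean intensity only); no texture or shape
  descriptors.
- Slice-wise only; no volumetric aggregation or 3-D metrics.
- Batch-norm statistics from single graphs are noisier than large-batch
  statistics; momentum 0.1 compensates but very small graphs (< ~30
  nodes) would be fragile.
- The Dice loss's ε guards empty-foreground graphs but makes gradients
  vanish when both prediction and labels are near-empty.
- Superpixel quantization bounds achievable pixel Dice; at 300 regions on
  96×96 phantoms the label round-trip alone costs roughly 1–2% Dice on
  livers and more on small tumors.
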