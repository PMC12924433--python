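# Methods

## Data model and preprocessing

A slice is a spot-by-gene count matrix with per-spot pixel coordinates
(image convention: origin top-left, x rightward, y downward, 0-based).
The spot spacing `d` — needed to choose the graph radius — is estimated as
the median over spots of the nearest positive neighbor distance; coincident
spots (which arise when horizontally merged slices share a cut-surface
column) are ignored by taking each spot's first *positive* neighbor gap.

Expression preprocessing is the conventional order: library-size
normalization (to the median total), `log1p`, selection of the top
`min(n_hvg, g)` highly variable genes (default 3000), then per-gene scaling
to zero mean and unit variance (population variance, so the invariant holds
exactly at any n; no clipping by default). The alternative order with the
log transform first is selectable (`log_before_norm`) because exports and
conventions differ between toolchains; every applied step is recorded in
`transform_log`. HVG ranking is a Seurat-flavor normalized dispersion:
variance/mean per gene, z-scored within 20 quantile bins of the gene means,
with exact ties broken deterministically by ascending gene index. Note the
binning implies that a high-variance gene can only rank highly relative to
genes of similar mean; fixtures that probe the ranking must spread their
constructed genes across the mean range.

## Histology features

Each spot's h×w crop (default 40×40, values in [0,1], border crops padded
by edge replication) is split into p×p patches (default p=8, so N=25
patches of length 192), linearly embedded to 768-dim tokens with learned
positional embeddings, and passed through a pre-norm transformer (12 heads,
6 MSA+MLP blocks). There is no class token: all N tokens pass through a
per-token 1000-dim linear head and are flattened row-major to one
n×(N·1000) matrix, which mean-centered PCA reduces to
`f2 = min(3000, n−1, N·1000)` components (signs fixed so each component's
largest-magnitude loading is positive). The encoder is a fixed feature
extractor: weights are seeded-random by default, or loaded from a
checkpoint matching the documented tensor-name schema (`HViT.state_dict`).
Whether the per-patch head carries pretrained classifier weights or a fresh
projection is left to the checkpoint supplier; both work. The forward pass
runs in float32 with spot-chunked buffers — single precision is ample for
a fixed feature extractor and keeps the pass within a few tens of seconds
per thousand spots on one core.

## Spatial graph

`A_ij = 1` iff the Euclidean distance is *strictly* less than r, plus
self-loops. A numeric radius must lie in the open interval (d, 2d) — below
d every spot is isolated, above 2d unrelated neighborhoods merge — and
`radius="auto"` uses 1.5 d, the interval midpoint. The same construction
serves 2D slices and aligned 3D stacks; operations consume the edge list
and a dense matrix is only materialized for n ≤ 5000 (tests/inspection).
Cross-slice graphs are exempt from the (d, 2d) check because sensible
cross-slice radii sit between the inter-slice z-gap and the in-plane pitch.

## Model

Modality encoders are two graph attention layers (input → 512 → 100 per
modality); the joint encoder is one layer (200 → 30). Edge scores use the
sigmoid form `e_ij = σ(v_sᵀ ELU(W h_i) + v_kᵀ ELU(W h_j))` taken literally
(an outer sigmoid rather than the more common LeakyReLU), normalized by a
per-neighborhood softmax. The decoder mirrors the encoder exactly with tied
weights (the transpose of each encoder weight) and *reuses* the encoder's
attention coefficients, so the decoder owns zero parameters; gradient
updates along the decoder path flow into the encoder tensors. ELU uses
α = 1. In expression-only mode (platforms without histology) the image
branch is dropped and the joint input width is the expression latent width.

Corruption shuffles the rows of X and I with one *shared* permutation
(keeping negatives cross-modally coherent; independent permutations are a
flag away) and leaves the graph unchanged; a fresh permutation is drawn
every epoch by default, with a fixed-permutation mode available. The
summary `s = σ(mean of H)` is computed from the positive stream only, and
the discriminator is bilinear with a sigmoid — the standard
deep-graph-infomax construction. Reconstruction error is the per-spot
Euclidean (L2) norm summed over spots and both streams; the binary
cross-entropy clamps probabilities to [1e-7, 1−1e-7].

Training is full-batch Adam (constant lr 1e-4, weight decay 1e-4, default
1200 epochs, β = 0.04) with no optimizer-state resets. Array arithmetic
runs in float32 on an in-package reverse-mode autodiff tape written for
exactly this model's primitives (sparse gather/scatter message passing,
segment softmax, row norms); per-epoch loss scalars are accumulated in
float64, so the identities `L_GATE = L_GATE_P + L_GATE_N` and
`L = L_GATE + β·L_CL` hold to ~1e-11 in the recorded series. The backward
sweep processes nodes in decreasing creation order — a topological order
that does not depend on what else hangs off shared nodes — which makes
gradient accumulation order, and hence floating-point rounding,
reproducible: a β = 0 run is bit-identical to a reconstruction-only run.
Two runs with the same seed and configuration are bit-identical on the
same BLAS. A non-finite loss aborts with the epoch and loss components.
With ELU on the final decoder layer, reconstructions are bounded below by
−1 while scaled expression is not; this caps the attainable reconstruction
of extreme negative values but does not affect the encoder embedding used
downstream.

## Clustering and refinement

With a known domain count, a full-covariance Gaussian mixture (seeded
k-means initialization, 5 restarts, reg_covar 1e-4) stands in for
model-based clustering; the covariance model is configurable since the
reference choice is unstated. Otherwise Louvain runs on a Jaccard-weighted
shared-nearest-neighbor graph (kNN = 15); sweep the resolution over
0.2–2.0. Refinement reassigns each spot to the modal label of its
`min(k, n−1)` spatially nearest neighbors (default k = 50), computed
synchronously from the pre-refinement labels, ties keeping the current
label — both choices made for determinism. Refinement is off by default
and intended for spatial-domain maps, not cell-type calls. Label matching
maximizes contingency-table agreement via the Hungarian algorithm, surplus
predicted categories taking fresh ids; ARI is the permutation-model
adjusted index and NMI uses arithmetic-mean normalization. UMAP projection
is seeded and used only for plotting.

## Multi-slice alignment

Alignment is pure translation, under the assumption that consecutive cut
surfaces are nearly identical in shape and size; no rotation or
deformation is modeled (optimal-transport registration is a different
family of methods, deliberately out of scope). Vertical mode treats every
spot as edge structure, subtracts each slice's centroid bias relative to
slice 1 (which is never moved), and assigns `z_1 = 0`,
`z_i = (i−1)·d + λ Σ_{j<i} l_{j,j+1}` with thickness and separations in
microns; λ defaults to 1 and a unit-scale factor converts z into the x/y
coordinate units when those are pixels. Horizontal mode takes the
rightmost spots of the left slice and leftmost of the right (within one
spot spacing of the extreme x), shifts the right slice by
`(max x₁ − min x₂, ȳ₁ − ȳ₂)`, and merges — the merged entity can be
re-aligned against further slices. Colliding spot ids are suffixed with
the slice id.

## Annotation transfer

Pathologist regions (labelme-style JSON polygons in image pixels) map to
spots by the ray-casting crossing number: a +x ray from the spot crosses a
simple polygon's boundary an odd number of times iff the spot is inside.
Edges follow the half-open rule (lower-y vertex included, upper excluded),
so rays through vertices count once and a point on the shared edge of two
adjacent polygons belongs to exactly one — the boundary behavior an
"any direction" ray leaves undefined. Overlapping regions resolve by
annotation order (first listed wins, logged); spots in no region are
flagged unassigned. Zero-area polygons match nothing, with a warning.

## Synthetic benchmarks

The generator emulates the structure the method exploits: a regular grid
(pitch 100 units; a radius graph on a grid behaves like one on a honeycomb,
and grid geometry is easier to reason about in tests), K spatial domains
(stripes, blocks or Voronoi), and counts with domain-specific markers.
Defaults describe the strong-signal benchmark: 30×30 spots, K=3 stripes,
200 genes with 25 markers per domain elevated by 1.5 log-fold over a
baseline mean of 2, gamma-Poisson (negative-binomial) noise with
dispersion 0.2 to emulate count overdispersion. The image fills each
spot's grid cell with its domain's base color plus Gaussian texture noise
(sd 0.03). An `expression_profiles` map lets several domains share one
expression profile, creating the ablation benchmark where only the image
separates two domains. What the generator does *not* emulate: real H&E
morphology (nuclei, stain variation), hexagonal packing (available as an
exercise via custom coordinates), spatial expression gradients within a
domain, or batch effects — so passing benchmarks demonstrates the
machinery recovers planted, well-separated structure, not performance on
real tissue.

## Problem sizes used in tests and the acceptance script

End-to-end checks train 200 epochs on the 30×30 benchmark (three seeds)
and on the 20×20 ablation benchmark — sizes chosen so the whole suite runs
on a single core in well under half an hour while the planted structure is
still unambiguous. The published-default 1200 epochs remain the `RunConfig`
default for real data.

## Known limitations

* The transformer is a fixed feature extractor; no histology fine-tuning.
* Full-batch training: memory and time scale with n × hidden width; no
  mini-batching or neighbor sampling.
* Translation-only slice alignment fails under rotation or distortion.
* The Gaussian-mixture stand-in is not numerically identical to
  R's model-based clustering family, though it serves the same interface
  (cluster count in, labels out).
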