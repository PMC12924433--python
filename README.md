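# spotfuse

Spatial-domain detection for spatial transcriptomics by **multi-modal graph
contrastive learning**. `spotfuse` learns a joint embedding of array spots
from three complementary signals — gene expression, histology-image texture
and color, and spatial proximity — and clusters that embedding into
spatially coherent tissue domains. It also reconstructs 3D tissue structure
by aligning serial or adjacent slices, and transfers pathologist polygon
annotations onto spots.

## Who this is for

Analysts working with spot-based spatial transcriptomics (10x Visium-style
MTX exports or plain CSV matrices), with or without a registered H&E image,
who want unsupervised tissue-domain maps, multi-slice 3D integration, or
per-spot labels derived from manual region annotations.

## The model

Each slice is modeled as an undirected graph `G = (V, E)`: one node per
spot, an edge whenever two spots lie closer than a radius `r ∈ (d, 2d)`
(`d` = spacing between adjacent spots), plus self-loops. Spot features are

* `X ∈ R^{n×f1}` — library-size-normalized, log-transformed, scaled
  expression over the top `f1` highly variable genes, and
* `I ∈ R^{n×f2}` — per-spot histology features: the 40×40-pixel crop around
  each spot is split into patches, encoded by a vision transformer (12
  heads, 6 MSA layers, per-token 1000-dim head), and reduced by PCA.

A **graph attention auto-encoder** encodes each modality with two attention
layers and fuses them with a joint layer into the embedding `H ∈ R^{n×f'}`.
Every layer aggregates neighbors with attention weights

    e_ij = σ(v_sᵀ ELU(W h_i) + v_kᵀ ELU(W h_j)),   α_ij = softmax_{j∈N_i}(e_ij),
    h_i ← ELU(Σ_{j∈N_i} α_ij W h_j),

and the decoder mirrors the encoder with *tied* weights and reused α — it
adds no parameters. Training minimizes

    L = L_GATE + β·L_CL,

where `L_GATE` sums per-spot reconstruction errors of a clean stream and a
corrupted stream (rows of `X` and `I` shuffled by one shared permutation,
graph unchanged), and `L_CL` is a binary cross-entropy contrastive loss: a
bilinear discriminator `D(h, s) = σ(hᵀ B s)` must score true spot
embeddings above corrupted ones against the graph summary
`s = σ(mean_i h_i)`. Defaults: `f1'=f2'=100`, `f=200`, `f'=30`, `β=0.04`,
Adam with lr `1e-4`, weight decay `1e-4`, 1200 epochs.

`H` is clustered by a seeded Gaussian mixture (when the number of domains
is known) or Louvain on a shared-nearest-neighbor graph, optionally refined
by a 50-nearest-neighbor spatial majority vote, and scored against ground
truth with ARI/NMI after Kuhn–Munkres label matching.

For multi-slice data, serial slices are center-aligned to a reference and
stacked at `z_i = (i−1)·d + λ Σ_{j<i} l_{j,j+1}` (slice thickness `d`,
separations `l`); adjacent slices are abutted edge-to-edge. A radius graph
on the aligned 3D coordinates links spots within and across slices so the
same model integrates the whole stack.

## Worked example

```python
import numpy as np
from spotfuse import (SyntheticSpec, generate_dataset, generate_image,
                      RunConfig, run_pipeline)

spec = SyntheticSpec(seed=0)                 # 30x30 grid, 3 stripe domains
ds = generate_dataset(spec)
img = generate_image(spec, ds)
cfg = RunConfig(seed=0, n_clusters=3)
res = run_pipeline(ds, cfg, image=img, epochs=200)
print(f"ARI={res.ari:.3f} NMI={res.nmi:.3f}")
print(f"loss {res.report.l_total[0]:.0f} -> {res.report.l_total[-1]:.0f}")
```

Output:

```
ARI=1.000 NMI=1.000
loss 90438 -> 73388
```

The embedding separates the three planted domains perfectly (ARI/NMI of 1
against the generator's labels) while the training loss falls by ~18% over
200 epochs. On real tissue the same call reads a Visium directory instead:

```bash
spotfuse run --input visium_dir/ --out results/ --n-clusters 7 --seed 0
spotfuse align --slices s1/ --slices s2/ --mode vertical --thickness 10 --out aligned/
spotfuse annotate --polygons regions.json --coords coords.csv --out labels.csv
spotfuse simulate --spots 30 --domains 3 --seed 0 --out fixture/
```

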