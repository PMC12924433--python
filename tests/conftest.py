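"""Shared fixtures.

The heavy session-scoped fixtures run the complete pipeline on the
strong-signal synthetic benchmark (30 x 30 grid, 3 stripe domains, both
modalities, 200 training epochs) and on the ablation benchmark where two
domains share an expression profile and only the histology image separates
them.  They are computed once and reused by every test that needs them.
"""

from __future__ import annotations

import numpy as np
import pytest

from spotfuse import (
    RunConfig,
    SyntheticSpec,
    generate_dataset,
    generate_image,
    run_pipeline,
)

E2E_SEEDS = (0, 1, 2)
E2E_EPOCHS = 200


@pytest.fixture(scope="session")
def small_dataset():
    """12 x 12 grid, 3 domains, 60 genes: cheap but structured."""
    spec = SyntheticSpec(
        grid_side=12, n_genes=60, markers_per_domain=15, seed=7
    )
    return generate_dataset(spec)


@pytest.fixture(scope="session")
def e2e_runs():
    """Full pipeline (expression + histology) on the strong-signal fixture,
    one run per seed; each entry carries the ARI/NMI and the loss report."""
    runs = {}
    for seed in E2E_SEEDS:
        spec = SyntheticSpec(seed=seed)
        ds = generate_dataset(spec)
        img = generate_image(spec, ds)
        cfg = RunConfig(seed=seed, n_clusters=spec.n_domains)
        runs[seed] = run_pipeline(ds, cfg, image=img, epochs=E2E_EPOCHS)
        runs[seed].truth = np.asarray(ds.labels)
        runs[seed].coords = ds.coords
    return runs


@pytest.fixture(scope="session")
def ablation_runs():
    """Two-modality vs expression-only runs on the fixture whose domains 0
    and 1 share an expression profile but differ in image color."""
    spec = SyntheticSpec(
        grid_side=20, expression_profiles={0: 0, 1: 0, 2: 2}, seed=3
    )
    ds = generate_dataset(spec)
    img = generate_image(spec, ds)
    cfg = RunConfig(seed=3, n_clusters=spec.n_domains)
    multi = run_pipeline(ds, cfg, image=img, epochs=E2E_EPOCHS)
    expr_only = run_pipeline(ds, cfg, use_image=False, epochs=E2E_EPOCHS)
    return {"multimodal": multi, "expression_only": expr_only, "truth": ds.labels}
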