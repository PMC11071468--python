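# voxseg

Probabilistic cell segmentation for imaging-based spatial
transcriptomics (10X Xenium, Vizgen MERSCOPE, NanoString CosMx), for
anyone who has a transcript table and a rough nuclear segmentation and
wants full cell boundaries, a trustworthy cell-by-gene matrix, and a way
to measure how much cross-cell contamination a segmentation introduces.

Instead of drawing boundaries from images, voxseg *simulates* them:
space is discretized into voxels, each voxel is unassigned or owned by
one cell, and a Metropolis–Hastings sampler perturbs ownership one voxel
at a time, scored by a probabilistic model of the observed transcripts.
The model is a Poisson point process with per-gene intensity

    λ_g(s) = τ_g^bg + τ_{g,σ(i(s))}

(background plus the owning cell's rate), a hierarchical Gamma mixture
over per-cell rates — so counts are negative binomial,
X_gc ~ NB(α_{g,z_c}, ν_c/(ν_c+β_{g,z_c})), with k latent components
acting as broad cell types — a LogNormal volume model per component, a
prior p_nuc = 0.8 that transcripts keep their nuclear assignment, and a
two-component Normal diffusion prior (ρ=0.2, σ_a=4 μm, σ_b=0.5 μm) that
lets transcripts be repositioned back into the cell they leaked from.
Boundary moves respect hard constraints (no cell annihilation, local
connectivity preservation, a per-layer perimeter bound
perimeter ≤ 1.3·2√(π·area)) with an explicit proposal-ratio correction,
so the chain genuinely samples its posterior; parameters are updated by
exact conjugate Gibbs steps using Chinese-restaurant-table and
Polya-Gamma augmentation. Sampling starts at 4 μm voxels and doubles
resolution twice, ending at 1 μm.

The package also implements two segmentation-quality metrics that need
no ground truth: **relative spurious co-expression** (how much gene
pairs that inflate under deliberate boundary expansion co-occur under a
method, relative to nuclear segmentation, on counts down-sampled to
exactly 50 per cell) and **normalized tumor proximity** (expected
hitting time of a random walk on the Delaunay cell graph to an absorbing
cell type, normalized by a k-step local-shuffle background), plus a
synthetic-tissue generator with full ground truth for end-to-end
validation.

## Worked example

```python
import numpy as np
from voxseg import (SyntheticConfig, generate_tissue, diffuse_transcripts,
                    SamplerConfig, PriorConfig, run, evaluate_segmentation)

cfg = SyntheticConfig(seed=3)          # 50 cells, 30 genes, 3 components,
table, truth = generate_tissue(cfg)    # 100×100 μm, 6% background noise
table = diffuse_transcripts(table, truth, cfg)   # ρ=0.2, σa=4, σb=0.5 μm

result = run(table, SamplerConfig(seed=1), PriorConfig(k=3))
report = evaluate_segmentation(result, truth)
print(f"{table.M} transcripts, {result.n_cells} cells")
print(f"accuracy {report.transcript_accuracy:.3f}  "
      f"cell-count ratio {report.cell_count_ratio:.2f}  "
      f"count corr {report.mean_count_correlation:.3f}")
```

prints

```
7630 transcripts, 50 cells
accuracy 0.903  cell-count ratio 1.00  count corr 0.979
```

i.e. 90.3% of the non-background transcripts end up assigned to the cell
matched to their true cell of origin, every one of the 50 seeded nuclei
survives as exactly one retained cell, and the per-cell expression
vectors correlate 0.979 with the truth. `result` carries the counts
matrix, per-cell metadata (centroid, volume, component), boundary
polygons per z-layer, and the inferred (de-diffused) transcript
positions.

The same pipeline is available from the shell:

```
voxseg simulate --out tissue/ --seed 3
voxseg segment --transcripts tissue/transcripts.csv --dialect generic \
               --output-dir out/ --seed 1 --components 3
voxseg proximity --cells meta.csv --absorbing-type tumor --out prox.csv
voxseg benchmark-coexpr --nuclear nuc.mtx --expanded exp.mtx --method m.mtx --out ratios.csv
```

`segment` writes a MatrixMarket cell-by-gene matrix (genes × cells) with
gene/cell sidecars, a cell-metadata CSV, GeoJSON boundary polygons, and
a per-transcript CSV with observed and inferred positions.

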