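# cellviews

Coordinated-multiple-views core for multimodal and spatially resolved
single-cell data: a declarative JSON view-configuration schema, a
coordination model that links views through named scopes, type-based
matching of views to data, lazy chunk/tile loading from Zarr-compatible
stores, access-optimized store export, and a deterministic static
snapshot renderer that exercises the whole stack.

## Who this is for

Analysts of single-cell and spatial omics experiments (scRNA-seq,
CITE-seq, smFISH, Visium, CODEX, ...) work with a patchwork of
artifacts: cell-by-feature matrices, dimensionality-reduction
embeddings, spatial coordinates, hierarchical cell-type annotations,
multiplexed multiscale images, and cell-segmentation label images.
Relating a pattern across those modalities — "which cells co-express
these two genes, and where do they sit in the tissue?" — requires
multiple *coordinated* visualizations, not one plot. `cellviews`
implements the data, configuration and coordination machinery that
makes such multi-view figures declarative, reproducible and cheap to
serve from static files.

## The model

**Entity triples.** Every data unit and every view carries up to three
identifiers: an observation type (cell, spot, molecule, ...), a feature
type (gene, protein, peak, ...), and a feature-value type (expression,
count, intensity). A view is matched to data by comparing exactly the
components its type consults: a heatmap is identified by all three; a
feature list by feature type alone.

**Coordination scopes.** Views are never linked to each other, only to
named values (*scopes*) of typed properties (*coordination types*:
`spatialZoom`, `featureSelection`, `obsColorEncoding`, ... — the
built-in registry has more than fifty). Views referencing the same
scope are coordinated; updating the scope updates all of them and no
other view. A view config — datasets/files, coordination space, grid
layout — is one canonical JSON document, so any interaction state can
be snapshotted, diffed, or shared as a self-contained URL fragment.

**Chunked access.** Observation-by-feature matrices are stored in
chunked (Zarr v2 layout) directory stores. With the per-feature chunk
plan (many observations × few features per chunk), fetching one gene
across all cells costs `ceil(n_obs / obs_per_chunk)` chunk reads.
Image and segmentation-bitmask pyramids load tile by tile at the
pyramid level matching the viewport zoom. Every handle keeps an access
log of the chunks actually fetched, so laziness is a tested property,
not a hope.

## Worked example

```python
import tempfile
from cellviews import (FixtureSpec, generate_dataset, generate_config,
                       render_snapshot, ChunkedMatrixHandle, load_matrix_subset)
from cellviews.coordination import resolve_view_state

root = tempfile.mkdtemp()
generate_dataset(FixtureSpec(n_cells=120, seed=7), root)   # synthetic multimodal dataset
cfg = generate_config(root, "smfish-like")                 # spatial + heatmap, linked

state = resolve_view_state(cfg, "heatmap")
print("linked featureSelection:", state["featureSelection"])

h = ChunkedMatrixHandle.open_store(f"{root}/expression.matrix.zarr")
print("matrix shape:", h.shape, "chunk shape:", h.chunk_shape)
col = load_matrix_subset(h, [state["featureSelection"][0]])
print("chunks fetched for one gene:", h.access_log)
print("mean expression:", round(float(col.mean()), 3))

snap = render_snapshot(cfg, root)
print("snapshot:", snap.raster.width_px, "x", snap.raster.height_px,
      "px,", len(snap.panels), "panels,", len(snap.failed_panels), "failed")
snap.save(f"{root}/smfish.png")
```

Output:

```
linked featureSelection: ['gene_000', 'gene_003']
matrix shape: (120, 40) chunk shape: (120, 10)
chunks fetched for one gene: [(0, 0)]
mean expression: 2.417
snapshot: 1000 x 600 px, 2 panels, 0 failed
```

The two marker genes selected in the shared `featureSelection` scope
drive both panels: the spatial view colors segmented cells by the first
gene's expression and the heatmap highlights the same selection. The
whole 120-cell column of that gene cost a single chunk fetch because
the store was written with the per-feature chunk plan. The rendered
PNG is byte-identical across runs for a fixed fixture seed.

The same pipeline is available from a shell:

```sh
viz make-fixture --out fx --cells 120 --seed 7 --template smfish-like
viz snapshot --config fx/config.smfish-like.json --out smfish.png
viz validate fx/config.smfish-like.json
viz convert --input matrix.csv --pattern per-feature --out store/
```

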