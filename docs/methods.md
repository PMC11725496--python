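# Methods

This note documents the models, conventions and numerical choices
behind `cellviews`, and what the synthetic fixture does and does not
establish about real data.

## Coordination model

State is factored into *coordination types* (named, typed properties:
camera parameters, selections, encodings, layer properties, user
preferences) and *coordination scopes* (named values of a type stored
in the config's coordination space). A layout item maps coordination
types to scope names; views referencing the same scope for a type are
coordinated on it. There are no observers or events: propagation is
pure state resolution (`resolve_view_state`), which for each type
relevant to the view's type returns the linked scope's value, or the
registry default when unlinked. A reference to a deleted scope is a
hard `DanglingScopeError`, never a silent fallback — a dangling link
is a corrupted document, while an absent link is a legitimate minimal
config.

Design choices made where the design was genuinely open:

- **Scope auto-naming** follows spreadsheet order (`A`, `B`, ..., `Z`,
  `AA`, ...) in creation order per type.
- **Value equality is exact** (deep structural equality, no float
  tolerance): coordination values are user state, not computed floats.
- **The registry is flat** — one level of scopes; meta-coordination
  (scopes of scopes) is out of scope.
- The built-in registry enumerates 54 types. The categories (entity
  identifiers, spatial/embedding/heatmap cameras, selections and
  highlights, color encodings, per-layer properties, genomic-camera
  placeholders, preferences) are a faithful reconstruction of what a
  coordinated single-cell viewer must expose; the exact names are this
  package's own.

## View configs

A config is one JSON document: `version`, `datasets` (each a list of
`{url, fileType, options, entity}` files), `coordinationSpace`, and a
`layout` of views on an unbounded nonnegative-integer grid. The schema
version is fixed at `spec-1.0`; unknown versions are rejected rather
than half-interpreted. Overlapping grid rectangles are a warning, not
an error — the grid does not forbid them and overlap can be
intentional. Validation is hand-rolled (violations carry JSON-pointer
style paths) because most of the invariants are referential — dangling
dataset uids, unregistered file types, scope references — which a
declarative schema language cannot express.

Canonical serialization: sorted keys, UTF-8, no insignificant
whitespace, `NaN`/`Infinity` rejected. Share URLs put the
DEFLATE-compressed, base64url-encoded canonical JSON in the URL
fragment (`#cfg=...`): self-contained and server-free, matching the
static-file deployment model. The encoding scheme is this package's
own choice.

## Data model and matching

Data types are a closed set (`obsFeatureMatrix`, `obsLocations`,
`obsEmbedding`, `obsSegmentations`, `obsSets`, `image`); file types
pair them with formats, and a joint file type (the AnnData-style store)
exposes several data types from one URL, with per-component paths in
its options. An accessor matches a view requirement iff the data type
matches and every entity component the view's type declares relevant is
equal; other components are ignored. Unspecified file entity components
default to `(cell, gene, expression)` — the dominant single-cell case —
so minimal configs work. When several accessors match one requirement,
the first in manifest order (file order, then data-type name) wins and
a warning is recorded. Matching is restricted to the view's declared
dataset.

## Loaders and laziness accounting

Every file type has a required full load that validates content
(malformed content raises a validation error naming the offending
field; an unreadable path raises a distinct I/O error). Chunked formats
additionally expose handles with subset loading:

- `ChunkedMatrixHandle.load_subset(features, obs_range)` reads, via
  zarr orthogonal indexing, exactly the chunks intersecting the
  requested rows × columns, each at most once.
- `ImagePyramid.load_tile(level, tx, ty, channels)` reads one tile;
  tiles coincide with storage chunks for stores written by this
  package, and segmentation bitmasks load through the identical path.

A counting store wrapper logs every chunk key fetched; a per-handle LRU
cache (default 128 chunks for matrices, 64 for images) sits in front of
storage, and the log records fetches, not cache hits. Cache semantics
are an engineering choice; the laziness tests therefore measure fresh
handles. Conventions: 0-based indexing, half-open ranges, raster
orientation (origin top-left, y down), CSVs comma-separated with a
header row and the observation id in the first column. Loaders accept
local paths only; the store layout served is exactly what a static file
server would expose.

## Store export

The per-feature chunk plan stores `min(n_obs, 4096)` observations ×
`min(n_features, 10)` features per chunk. The direction (many
observations, few features) is what makes whole-feature fetches cheap;
the caps 4096 and 10 are this package's defaults, chosen so that a
single-feature fetch on a million-cell matrix costs a few hundred
chunk reads while chunks stay in the tens-of-kilobytes range. The
per-observation plan is the transpose mirror; `balanced` caps both
sides at 256. Default codec is Zlib level 5 (DEFLATE family); gzip and
zstd are available. Export refuses non-finite values before writing
anything.

Image pyramids halve Y/X per level (`ceil` division), 2×2 block means
for intensity images and top-left stride sampling for bitmasks —
labels are categorical and must never be averaged. Block means use the
true mean of ragged edge blocks, so global mean intensity is conserved
exactly on even dimensions (the conservation test uses even sizes for
that reason). Multiscale metadata follows the OME-style
`multiscales`/`datasets` attribute layout, with an `image-label` marker
attribute on bitmask stores.

The size report compares the store's on-disk bytes against an actual
delimited-text serialization of the same matrix using full-precision
float `repr` — a fair comparison, not a truncated one.

## Viewport math

Zoom is logarithmic: `2**zoom` screen pixels per data unit. Level
selection returns the finest level whose downsample factor is at least
the data-pixels-per-screen-pixel (never fetch more resolution than the
screen can show), clamped to the deepest level. Visible tiles are
exactly those whose data-space footprint intersects the viewport
rectangle (open intersection; touching edges excluded).

Heatmap aggregation bins are proportional integer partitions (bin `k`
of `p` over `n` cells covers `[floor(k·n/p), floor((k+1)·n/p))`): the
bins tile the matrix exactly, no cell is dropped or double-counted, and
a constant matrix yields a constant raster at every zoom — the
anti-aliasing criterion. Mean (default), max and min are exposed; the
choice of default is ours. Axis ticks are drawn at a uniform stride
chosen so consecutive labels are at least the widest label apart, with
a fixed 7 px per character; zooming in never drops labels.

## Renderer

Pure-numpy rasterization; PNG via Pillow; no GUI toolkit, so identical
inputs give byte-identical images. Per-view rasters: scatterplot,
spatial (layered), heatmap, set-size bar chart, feature-value
histogram, per-set violin silhouettes. Controller views exist as
coordination state only and render as neutral panels.

Conventions (stated, since no canonical z-order or blend equation
exists for this composition): spatial stacks composite back-to-front
with standard alpha *over*, built bottom-up as images, segmentations,
spots, points. Image channels are contrast-windowed, tinted by their
channel color, summed additively and clipped at 255 (the standard
multiplexed composite). Segmentation pixels look up the per-observation
color of their label (label `L` ↔ observation `L-1`; 0 = background =
transparent). Spots are fixed-radius circles (default 4 px), points
single pixels; both radii are coordination values. Panels are 200 px
per grid unit. The default colormap is a 256-entry viridis table;
missing values render mid-grey. One shared code path resolves
per-observation colors for every view, which is what makes linked
views color identically; when a linked feature selection spans
modalities, each view colors by the first selected feature its own
matrix contains, and renders missing-grey if none match.

A failing panel is recorded in the snapshot's per-panel report and
drawn as a hatched placeholder; other panels still render.

## Synthetic fixture

`FixtureSpec` defaults: 120 cells, 40 genes, 12 proteins, 128×128
image, 3 channels, 4 clusters. Counts are Gamma-Poisson
(negative-binomial-like, dispersion 2) with three marker genes per
cluster at 5× mean — enough separation that cluster structure is
visible in every view without being trivial. Clusters sit as Gaussian
blobs on a jittered grid in the image frame and on a circle in the
embedding; segmentations are disks of radius 3 labeled `1..n_cells`
(overlaps resolved later-label-wins, capacity checked up front); image
channels add a Gaussian blob per cell scaled by that cell's expression
of a channel-assigned marker gene, over Poisson background. One seed
fixes the whole tree byte-for-byte.

What the fixture does *not* emulate: realistic segmentation shapes,
spatial expression gradients within clusters, batch effects, doublets,
or the scale of real atlases (tests run at hundreds of cells, not
millions). Passing tests therefore demonstrate the correctness of the
coordination, loading, export and rendering *machinery* — exact chunk
accounting, bijective serialization, deterministic rendering — not
statistical claims about real tissues.

## Problem sizes

Test and acceptance workloads are sized for a desk-scale run: random
config round-trips at n=200, laziness and aggregation oracles at 100
random instances each, viewport math at 200 random viewports, export
round-trips at 2000×200, and the end-to-end pipeline at 120 cells —
sizes at which the brute-force oracles are still exact and instant.

## Known limitations

- No HDF5 stores, no remote (HTTP) chunk fetching, no genome-browser
  tile formats.
- OME-TIFF is read single-resolution and pyramidized in memory, not
  tiled natively.
- The schema has one version and no migration path.
- Rendering is nearest-neighbor; there is no sub-pixel anti-aliasing of
  markers (aggregation anti-aliasing applies to the heatmap body).
- Meta-coordination and runtime plugin registration are out of scope.
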