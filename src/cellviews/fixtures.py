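"""Deterministic synthetic multimodal single-cell fixture generator.

Emulates the heterogeneous-experiment setting the framework exists for:
one cohort of cells carrying a gene-expression count matrix, a surface
protein intensity matrix, spatial coordinates, a 2-D embedding,
hierarchical cluster annotations, a multichannel image whose channels
track cluster marker expression, and a label-image (bitmask) cell
segmentation — all written in the formats the loaders read, plus
matching view configs for three archetypal experiment layouts.

The expression model is a Gamma-Poisson (negative-binomial-like) count
mixture: every gene has a baseline mean and each cluster inflates its
marker genes' means fivefold, giving realistic sparsity and separable
clusters without fitting any real dataset. One seed fixes the entire
fixture tree byte-for-byte.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .config import ConfigBuilder, ViewConfig
from .errors import FixtureError
from .loaders import DenseMatrix, SetHierarchy, SetNode
from .renderer import SET_PALETTE, fit_camera, PX_PER_GRID_UNIT
from .store_export import (
    export_image_pyramid,
    export_matrix,
    export_sets,
    plan_chunks,
)

__all__ = ["FixtureSpec", "generate_dataset", "generate_config", "TEMPLATES"]

#: Marker genes per cluster and their mean inflation factor.
MARKERS_PER_CLUSTER = 3
MARKER_SHIFT = 5.0
#: Segmentation disk radius in image pixels.
DISK_RADIUS = 3

TEMPLATES = ("citeseq-like", "smfish-like", "visium-like")

_FILES = {
    "expression": "expression.matrix.zarr",
    "protein": "protein.matrix.zarr",
    "locations": "locations.csv",
    "embedding": "embedding.csv",
    "sets": "cell_sets.json",
    "image": "image.ome.zarr",
    "segmentation": "segmentation.ome.zarr",
}


@dataclass(frozen=True)
class FixtureSpec:
    """Study conditions for one synthetic dataset; seed fixes everything."""

    n_cells: int = 120
    n_genes: int = 40
    n_proteins: int = 12
    image_size: tuple[int, int] = (128, 128)  # (Y, X)
    n_channels: int = 3
    n_clusters: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_cells", "n_genes", "n_proteins", "n_channels", "n_clusters"):
            if getattr(self, name) < 1:
                raise FixtureError(f"{name} must be >= 1")
        if min(self.image_size) < 1:
            raise FixtureError("image_size dims must be >= 1")


def _cluster_markers(spec: FixtureSpec, n_features: int, per_cluster: int) -> list[list[int]]:
    """Disjoint marker indices per cluster (wrapping if features are few)."""
    out = []
    idx = 0
    for _ in range(spec.n_clusters):
        out.append([(idx + j) % n_features for j in range(per_cluster)])
        idx += per_cluster
    return out


def _counts(
    rng: np.random.Generator,
    n_cells: int,
    n_features: int,
    clusters: np.ndarray,
    markers: list[list[int]],
    dispersion: float = 2.0,
) -> np.ndarray:
    base = rng.gamma(shape=2.0, scale=1.0, size=n_features) + 0.3
    means = np.tile(base, (n_cells, 1))
    for k, marker_idx in enumerate(markers):
        rows = np.flatnonzero(clusters == k)
        for j in marker_idx:
            means[rows, j] *= MARKER_SHIFT
    lam = rng.gamma(shape=dispersion, scale=means / dispersion)
    return rng.poisson(lam).astype(np.int32)


def _cell_positions(
    rng: np.random.Generator, spec: FixtureSpec, clusters: np.ndarray
) -> np.ndarray:
    """Cluster blobs on a jittered grid inside the image frame."""
    h, w = spec.image_size
    r = DISK_RADIUS
    if spec.n_cells * (2 * r + 1) ** 2 > 0.8 * h * w:
        raise FixtureError(
            f"{spec.n_cells} disks of radius {r} cannot fit a {h}x{w} image; "
            "use a larger image_size"
        )
    side = math.ceil(math.sqrt(spec.n_clusters))
    margin = max(r + 1, min(h, w) // (side * 4))
    cy = np.linspace(margin, h - margin, side + 1)[:-1] + (h - 2 * margin) / (2 * side)
    cx = np.linspace(margin, w - margin, side + 1)[:-1] + (w - 2 * margin) / (2 * side)
    centers = [(cx[k % side], cy[k // side]) for k in range(spec.n_clusters)]
    jitter = rng.normal(0.0, 1.5, size=(spec.n_clusters, 2))
    sigma = min(h, w) / (side * 6.0)
    pos = np.empty((spec.n_cells, 2))
    for i, k in enumerate(clusters):
        cxk, cyk = centers[k]
        pos[i, 0] = cxk + jitter[k, 0] + rng.normal(0, sigma)
        pos[i, 1] = cyk + jitter[k, 1] + rng.normal(0, sigma)
    pos[:, 0] = np.clip(pos[:, 0], r, w - r - 1)
    pos[:, 1] = np.clip(pos[:, 1], r, h - r - 1)
    return np.round(pos, 3)


def _paint_bitmask(spec: FixtureSpec, pos: np.ndarray) -> np.ndarray:
    """Disks labeled 1..n_cells at cell positions; overlaps resolved
    later-label-wins; 0 is background."""
    h, w = spec.image_size
    mask = np.zeros((1, h, w), dtype=np.uint32)
    r = DISK_RADIUS
    yy, xx = np.mgrid[-r : r + 1, -r : r + 1]
    disk = (xx ** 2 + yy ** 2) <= r ** 2
    for label, (x, y) in enumerate(np.round(pos).astype(int), start=1):
        y0, y1 = max(y - r, 0), min(y + r + 1, h)
        x0, x1 = max(x - r, 0), min(x + r + 1, w)
        sub = disk[y0 - (y - r) : y1 - (y - r), x0 - (x - r) : x1 - (x - r)]
        mask[0, y0:y1, x0:x1][sub] = label
    return mask


def _paint_image(
    rng: np.random.Generator,
    spec: FixtureSpec,
    pos: np.ndarray,
    expr: np.ndarray,
    markers: list[list[int]],
) -> np.ndarray:
    """Channels whose intensity at each cell tracks one marker gene."""
    h, w = spec.image_size
    img = np.zeros((spec.n_channels, h, w), dtype=np.float64)
    r = DISK_RADIUS + 1
    yy, xx = np.mgrid[-r : r + 1, -r : r + 1]
    blob = np.exp(-(xx ** 2 + yy ** 2) / (2.0 * (r / 2.0) ** 2))
    for c in range(spec.n_channels):
        gene = markers[c % spec.n_clusters][0]
        weights = expr[:, gene].astype(float)
        peak = max(weights.max(), 1.0)
        for i, (x, y) in enumerate(np.round(pos).astype(int)):
            y0, y1 = max(y - r, 0), min(y + r + 1, h)
            x0, x1 = max(x - r, 0), min(x + r + 1, w)
            sub = blob[y0 - (y - r) : y1 - (y - r), x0 - (x - r) : x1 - (x - r)]
            img[c, y0:y1, x0:x1] += 220.0 * (weights[i] / peak) * sub
    img += rng.poisson(2.0, size=img.shape)
    return np.clip(img, 0, 255).astype(np.uint8)


def generate_dataset(spec: FixtureSpec, out_dir: str | Path) -> Path:
    """Write the full fixture tree; identical specs give identical bytes."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed)

    clusters = rng.integers(0, spec.n_clusters, size=spec.n_cells)
    cell_ids = [f"cell_{i:04d}" for i in range(spec.n_cells)]
    gene_ids = [f"gene_{j:03d}" for j in range(spec.n_genes)]
    protein_ids = [f"prot_{j:03d}" for j in range(spec.n_proteins)]

    gene_markers = _cluster_markers(spec, spec.n_genes, MARKERS_PER_CLUSTER)
    protein_markers = _cluster_markers(spec, spec.n_proteins, 2)

    expr = _counts(rng, spec.n_cells, spec.n_genes, clusters, gene_markers)
    prot = _counts(rng, spec.n_cells, spec.n_proteins, clusters, protein_markers)

    export_matrix(
        DenseMatrix(cell_ids, gene_ids, expr),
        out / _FILES["expression"],
        plan_chunks(spec.n_cells, spec.n_genes, "per-feature"),
    )
    export_matrix(
        DenseMatrix(cell_ids, protein_ids, prot.astype(np.float64)),
        out / _FILES["protein"],
        plan_chunks(spec.n_cells, spec.n_proteins, "per-feature"),
    )

    pos = _cell_positions(rng, spec, clusters)
    pd.DataFrame(pos, index=pd.Index(cell_ids, name="obsId"), columns=["x", "y"]).to_csv(
        out / _FILES["locations"]
    )

    # embedding: cluster centers on a circle plus Gaussian noise
    theta = 2 * np.pi * np.arange(spec.n_clusters) / spec.n_clusters
    emb = np.column_stack(
        [10 * np.cos(theta)[clusters], 10 * np.sin(theta)[clusters]]
    ) + rng.normal(0, 1.2, size=(spec.n_cells, 2))
    pd.DataFrame(
        np.round(emb, 4), index=pd.Index(cell_ids, name="obsId"), columns=["x", "y"]
    ).to_csv(out / _FILES["embedding"])

    leaves = [
        SetNode(
            f"Cluster {k + 1}",
            color=SET_PALETTE[k % len(SET_PALETTE)],
            obs_ids=[cell_ids[i] for i in np.flatnonzero(clusters == k)],
        )
        for k in range(spec.n_clusters)
    ]
    export_sets(
        SetHierarchy([SetNode("Clusters", children=leaves)]), out / _FILES["sets"]
    )

    n_levels = max(1, int(math.log2(max(min(spec.image_size) // 32, 1))) + 1)
    export_image_pyramid(
        _paint_image(rng, spec, pos, expr, gene_markers),
        out / _FILES["image"],
        n_levels=n_levels,
        tile_size=64,
        channel_names=[f"ch{c}" for c in range(spec.n_channels)],
    )
    export_image_pyramid(
        _paint_bitmask(spec, pos),
        out / _FILES["segmentation"],
        n_levels=n_levels,
        tile_size=64,
        is_bitmask=True,
    )
    return out


def _require(fixture_dir: Path, components: list[str]) -> None:
    missing = [c for c in components if not (fixture_dir / _FILES[c]).exists()]
    if missing:
        raise FixtureError(
            "fixture is missing components required by this template: "
            + ", ".join(f"{c} ({_FILES[c]})" for c in missing)
        )


def _add_common_files(b: ConfigBuilder, uid: str) -> None:
    b.add_file(uid, _FILES["expression"], "obsFeatureMatrix.zarr")
    b.add_file(
        uid,
        _FILES["protein"],
        "obsFeatureMatrix.zarr",
        entity={"obsType": "cell", "featureType": "protein", "featureValueType": "intensity"},
    )
    b.add_file(uid, _FILES["locations"], "obsLocations.csv")
    b.add_file(uid, _FILES["embedding"], "obsEmbedding.csv", options={"embeddingType": "synthetic-umap"})
    b.add_file(uid, _FILES["sets"], "obsSets.json")
    b.add_file(uid, _FILES["image"], "image.ome-zarr")
    b.add_file(uid, _FILES["segmentation"], "obsSegmentations.ome-zarr")


def _embedding_bounds(fixture_dir: Path) -> tuple[float, float, float, float]:
    df = pd.read_csv(fixture_dir / _FILES["embedding"], index_col=0)
    return (
        float(df["x"].min()),
        float(df["y"].min()),
        float(df["x"].max()),
        float(df["y"].max()),
    )


def _image_size(fixture_dir: Path) -> tuple[int, int]:
    import zarr

    root = zarr.open_group(str(fixture_dir / _FILES["image"]), mode="r")
    _, h, w = root["0"].shape
    return h, w


def _marker_gene_names(fixture_dir: Path) -> list[str]:
    import zarr

    root = zarr.open_group(str(fixture_dir / _FILES["expression"]), mode="r")
    genes = list(root.attrs["featureIds"])
    return [genes[k * MARKERS_PER_CLUSTER % len(genes)] for k in range(2)]


def generate_config(fixture_dir: str | Path, template: str) -> ViewConfig:
    """Build a validated view config for a fixture.

    Templates mirror archetypal experiments: ``citeseq-like`` links two
    scatterplots and a heatmap on a cross-modality feature selection
    (gene + surface protein); ``smfish-like`` superimposes image,
    segmentation and spot layers in one spatial view with a linked
    heatmap; ``visium-like`` pairs a spot-on-image spatial view with an
    embedding scatterplot and per-cluster summaries.
    """
    fixture_dir = Path(fixture_dir)
    if template not in TEMPLATES:
        raise FixtureError(f"unknown template {template!r}; use one of {TEMPLATES}")
    b = ConfigBuilder(name=f"synthetic fixture ({template})")
    b.add_dataset("fixture", name="synthetic multimodal fixture")

    panel = 2 * PX_PER_GRID_UNIT
    markers = None

    if template == "citeseq-like":
        _require(fixture_dir, ["expression", "protein", "embedding", "sets"])
        _add_common_files(b, "fixture")
        v_rna = b.add_view("scatterplot", "fixture", x=0, y=0, w=2, h=2, uid="rna-scatter")
        v_adt = b.add_view("scatterplot", "fixture", x=2, y=0, w=2, h=2, uid="protein-scatter")
        v_hm = b.add_view("heatmap", "fixture", x=0, y=2, w=4, h=2, uid="rna-heatmap")
        markers = _marker_gene_names(fixture_dir)
        b.link_views([v_rna, v_adt, v_hm], "featureSelection", [markers[0], "prot_000"])
        b.link_views([v_rna, v_adt], "obsColorEncoding", "featureValue")
        zoom, tx, ty = fit_camera(_embedding_bounds(fixture_dir), panel, panel)
        for ctype, val in (
            ("embeddingZoom", zoom),
            ("embeddingTargetX", tx),
            ("embeddingTargetY", ty),
        ):
            b.link_views([v_rna, v_adt], ctype, val)
        # the protein view reads the protein modality
        b.link_views([v_adt], "featureType", "protein")
        b.link_views([v_adt], "featureValueType", "intensity")
        b.link_views([v_rna, v_adt], "embeddingObsRadius", 2.0)
    elif template == "smfish-like":
        _require(
            fixture_dir,
            ["expression", "locations", "sets", "image", "segmentation"],
        )
        _add_common_files(b, "fixture")
        v_sp = b.add_view("spatial", "fixture", x=0, y=0, w=3, h=3, uid="spatial")
        v_hm = b.add_view("heatmap", "fixture", x=3, y=0, w=2, h=3, uid="heatmap")
        markers = _marker_gene_names(fixture_dir)
        b.link_views([v_sp, v_hm], "featureSelection", markers)
        b.link_views([v_sp], "obsColorEncoding", "featureValue")
        h, w = _image_size(fixture_dir)
        zoom, tx, ty = fit_camera((0, 0, w, h), 3 * PX_PER_GRID_UNIT, 3 * PX_PER_GRID_UNIT)
        b.link_views([v_sp], "spatialZoom", zoom)
        b.link_views([v_sp], "spatialTargetX", tx)
        b.link_views([v_sp], "spatialTargetY", ty)
        b.link_views([v_sp], "spotRadius", 2.0)
        b.link_views([v_sp], "pointLayerVisible", False)
    else:  # visium-like
        _require(fixture_dir, ["expression", "locations", "embedding", "sets", "image"])
        _add_common_files(b, "fixture")
        v_sp = b.add_view("spatial", "fixture", x=0, y=0, w=2, h=2, uid="spatial")
        v_sc = b.add_view("scatterplot", "fixture", x=2, y=0, w=2, h=2, uid="scatter")
        v_sz = b.add_view("obsSetSizes", "fixture", x=0, y=2, w=2, h=2, uid="set-sizes")
        v_hi = b.add_view(
            "featureValueHistogram", "fixture", x=2, y=2, w=2, h=2, uid="histogram"
        )
        markers = _marker_gene_names(fixture_dir)
        b.link_views([v_sp, v_sc], "obsColorEncoding", "setMembership")
        b.link_views([v_hi], "featureSelection", [markers[0]])
        h, w = _image_size(fixture_dir)
        zoom, tx, ty = fit_camera((0, 0, w, h), panel, panel)
        b.link_views([v_sp], "spatialZoom", zoom)
        b.link_views([v_sp], "spatialTargetX", tx)
        b.link_views([v_sp], "spatialTargetY", ty)
        b.link_views([v_sp], "spotRadius", 3.0)
        b.link_views([v_sp], "segmentationLayerVisible", False)
        ez, ex, ey = fit_camera(_embedding_bounds(fixture_dir), panel, panel)
        b.link_views([v_sc], "embeddingZoom", ez)
        b.link_views([v_sc], "embeddingTargetX", ex)
        b.link_views([v_sc], "embeddingTargetY", ey)
        b.link_views([v_sc], "embeddingObsRadius", 2.0)
    return b.build()
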