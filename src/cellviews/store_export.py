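"""Write matrices, images and annotations to chunked stores.

The chunk geometry of an observation-by-feature store decides its access
cost: fetching one feature across all observations touches one chunk
per chunk-row, so the per-feature pattern packs many observations and
few features into each chunk (and the per-observation pattern is its
transpose mirror). Stores are plain directories of static objects — a
dumb file server (or local disk) is all that is needed to serve them.

Stores are written in Zarr v2 directory layout with a DEFLATE-family
codec; image pyramids carry OME-style multiscale metadata. Intensity
pyramids reduce levels by 2x2 block means; bitmask (label) pyramids by
top-left stride sampling, since label values are categorical and must
never be averaged.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numcodecs
import numpy as np
import zarr

from .errors import StoreExportError
from .loaders import DenseMatrix

__all__ = [
    "ChunkPlan",
    "StoreSizeReport",
    "plan_chunks",
    "export_matrix",
    "export_image_pyramid",
    "build_pyramid_levels",
    "export_sets",
    "store_size_report",
    "delimited_text_bytes",
]

#: Per-feature pattern caps: few features, many observations per chunk.
FEATURES_PER_CHUNK_SMALL = 10
OBS_PER_CHUNK_CAP = 4096
BALANCED_CAP = 256

_CODECS = {
    "zlib": numcodecs.Zlib,
    "gzip": numcodecs.GZip,
    "zstd": numcodecs.Zstd,
}


@dataclass(frozen=True)
class ChunkPlan:
    """Chunk geometry and compression for one matrix store."""

    chunk_shape: tuple[int, int]  # (obs per chunk, features per chunk)
    codec: str = "zlib"
    level: int = 5
    target_pattern: str = "per-feature"

    def compressor(self):
        try:
            return _CODECS[self.codec](level=self.level)
        except KeyError:
            raise StoreExportError(f"unknown codec {self.codec!r}") from None


def plan_chunks(
    n_obs: int,
    n_features: int,
    target_pattern: str = "per-feature",
    codec: str = "zlib",
    level: int = 5,
) -> ChunkPlan:
    """Choose a chunk shape optimizing the given access pattern.

    ``per-feature``: whole-feature fetches cheap — many observations
    (up to 4096) and few features (up to 10) per chunk. A one-feature
    fetch then costs ``ceil(n_obs / obs_per_chunk)`` chunks.
    ``per-observation`` is the transpose mirror; ``balanced`` caps both
    dimensions equally.
    """
    if n_obs < 1 or n_features < 1:
        raise StoreExportError("matrix dimensions must be >= 1 to plan chunks")
    if target_pattern == "per-feature":
        shape = (min(n_obs, OBS_PER_CHUNK_CAP), min(n_features, FEATURES_PER_CHUNK_SMALL))
    elif target_pattern == "per-observation":
        shape = (min(n_obs, FEATURES_PER_CHUNK_SMALL), min(n_features, OBS_PER_CHUNK_CAP))
    elif target_pattern == "balanced":
        shape = (min(n_obs, BALANCED_CAP), min(n_features, BALANCED_CAP))
    else:
        raise StoreExportError(f"unknown target pattern {target_pattern!r}")
    return ChunkPlan(shape, codec, level, target_pattern)


def export_matrix(
    matrix: DenseMatrix, out_path: str | Path, plan: Optional[ChunkPlan] = None
) -> Path:
    """Write a matrix to a chunked store; round-trips exactly on re-open.

    Refuses non-finite values before writing anything. The resulting
    directory opens with
    :meth:`~cellviews.loaders.ChunkedMatrixHandle.open_store`.
    """
    values = np.asarray(matrix.values)
    if values.size and np.issubdtype(values.dtype, np.floating):
        if not np.isfinite(values).all():
            raise StoreExportError(
                "matrix contains non-finite values; refusing to export"
            )
    n_obs, n_feat = values.shape
    if plan is None:
        plan = plan_chunks(max(n_obs, 1), max(n_feat, 1))
    c0 = max(1, min(plan.chunk_shape[0], max(n_obs, 1)))
    c1 = max(1, min(plan.chunk_shape[1], max(n_feat, 1)))
    out = Path(out_path)
    root = zarr.open_group(str(out), mode="w", zarr_format=2)
    root.attrs["obsIds"] = list(matrix.obs_ids)
    root.attrs["featureIds"] = list(matrix.feature_ids)
    root.attrs["chunkPlan"] = {
        "chunkShape": [c0, c1],
        "codec": plan.codec,
        "level": plan.level,
        "targetPattern": plan.target_pattern,
    }
    arr = root.create_array(
        "matrix",
        shape=values.shape,
        chunks=(c0, c1),
        dtype=values.dtype,
        compressors=plan.compressor(),
    )
    if values.size:
        arr[:, :] = values
    return out


def build_pyramid_levels(
    image: np.ndarray, n_levels: int, is_bitmask: bool = False
) -> list[np.ndarray]:
    """Downsampled levels of a (C, Y, X) image; level 0 is the input.

    Each level halves Y and X (ceil): 2x2 block means for intensity
    images, top-left stride sampling for bitmasks.
    """
    image = np.asarray(image)
    if image.ndim != 3:
        raise StoreExportError(f"expected (C, Y, X) image, got shape {image.shape}")
    if n_levels < 1:
        raise StoreExportError("n_levels must be >= 1")
    _, h, w = image.shape
    if 2 ** (n_levels - 1) > max(h, w):
        raise StoreExportError(
            f"{n_levels} levels would give an empty level for a {h}x{w} image"
        )
    levels = [image]
    current = image
    for _ in range(1, n_levels):
        if is_bitmask:
            current = current[:, ::2, ::2]
        else:
            current = _halve_mean(current)
        levels.append(current)
    return levels


def _halve_mean(arr: np.ndarray) -> np.ndarray:
    """2x2 block means along Y and X (ragged edge blocks use their own
    true mean), preserving channel axis."""
    c, h, w = arr.shape
    hh, hw = -(-h // 2), -(-w // 2)
    out = np.empty((c, hh, hw), dtype=np.result_type(arr.dtype, np.float64))
    acc = arr.astype(np.float64)
    ys = np.arange(0, h, 2)
    xs = np.arange(0, w, 2)
    sums = np.add.reduceat(np.add.reduceat(acc, ys, axis=1), xs, axis=2)
    ycnt = np.minimum(ys + 2, h) - ys
    xcnt = np.minimum(xs + 2, w) - xs
    counts = np.outer(ycnt, xcnt)[None, :, :]
    out[:] = sums / counts
    if np.issubdtype(arr.dtype, np.integer):
        return out  # promoted to float: means of counts are fractional
    return out.astype(arr.dtype)


def export_image_pyramid(
    image: np.ndarray,
    out_path: str | Path,
    n_levels: int,
    tile_size: int = 256,
    is_bitmask: bool = False,
    channel_names: Optional[Sequence[str]] = None,
    codec: str = "zlib",
    level: int = 5,
) -> Path:
    """Write a (C, Y, X) image as an OME-style multiscale chunked store."""
    levels = build_pyramid_levels(image, n_levels, is_bitmask=is_bitmask)
    out = Path(out_path)
    root = zarr.open_group(str(out), mode="w", zarr_format=2)
    datasets = []
    compressor = _CODECS[codec](level=level) if codec in _CODECS else None
    if compressor is None:
        raise StoreExportError(f"unknown codec {codec!r}")
    for i, lv in enumerate(levels):
        arr = root.create_array(
            str(i),
            shape=lv.shape,
            chunks=(1, min(tile_size, lv.shape[1]), min(tile_size, lv.shape[2])),
            dtype=lv.dtype,
            compressors=compressor,
        )
        arr[:] = lv
        factor = 2 ** i
        datasets.append(
            {
                "path": str(i),
                "coordinateTransformations": [
                    {"type": "scale", "scale": [1, float(factor), float(factor)]}
                ],
            }
        )
    root.attrs["multiscales"] = [
        {
            "version": "0.4",
            "axes": [
                {"name": "c", "type": "channel"},
                {"name": "y", "type": "space"},
                {"name": "x", "type": "space"},
            ],
            "datasets": datasets,
        }
    ]
    if is_bitmask:
        root.attrs["image-label"] = {"source": {}}
    if channel_names is not None:
        root.attrs["omero"] = {
            "channels": [{"label": str(n)} for n in channel_names]
        }
    return out


def export_sets(hierarchy, out_path: str | Path) -> Path:
    """Write a set hierarchy as its JSON document."""
    import json

    out = Path(out_path)
    out.write_text(
        json.dumps(hierarchy.to_dict(), sort_keys=True, indent=1) + "\n",
        "utf-8",
    )
    return out


@dataclass(frozen=True)
class StoreSizeReport:
    """Size/access trade-off of a chunked store vs. delimited text."""

    stored_bytes: int
    equivalent_delimited_text_bytes: int
    chunk_count: int
    per_feature_fetch_chunks: int
    per_observation_fetch_chunks: int


def delimited_text_bytes(matrix: DenseMatrix) -> int:
    """Bytes of the same matrix as delimited text, full-precision floats."""
    lines = ["," + ",".join(matrix.feature_ids)]
    values = matrix.values
    floating = values.size and np.issubdtype(values.dtype, np.floating)
    for i, oid in enumerate(matrix.obs_ids):
        row = values[i]
        if floating:
            cells = [repr(float(v)) for v in row]
        else:
            cells = [str(v) for v in row]
        lines.append(oid + "," + ",".join(cells))
    return len(("\n".join(lines) + "\n").encode("utf-8"))


def store_size_report(store_path: str | Path, matrix: DenseMatrix) -> StoreSizeReport:
    """Measure a written store against its delimited-text equivalent."""
    store_path = Path(store_path)
    stored = sum(
        f.stat().st_size for f in store_path.rglob("*") if f.is_file()
    )
    root = zarr.open_group(str(store_path), mode="r")
    arr = root["matrix"]
    n_obs, n_feat = arr.shape
    c0, c1 = arr.chunks
    chunk_count = math.ceil(n_obs / c0) * math.ceil(n_feat / c1) if n_obs and n_feat else 0
    return StoreSizeReport(
        stored_bytes=stored,
        equivalent_delimited_text_bytes=delimited_text_bytes(matrix),
        chunk_count=chunk_count,
        per_feature_fetch_chunks=math.ceil(n_obs / c0) if n_obs else 0,
        per_observation_fetch_chunks=math.ceil(n_feat / c1) if n_feat else 0,
    )
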