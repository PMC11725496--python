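"""File-type loaders: full loads, lazy subset loads, and access accounting.

Every file type has a required full-load path (:func:`load_full`) that
validates content and returns a dense in-memory payload. Chunked-store
formats additionally support *subset* loading through handles
(:class:`ChunkedMatrixHandle`, :class:`ImagePyramid`) that read only the
chunks intersecting a request. To make that laziness testable rather
than aspirational, every handle records the chunk indices actually
fetched from storage in an append-only access log; a small per-handle
LRU cache sits in front of storage, and the log records fetches, not
cache hits.

Conventions: all indexing is 0-based with half-open ranges; images use
raster orientation (origin top-left, y down); CSVs are comma-separated,
first row header, first column the observation id, UTF-8.
"""

from __future__ import annotations

import json
import re
from collections import OrderedDict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Optional, Sequence

import numpy as np
import pandas as pd
import zarr
from zarr.storage import LocalStore

from .errors import (
    DataIOError,
    DataValidationError,
    RequestError,
)

__all__ = [
    "DenseMatrix",
    "ObservationTable",
    "SetNode",
    "SetHierarchy",
    "ChunkedMatrixHandle",
    "ImagePyramid",
    "load_full",
    "open_matrix",
    "open_pyramid",
    "load_matrix_subset",
    "load_image_tile",
    "chunks_intersecting",
]


def _resolve_path(url: str, base_dir: Optional[str]) -> Path:
    if re.match(r"^[a-z][a-z0-9+.-]*://", url) and not url.startswith("file://"):
        raise NotImplementedError(
            "remote URL loading is not implemented; stores are plain "
            "directories of static files — fetch them locally first"
        )
    if url.startswith("file://"):
        url = url[len("file://") :]
    p = Path(url)
    if not p.is_absolute() and base_dir is not None:
        p = Path(base_dir) / p
    return p


# ---------------------------------------------------------------------------
# payload containers


@dataclass
class DenseMatrix:
    """A fully materialized observation-by-feature matrix."""

    obs_ids: list[str]
    feature_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.shape != (len(self.obs_ids), len(self.feature_ids)):
            raise DataValidationError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.obs_ids)} observations x {len(self.feature_ids)} features"
            )
        for label, ids in (("obs", self.obs_ids), ("feature", self.feature_ids)):
            if len(set(ids)) != len(ids):
                raise DataValidationError(f"duplicate {label} ids")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


class ObservationTable:
    """Per-observation columns (coordinates, memberships) keyed by obs id."""

    def __init__(self, frame: pd.DataFrame):
        if frame.index.has_duplicates:
            dups = frame.index[frame.index.duplicated()].unique().tolist()
            raise DataValidationError(f"duplicate observation ids: {dups[:5]}")
        self.frame = frame

    @property
    def obs_ids(self) -> list[str]:
        return [str(i) for i in self.frame.index]

    def __len__(self) -> int:
        return len(self.frame)

    def column(self, name: str) -> np.ndarray:
        if name not in self.frame.columns:
            raise DataValidationError(f"missing required column {name!r}")
        return self.frame[name].to_numpy()

    def coords(self, names: Sequence[str] = ("x", "y")) -> np.ndarray:
        cols = [self.column(n) for n in names]
        out = np.column_stack(cols).astype(float)
        if not np.isfinite(out).all():
            raise DataValidationError(
                f"non-finite values in columns {list(names)}"
            )
        return out


@dataclass
class SetNode:
    """A node in an observation-set hierarchy; leaves hold member ids."""

    name: str
    color: Optional[tuple[int, int, int]] = None
    children: list["SetNode"] = field(default_factory=list)
    obs_ids: Optional[list[str]] = None

    @property
    def is_leaf(self) -> bool:
        return self.obs_ids is not None


class SetHierarchy:
    """Tree of named observation sets (flat or hierarchical annotations).

    Within one root, every observation id belongs to at most one leaf,
    so each root is a (possibly partial) partition of the observations
    — e.g. one root per clustering resolution.
    """

    def __init__(self, roots: list[SetNode]):
        self.roots = roots
        for root in roots:
            seen: set[str] = set()
            for _, node in self.iter_leaves(root):
                for oid in node.obs_ids or []:
                    if oid in seen:
                        raise DataValidationError(
                            f"observation {oid!r} appears in more than one "
                            f"leaf under root {root.name!r}"
                        )
                    seen.add(oid)

    @staticmethod
    def _node_from_dict(d: Any, visiting: set[int], path: str) -> SetNode:
        if id(d) in visiting:
            raise DataValidationError(f"cycle detected in set tree at {path}")
        if not isinstance(d, dict) or "name" not in d:
            raise DataValidationError(f"set node at {path} must have a name")
        visiting.add(id(d))
        color = tuple(d["color"]) if "color" in d else None
        if "children" in d and "set" in d:
            raise DataValidationError(
                f"node {d['name']!r} has both children and a member set"
            )
        if "children" in d:
            children = [
                SetHierarchy._node_from_dict(c, visiting, f"{path}/{d['name']}")
                for c in d["children"]
            ]
            node = SetNode(d["name"], color, children, None)
        else:
            members = d.get("set", [])
            if not all(isinstance(m, str) for m in members):
                raise DataValidationError(
                    f"member ids of {d['name']!r} must be strings"
                )
            node = SetNode(d["name"], color, [], list(members))
        visiting.discard(id(d))
        return node

    @classmethod
    def from_dict(cls, doc: Any) -> "SetHierarchy":
        if not isinstance(doc, dict) or "tree" not in doc:
            raise DataValidationError("set hierarchy must have a 'tree' key")
        visiting: set[int] = set()
        return cls(
            [cls._node_from_dict(n, visiting, "/tree") for n in doc["tree"]]
        )

    def to_dict(self) -> dict:
        def node_dict(n: SetNode) -> dict:
            out: dict[str, Any] = {"name": n.name}
            if n.color is not None:
                out["color"] = list(n.color)
            if n.is_leaf:
                out["set"] = list(n.obs_ids or [])
            else:
                out["children"] = [node_dict(c) for c in n.children]
            return out

        return {"version": "0.1", "tree": [node_dict(r) for r in self.roots]}

    def iter_leaves(self, root: Optional[SetNode] = None):
        """Yield (path, node) for every leaf, depth-first."""

        def walk(node: SetNode, path: tuple[str, ...]):
            path = path + (node.name,)
            if node.is_leaf:
                yield path, node
            for c in node.children:
                yield from walk(c, path)

        roots = [root] if root is not None else self.roots
        for r in roots:
            yield from walk(r, ())

    def membership(self, root_index: int = 0) -> dict[str, tuple[str, ...]]:
        """obs id -> leaf path under the given root."""
        out: dict[str, tuple[str, ...]] = {}
        for path, node in self.iter_leaves(self.roots[root_index]):
            for oid in node.obs_ids or []:
                out[oid] = path
        return out


# ---------------------------------------------------------------------------
# chunk accounting


_CHUNK_SEG = re.compile(r"^\d+(\.\d+)*$")


class _CountingStore(LocalStore):
    """Local zarr store that logs chunk fetches and LRU-caches chunk bytes.

    The log records storage fetches only — a request served from the
    cache does not append. Metadata keys are never logged or cached.
    """

    def __init__(self, root: str | Path, cache_size: int = 128):
        super().__init__(root=str(root), read_only=True)
        self.fetch_log: list[str] = []
        self._cache: OrderedDict[str, Any] = OrderedDict()
        self._cache_size = cache_size

    @staticmethod
    def _is_chunk_key(key: str) -> bool:
        last = key.rsplit("/", 1)[-1]
        if last.startswith("."):  # .zarray/.zgroup/.zattrs
            return False
        if last == "zarr.json":
            return False
        if "/c/" in key or key.startswith("c/"):
            return True
        return bool(_CHUNK_SEG.match(last))

    async def get(self, key, prototype=None, byte_range=None):
        if byte_range is None and self._is_chunk_key(key):
            if key in self._cache:
                self._cache.move_to_end(key)
                return self._cache[key]
            self.fetch_log.append(key)
            buf = await super().get(key, prototype, byte_range)
            if buf is not None:
                self._cache[key] = buf
                if len(self._cache) > self._cache_size:
                    self._cache.popitem(last=False)
            return buf
        return await super().get(key, prototype, byte_range)

    def chunk_indices_for(self, array_path: str) -> list[tuple[int, ...]]:
        """Translate logged keys into chunk-grid indices of one array."""
        prefix = f"{array_path}/" if array_path else ""
        out: list[tuple[int, ...]] = []
        for key in self.fetch_log:
            if not key.startswith(prefix):
                continue
            rest = key[len(prefix) :]
            if rest.startswith("c/"):  # v3 layout
                parts = rest[2:].split("/")
            elif "/" in rest:  # a nested array's chunk, not ours
                continue
            else:  # v2 layout: "i.j"
                parts = rest.split(".")
            if parts and all(p.isdigit() for p in parts):
                out.append(tuple(int(p) for p in parts))
        return out


def chunks_intersecting(
    shape: tuple[int, int],
    chunk_shape: tuple[int, int],
    rows: Sequence[int],
    cols: Sequence[int],
) -> set[tuple[int, int]]:
    """Brute-force set of chunk indices a (rows x cols) selection touches."""
    row_chunks = {r // chunk_shape[0] for r in rows}
    col_chunks = {c // chunk_shape[1] for c in cols}
    return {(i, j) for i in row_chunks for j in col_chunks}


# ---------------------------------------------------------------------------
# chunked matrix handle


class ChunkedMatrixHandle:
    """Lazily readable observation-by-feature matrix over a chunked store.

    ``access_log`` lists the chunk indices fetched from storage so far,
    in fetch order. In-memory handles (wrapping a dense matrix) present
    the same interface with a single virtual chunk.
    """

    def __init__(
        self,
        array,
        obs_ids: list[str],
        feature_ids: list[str],
        store: Optional[_CountingStore] = None,
        array_path: str = "",
    ):
        self._array = array
        self._store = store
        self._array_path = array_path
        self.obs_ids = [str(i) for i in obs_ids]
        self.feature_ids = [str(i) for i in feature_ids]
        if array.shape != (len(self.obs_ids), len(self.feature_ids)):
            raise DataValidationError(
                f"store array shape {array.shape} does not match id lists "
                f"({len(self.obs_ids)}, {len(self.feature_ids)})"
            )
        self._feature_index = {f: i for i, f in enumerate(self.feature_ids)}

    @property
    def shape(self) -> tuple[int, int]:
        return tuple(self._array.shape)

    @property
    def chunk_shape(self) -> tuple[int, int]:
        ch = getattr(self._array, "chunks", None)
        return tuple(ch) if ch is not None else self.shape

    @property
    def access_log(self) -> list[tuple[int, ...]]:
        if self._store is None:
            return []
        return self._store.chunk_indices_for(self._array_path)

    # -- opening ---------------------------------------------------------

    @classmethod
    def open_store(
        cls,
        path: str | Path,
        array_path: str = "matrix",
        base_dir: Optional[str] = None,
        cache_size: int = 128,
    ) -> "ChunkedMatrixHandle":
        """Open a matrix store written by :mod:`cellviews.store_export`."""
        p = _resolve_path(str(path), base_dir)
        if not p.exists():
            raise DataIOError(f"store not found: {p}")
        store = _CountingStore(p, cache_size=cache_size)
        try:
            root = zarr.open_group(store=store, mode="r")
            arr = root[array_path]
            obs_ids = root.attrs["obsIds"]
            feature_ids = root.attrs["featureIds"]
        except (KeyError, Exception) as exc:  # noqa: BLE001 - classify below
            if isinstance(exc, KeyError):
                raise DataValidationError(
                    f"store at {p} lacks required member: {exc}"
                ) from exc
            raise DataIOError(f"cannot open store at {p}: {exc}") from exc
        return cls(arr, list(obs_ids), list(feature_ids), store, array_path)

    @classmethod
    def open_anndata(
        cls,
        path: str | Path,
        matrix_path: str = "X",
        base_dir: Optional[str] = None,
        cache_size: int = 128,
    ) -> "ChunkedMatrixHandle":
        """Open the matrix inside an AnnData-style obs/var/obsm layout."""
        p = _resolve_path(str(path), base_dir)
        if not p.exists():
            raise DataIOError(f"store not found: {p}")
        store = _CountingStore(p, cache_size=cache_size)
        root = zarr.open_group(store=store, mode="r")
        try:
            arr = root[matrix_path]
            obs_ids = [str(x) for x in root["obs/_index"][:]]
            var_ids = [str(x) for x in root["var/_index"][:]]
        except KeyError as exc:
            raise DataValidationError(
                f"AnnData-style store at {p} lacks member {exc}"
            ) from exc
        return cls(arr, obs_ids, var_ids, store, matrix_path)

    @classmethod
    def in_memory(
        cls, matrix: DenseMatrix, chunk_shape: Optional[tuple[int, int]] = None
    ) -> "ChunkedMatrixHandle":
        return cls(matrix.values, matrix.obs_ids, matrix.feature_ids)

    # -- reading ---------------------------------------------------------

    def load_full(self) -> DenseMatrix:
        return DenseMatrix(
            list(self.obs_ids), list(self.feature_ids), np.asarray(self._array[:, :])
        )

    def load_subset(
        self,
        feature_ids: Sequence[str],
        obs_range: Optional[tuple[int, int]] = None,
    ) -> np.ndarray:
        """Dense block for the requested features (all or a half-open
        observation range); reads only intersecting chunks, each once."""
        unknown = [f for f in feature_ids if f not in self._feature_index]
        if unknown:
            raise RequestError(f"unknown feature ids: {unknown}")
        n_obs = self.shape[0]
        if obs_range is None:
            obs_range = (0, n_obs)
        lo, hi = obs_range
        if not (0 <= lo <= hi <= n_obs):
            raise RequestError(
                f"observation range {obs_range} outside [0, {n_obs}]"
            )
        cols = [self._feature_index[f] for f in feature_ids]
        order = np.unique(cols)
        if lo == hi or len(cols) == 0:
            return np.empty((hi - lo, len(cols)), dtype=self._array.dtype)
        if hasattr(self._array, "oindex"):
            block = self._array.oindex[slice(lo, hi), order]
        else:
            block = np.asarray(self._array)[lo:hi][:, order]
        # restore the requested column order (duplicates allowed)
        pos = {c: k for k, c in enumerate(order)}
        return np.asarray(block)[:, [pos[c] for c in cols]]


def load_matrix_subset(
    handle: ChunkedMatrixHandle,
    feature_ids: Sequence[str],
    obs_range: Optional[tuple[int, int]] = None,
) -> np.ndarray:
    return handle.load_subset(feature_ids, obs_range)


# ---------------------------------------------------------------------------
# image pyramids


class ImagePyramid:
    """Multiscale multichannel raster addressed by (level, tile) on demand.

    Level ``L`` is the level-0 image downsampled by ``2**L``; arrays are
    (C, Y, X). Bitmask pyramids (label images whose pixel values are
    observation ids, 0 = background) load through the identical path.
    """

    def __init__(
        self,
        levels: list,
        tile_size: int,
        is_bitmask: bool = False,
        store: Optional[_CountingStore] = None,
        level_paths: Optional[list[str]] = None,
        channel_names: Optional[list[str]] = None,
    ):
        if not levels:
            raise DataValidationError("pyramid must have at least one level")
        self.levels = levels
        self.tile_size = int(tile_size)
        self.is_bitmask = is_bitmask
        self._store = store
        self._level_paths = level_paths or [str(i) for i in range(len(levels))]
        self.channel_names = channel_names

    @property
    def n_levels(self) -> int:
        return len(self.levels)

    @property
    def n_channels(self) -> int:
        return self.levels[0].shape[0]

    def downsample_factor(self, level: int) -> int:
        return 2 ** level

    def level_shape(self, level: int) -> tuple[int, int, int]:
        return tuple(self.levels[level].shape)

    def tile_grid(self, level: int) -> tuple[int, int]:
        """(tiles in x, tiles in y) for a level."""
        _, h, w = self.level_shape(level)
        ts = self.tile_size
        return (-(-w // ts), -(-h // ts))

    def access_log(self, level: int) -> list[tuple[int, ...]]:
        if self._store is None:
            return []
        return self._store.chunk_indices_for(self._level_paths[level])

    @classmethod
    def open_store(
        cls, path: str | Path, base_dir: Optional[str] = None, cache_size: int = 64
    ) -> "ImagePyramid":
        """Open an OME-style multiscale store written by store_export."""
        p = _resolve_path(str(path), base_dir)
        if not p.exists():
            raise DataIOError(f"image store not found: {p}")
        store = _CountingStore(p, cache_size=cache_size)
        root = zarr.open_group(store=store, mode="r")
        attrs = dict(root.attrs)
        try:
            ms = attrs["multiscales"][0]
            paths = [d["path"] for d in ms["datasets"]]
        except (KeyError, IndexError) as exc:
            raise DataValidationError(
                f"store at {p} lacks OME-style multiscales metadata"
            ) from exc
        levels = [root[pp] for pp in paths]
        ts = levels[0].chunks[-1]
        names = None
        omero = attrs.get("omero")
        if omero and "channels" in omero:
            names = [c.get("label", str(i)) for i, c in enumerate(omero["channels"])]
        return cls(
            levels,
            tile_size=ts,
            is_bitmask="image-label" in attrs,
            store=store,
            level_paths=paths,
            channel_names=names,
        )

    @classmethod
    def from_array(
        cls, image: np.ndarray, n_levels: int, tile_size: int = 256,
        is_bitmask: bool = False,
    ) -> "ImagePyramid":
        """Build an in-memory pyramid from a (C, Y, X) array."""
        from .store_export import build_pyramid_levels

        return cls(
            build_pyramid_levels(image, n_levels, is_bitmask=is_bitmask),
            tile_size=tile_size,
            is_bitmask=is_bitmask,
        )

    def load_tile(
        self,
        level: int,
        tile_x: int,
        tile_y: int,
        channels: Optional[Sequence[int]] = None,
        t: int = 0,
        z: int = 0,
    ) -> np.ndarray:
        """Load one tile; edge tiles may be smaller than ``tile_size``.

        Only the chunks of that tile are read (tiles coincide with the
        storage chunk grid for stores written by this package).
        """
        if not (0 <= level < self.n_levels):
            raise RequestError(f"level {level} outside pyramid (n={self.n_levels})")
        if t != 0 or z != 0:
            raise RequestError("store holds a single timepoint and z-plane")
        ntx, nty = self.tile_grid(level)
        if not (0 <= tile_x < ntx and 0 <= tile_y < nty):
            raise RequestError(
                f"tile ({tile_x}, {tile_y}) outside {ntx}x{nty} grid of level {level}"
            )
        arr = self.levels[level]
        c, h, w = arr.shape
        ts = self.tile_size
        ys = slice(tile_y * ts, min((tile_y + 1) * ts, h))
        xs = slice(tile_x * ts, min((tile_x + 1) * ts, w))
        if channels is None:
            channels = list(range(c))
        bad = [ch for ch in channels if not 0 <= ch < c]
        if bad:
            raise RequestError(f"channel indices out of range: {bad}")
        if hasattr(arr, "oindex"):
            tile = arr.oindex[np.asarray(sorted(set(channels))), ys, xs]
            order = sorted(set(channels))
            pos = {ch: k for k, ch in enumerate(order)}
            return np.asarray(tile)[[pos[ch] for ch in channels]]
        return np.asarray(arr)[list(channels), ys, xs]


def load_image_tile(
    pyramid: ImagePyramid,
    level: int,
    tile_x: int,
    tile_y: int,
    channels: Optional[Sequence[int]] = None,
    t: int = 0,
    z: int = 0,
) -> np.ndarray:
    return pyramid.load_tile(level, tile_x, tile_y, channels, t, z)


# ---------------------------------------------------------------------------
# full loads per file type


def _read_csv(path: Path) -> pd.DataFrame:
    if not path.exists():
        raise DataIOError(f"file not found: {path}")
    try:
        return pd.read_csv(path, index_col=0, encoding="utf-8")
    except OSError as exc:
        raise DataIOError(f"cannot read {path}: {exc}") from exc
    except Exception as exc:
        raise DataValidationError(f"malformed CSV {path}: {exc}") from exc


def _load_matrix_csv(acc, base_dir) -> DenseMatrix:
    frame = _read_csv(_resolve_path(acc.url, base_dir))
    values = frame.to_numpy()
    if values.size and not np.issubdtype(values.dtype, np.number):
        raise DataValidationError(
            f"matrix CSV {acc.url} has non-numeric values"
        )
    return DenseMatrix(
        [str(i) for i in frame.index],
        [str(c) for c in frame.columns],
        values.astype(float) if values.size else values.reshape(frame.shape),
    )


def _load_locations_csv(acc, base_dir) -> ObservationTable:
    table = ObservationTable(_read_csv(_resolve_path(acc.url, base_dir)))
    table.coords(("x", "y"))  # validates presence and finiteness
    return table


def _load_embedding_csv(acc, base_dir) -> ObservationTable:
    table = ObservationTable(_read_csv(_resolve_path(acc.url, base_dir)))
    if len(table.frame.columns) < 2:
        raise DataValidationError(
            f"embedding CSV {acc.url} needs at least 2 coordinate columns"
        )
    return table


def _load_sets_json(acc, base_dir) -> SetHierarchy:
    p = _resolve_path(acc.url, base_dir)
    if not p.exists():
        raise DataIOError(f"file not found: {p}")
    try:
        doc = json.loads(p.read_text("utf-8"))
    except json.JSONDecodeError as exc:
        raise DataValidationError(f"malformed JSON {p}: {exc}") from exc
    return SetHierarchy.from_dict(doc)


def _load_matrix_zarr(acc, base_dir) -> DenseMatrix:
    return open_matrix(acc, base_dir).load_full()


def _load_image_tiff(acc, base_dir) -> ImagePyramid:
    import tifffile

    p = _resolve_path(acc.url, base_dir)
    if not p.exists():
        raise DataIOError(f"file not found: {p}")
    arr = tifffile.imread(p)
    if arr.ndim == 2:
        arr = arr[None, :, :]
    return ImagePyramid.from_array(arr, n_levels=1)


def open_matrix(acc, base_dir: Optional[str] = None) -> ChunkedMatrixHandle:
    """Open a lazily readable handle for a matrix accessor of any format."""
    if acc.file_type == "obsFeatureMatrix.zarr":
        return ChunkedMatrixHandle.open_store(
            acc.url, acc.options.get("path", "matrix"), base_dir
        )
    if acc.file_type == "anndata.zarr":
        return ChunkedMatrixHandle.open_anndata(
            acc.url, acc.options.get("matrixPath", "X"), base_dir
        )
    if acc.file_type == "obsFeatureMatrix.csv":
        return ChunkedMatrixHandle.in_memory(_load_matrix_csv(acc, base_dir))
    raise DataValidationError(
        f"file type {acc.file_type!r} does not expose a matrix"
    )


def open_pyramid(acc, base_dir: Optional[str] = None) -> ImagePyramid:
    if acc.file_type in ("image.ome-zarr", "obsSegmentations.ome-zarr"):
        return ImagePyramid.open_store(acc.url, base_dir)
    if acc.file_type == "image.ome-tiff":
        return _load_image_tiff(acc, base_dir)
    raise DataValidationError(
        f"file type {acc.file_type!r} does not expose an image pyramid"
    )


def _anndata_table(acc, base_dir, path_key: str) -> ObservationTable:
    p = _resolve_path(acc.url, base_dir)
    store = _CountingStore(p)
    root = zarr.open_group(store=store, mode="r")
    rel = acc.options[path_key]
    try:
        coords = np.asarray(root[rel][:])
        obs_ids = [str(x) for x in root["obs/_index"][:]]
    except KeyError as exc:
        raise DataValidationError(
            f"AnnData-style store at {p} lacks member {exc}"
        ) from exc
    frame = pd.DataFrame(
        coords[:, :2], index=obs_ids, columns=["x", "y"]
    )
    return ObservationTable(frame)


_LOADERS = {
    ("obsFeatureMatrix.csv", "obsFeatureMatrix"): _load_matrix_csv,
    ("obsLocations.csv", "obsLocations"): _load_locations_csv,
    ("obsEmbedding.csv", "obsEmbedding"): _load_embedding_csv,
    ("obsSets.json", "obsSets"): _load_sets_json,
    ("obsFeatureMatrix.zarr", "obsFeatureMatrix"): _load_matrix_zarr,
    ("image.ome-zarr", "image"): lambda a, b: open_pyramid(a, b),
    ("obsSegmentations.ome-zarr", "obsSegmentations"): lambda a, b: open_pyramid(a, b),
    ("image.ome-tiff", "image"): _load_image_tiff,
    ("anndata.zarr", "obsFeatureMatrix"): _load_matrix_zarr,
    ("anndata.zarr", "obsEmbedding"): lambda a, b: _anndata_table(
        a, b, "embeddingPath"
    ),
    ("anndata.zarr", "obsLocations"): lambda a, b: _anndata_table(
        a, b, "locationsPath"
    ),
    ("anndata.zarr", "obsSets"): lambda a, b: _load_sets_json_rel(a, b),
}


def _load_sets_json_rel(acc, base_dir) -> SetHierarchy:
    # sets stored as a sidecar JSON path inside the store directory
    p = _resolve_path(acc.url, base_dir) / acc.options["setsPath"]
    if not p.exists():
        raise DataIOError(f"file not found: {p}")
    return SetHierarchy.from_dict(json.loads(p.read_text("utf-8")))


def load_full(acc, base_dir: Optional[str] = None):
    """Required full-load entry point: validate and return the payload
    for an accessor's data type (see :func:`~cellviews.data_model.expand_joint_file_type`)."""
    try:
        fn = _LOADERS[(acc.file_type, acc.data_type)]
    except KeyError:
        raise DataValidationError(
            f"no loader for file type {acc.file_type!r} / data type "
            f"{acc.data_type!r}"
        ) from None
    return fn(acc, base_dir)
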