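"""Viewport mathematics shared by image and heatmap rendering.

Pure functions: which pyramid level a zoom level warrants, which tiles a
viewport can see, and how to aggregate a matrix block onto a coarser
pixel grid without aliasing. The zoom convention is logarithmic:
``2**zoom`` screen pixels per data unit, so zoom 0 is a 1:1 mapping and
negative zooms are zoomed out.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "Viewport",
    "PyramidLevel",
    "select_pyramid_level",
    "visible_tiles",
    "data_bounds",
    "aggregate_matrix_to_pixels",
    "partition_bounds",
    "axis_tick_policy",
    "TICK_CHAR_WIDTH_PX",
]


@dataclass(frozen=True)
class Viewport:
    """A camera over data space: center, log2 zoom, and screen size."""

    target_x: float
    target_y: float
    zoom: float  # screen pixels per data unit = 2**zoom
    width_px: int
    height_px: int
    channels: tuple[int, ...] = ()
    t: int = 0
    z: int = 0

    def __post_init__(self) -> None:
        if self.width_px < 1 or self.height_px < 1:
            raise ValueError("viewport must be at least 1x1 screen pixels")

    @property
    def scale(self) -> float:
        return 2.0 ** self.zoom

    @property
    def data_px_per_screen_px(self) -> float:
        return 1.0 / self.scale


@dataclass(frozen=True)
class PyramidLevel:
    """Geometry of one pyramid level as seen by the viewport math."""

    index: int
    shape: tuple[int, int]  # (height, width) in level pixels
    tile_size: int

    def __post_init__(self) -> None:
        if self.tile_size < 1:
            raise ValueError("tile size must be >= 1")

    @property
    def downsample_factor(self) -> int:
        return 2 ** self.index


def data_bounds(viewport: Viewport) -> tuple[float, float, float, float]:
    """(x0, y0, x1, y1) rectangle of data space the viewport covers."""
    half_w = viewport.width_px / (2.0 * viewport.scale)
    half_h = viewport.height_px / (2.0 * viewport.scale)
    return (
        viewport.target_x - half_w,
        viewport.target_y - half_h,
        viewport.target_x + half_w,
        viewport.target_y + half_h,
    )


def select_pyramid_level(
    viewport: Viewport, levels: Sequence[PyramidLevel]
) -> int:
    """Pick the level to fetch for a zoom: the highest-resolution level
    whose downsample factor is >= the data pixels spanned by one screen
    pixel (never fetch more resolution than the screen can display),
    clamped to the deepest available level when zoomed far out."""
    if not levels:
        raise ValueError("need at least one pyramid level")
    needed = viewport.data_px_per_screen_px
    admissible = [lv for lv in levels if lv.downsample_factor >= needed]
    if admissible:
        return min(admissible, key=lambda lv: lv.downsample_factor).index
    return max(levels, key=lambda lv: lv.downsample_factor).index


def visible_tiles(
    viewport: Viewport, level: PyramidLevel
) -> list[tuple[int, int]]:
    """Exactly the (tile_x, tile_y) whose data-space footprint intersects
    the viewport rectangle, in row-major order.

    Tile (tx, ty) covers level pixels ``[tx*ts, min((tx+1)*ts, w)) x
    [ty*ts, ...)``; footprints scale by the level's downsample factor.
    Intersection is open (touching edges do not count).
    """
    x0, y0, x1, y1 = data_bounds(viewport)
    f = level.downsample_factor
    h, w = level.shape
    ts = level.tile_size
    n_tx, n_ty = -(-w // ts), -(-h // ts)
    out = []
    for ty in range(n_ty):
        ty0, ty1 = ty * ts * f, min((ty + 1) * ts, h) * f
        if ty1 <= y0 or ty0 >= y1:
            continue
        for tx in range(n_tx):
            tx0, tx1 = tx * ts * f, min((tx + 1) * ts, w) * f
            if tx1 <= x0 or tx0 >= x1:
                continue
            out.append((tx, ty))
    return out


def partition_bounds(n: int, parts: int) -> np.ndarray:
    """Proportional integer partition: bin k covers ``[floor(k*n/parts),
    floor((k+1)*n/parts))``. Bins tile [0, n) exactly, none empty when
    parts <= n."""
    return (np.arange(parts + 1) * n) // parts


_AGG = {
    "mean": lambda x, b: _reduceat_mean(x, b),
    "max": lambda x, b: np.maximum.reduceat(x, b[:-1], axis=0),
    "min": lambda x, b: np.minimum.reduceat(x, b[:-1], axis=0),
}


def _reduceat_mean(x: np.ndarray, bounds: np.ndarray) -> np.ndarray:
    sums = np.add.reduceat(x.astype(np.float64), bounds[:-1], axis=0)
    counts = np.diff(bounds).astype(np.float64)
    return sums / counts[:, None]


def aggregate_matrix_to_pixels(
    block: np.ndarray, pixel_rows: int, pixel_cols: int, agg: str = "mean"
) -> np.ndarray:
    """Anti-aliased reduction of a matrix block onto a pixel grid.

    Pixel (i, j) aggregates the contiguous bin of matrix cells mapped to
    it by the proportional partition of rows and columns; the bins tile
    the block, so no cell is dropped or double-counted and a constant
    matrix yields a constant raster at any grid (no aliasing or Moire
    patterning). If the requested grid is finer than the block in either
    axis, that axis passes through unaggregated.
    """
    block = np.asarray(block)
    if block.ndim != 2:
        raise ValueError("block must be 2-D")
    n, m = block.shape
    if n == 0 or m == 0 or pixel_rows == 0 or pixel_cols == 0:
        return np.empty((0, 0), dtype=float)
    if agg not in _AGG:
        raise ValueError(f"unknown aggregation {agg!r}; use mean, max or min")
    pixel_rows = min(pixel_rows, n) if pixel_rows <= n else n
    pixel_cols = min(pixel_cols, m) if pixel_cols <= m else m
    rb = partition_bounds(n, pixel_rows)
    out = _AGG[agg](block, rb)
    cb = partition_bounds(m, pixel_cols)
    out = _AGG[agg](out.T, cb).T
    return out


#: Fixed per-character label width used by the tick policy.
TICK_CHAR_WIDTH_PX = 7


def axis_tick_policy(
    zoom: float, labels: Sequence[str], axis_length_px: float
) -> list[int]:
    """Indices of axis labels to draw without overlap.

    Each of the ``n`` labels owns a bin of the axis; at zoom ``z`` the
    bin pitch is ``axis_length_px * 2**z / n`` screen pixels. Labels are
    drawn at a uniform stride chosen so that consecutive drawn labels
    are at least the widest label apart (width = characters x 7 px):
    at most one label per bin, never overlapping, and zooming in never
    drops labels.
    """
    n = len(labels)
    if n == 0 or axis_length_px <= 0:
        return []
    pitch = axis_length_px * (2.0 ** zoom) / n
    extent = max((len(s) for s in labels), default=0) * TICK_CHAR_WIDTH_PX
    extent = max(extent, 1)
    stride = max(1, int(np.ceil(extent / pitch)))
    return list(range(0, n, stride))
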