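"""Static snapshot rendering of a full view config.

Renders each view of a layout to an RGBA raster with plain numpy
pixel-pushing (no GUI toolkit), composes the panels on the layout grid,
and drives *every* visual encoding from resolved coordination state —
so two views linked on a scope provably render from identical values.
Rendering is deterministic: the same config and fixture seed give
byte-identical rasters.

Spatial views composite layers back-to-front with alpha: images at the
bottom (additive per-channel blending after contrast windowing), then
segmentation bitmasks (pixel value = observation label, 0 transparent),
then spots (fixed-radius circles) and points (single pixels).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Optional, Sequence

import numpy as np

from . import tiling
from .coordination import resolve_view_state
from .data_model import dataset_manifest, match_view_to_data, EntityTriple
from .errors import RenderError
from .loaders import (
    ChunkedMatrixHandle,
    ImagePyramid,
    ObservationTable,
    SetHierarchy,
    load_full,
    open_matrix,
    open_pyramid,
)
from .tiling import (
    PyramidLevel,
    Viewport,
    aggregate_matrix_to_pixels,
    axis_tick_policy,
    select_pyramid_level,
    visible_tiles,
)

__all__ = [
    "ColorEncoding",
    "SpatialLayer",
    "Raster",
    "Snapshot",
    "PanelReport",
    "colormap_table",
    "map_values_to_colors",
    "render_spatial",
    "render_heatmap",
    "render_scatterplot",
    "render_snapshot",
    "fit_camera",
    "PX_PER_GRID_UNIT",
]

#: Panel pixels per abstract layout grid unit.
PX_PER_GRID_UNIT = 200

#: Color for missing / unassigned values: mid-grey.
MISSING_COLOR = (128, 128, 128)

_BG = np.array([255, 255, 255, 255], dtype=np.uint8)

#: Deterministic categorical palette for observation sets (RGB).
SET_PALETTE = [
    (31, 119, 180),
    (255, 127, 14),
    (44, 160, 44),
    (214, 39, 40),
    (148, 103, 189),
    (140, 86, 75),
    (227, 119, 194),
    (127, 127, 127),
    (188, 189, 34),
    (23, 190, 207),
]

#: Default per-channel colors for multiplexed image composites.
CHANNEL_PALETTE = [
    (0, 0, 255),
    (0, 255, 0),
    (255, 0, 255),
    (255, 255, 0),
    (0, 255, 255),
    (255, 128, 0),
    (255, 255, 255),
    (255, 0, 0),
]

_COLORMAP_CACHE: dict[tuple[str, int], np.ndarray] = {}


def colormap_table(name: str, n: int = 256) -> np.ndarray:
    """(n, 3) uint8 table for a named quantitative colormap."""
    key = (name, n)
    if key not in _COLORMAP_CACHE:
        import matplotlib

        try:
            cmap = matplotlib.colormaps[name]
        except KeyError:
            raise RenderError(f"unknown colormap {name!r}") from None
        rgba = cmap(np.linspace(0.0, 1.0, n))
        _COLORMAP_CACHE[key] = (rgba[:, :3] * 255).round().astype(np.uint8)
    return _COLORMAP_CACHE[key]


@dataclass
class ColorEncoding:
    """How per-observation values become colors."""

    mode: str = "featureValue"  # featureValue | setMembership | static
    colormap: Any = "viridis"  # name or (K, 3) table
    domain: Optional[tuple[float, float]] = None
    quantiles: tuple[float, float] = (0.0, 1.0)
    static_color: tuple[int, int, int] = (180, 180, 180)
    missing_color: tuple[int, int, int] = MISSING_COLOR

    def table(self) -> np.ndarray:
        if isinstance(self.colormap, str):
            return colormap_table(self.colormap)
        return np.asarray(self.colormap, dtype=np.uint8)


def map_values_to_colors(
    values: Sequence[float], encoding: ColorEncoding
) -> np.ndarray:
    """Map numbers to RGB via piecewise-linear colormap interpolation.

    Values at or below the domain minimum get the first table entry, at
    or above the maximum the last; NaN gets the missing color. A
    degenerate domain (max <= min, e.g. all-equal values under a
    quantile domain) maps everything to the first entry.
    """
    values = np.asarray(values, dtype=float)
    table = encoding.table().astype(float)
    k = len(table)
    if encoding.domain is not None:
        lo, hi = encoding.domain
    else:
        finite = values[np.isfinite(values)]
        if finite.size:
            lo, hi = (float(np.quantile(finite, q)) for q in encoding.quantiles)
        else:
            lo, hi = 0.0, 0.0
    out = np.empty((len(values), 3), dtype=np.uint8)
    missing = ~np.isfinite(values)
    if hi <= lo:
        t = np.zeros(len(values))
    else:
        t = np.clip((values - lo) / (hi - lo), 0.0, 1.0)
    t = np.nan_to_num(t)
    pos = t * (k - 1)
    i0 = np.floor(pos).astype(int)
    i1 = np.minimum(i0 + 1, k - 1)
    frac = (pos - i0)[:, None]
    rgb = table[i0] * (1 - frac) + table[i1] * frac
    out[:] = np.clip(np.round(rgb), 0, 255).astype(np.uint8)
    out[missing] = encoding.missing_color
    return out


# ---------------------------------------------------------------------------
# rasters and compositing


@dataclass
class Raster:
    """An RGBA pixel array with screen-pixel addressing."""

    pixels: np.ndarray  # (H, W, 4) uint8

    @classmethod
    def blank(cls, width_px: int, height_px: int, color=_BG) -> "Raster":
        px = np.empty((height_px, width_px, 4), dtype=np.uint8)
        px[:] = color
        return cls(px)

    @property
    def width_px(self) -> int:
        return self.pixels.shape[1]

    @property
    def height_px(self) -> int:
        return self.pixels.shape[0]

    def save(self, path: str | Path) -> Path:
        from PIL import Image

        path = Path(path)
        Image.fromarray(self.pixels, mode="RGBA").save(path, format="PNG")
        return path


def _composite_over(dst: np.ndarray, src: np.ndarray) -> None:
    """Alpha-composite src over dst in place; both (H, W, 4) uint8."""
    sa = src[..., 3:4].astype(np.float64) / 255.0
    da = dst[..., 3:4].astype(np.float64) / 255.0
    out_a = sa + da * (1 - sa)
    safe = np.where(out_a == 0, 1.0, out_a)
    rgb = (
        src[..., :3] * sa + dst[..., :3] * da * (1 - sa)
    ) / safe
    dst[..., :3] = np.clip(np.round(rgb), 0, 255).astype(np.uint8)
    dst[..., 3] = np.clip(np.round(out_a[..., 0] * 255), 0, 255).astype(np.uint8)


def _paint_disks(
    canvas: np.ndarray,
    xy_screen: np.ndarray,
    colors: np.ndarray,
    radius: float,
    opacity: float,
) -> None:
    """Stamp filled circles (radius in px; radius < 1 = single pixel)."""
    h, w = canvas.shape[:2]
    r = max(int(round(radius)), 0)
    if r <= 0:
        xs = np.round(xy_screen[:, 0]).astype(int)
        ys = np.round(xy_screen[:, 1]).astype(int)
        ok = (xs >= 0) & (xs < w) & (ys >= 0) & (ys < h)
        a = int(round(255 * opacity))
        layer = np.zeros_like(canvas)
        layer[ys[ok], xs[ok], :3] = colors[ok]
        layer[ys[ok], xs[ok], 3] = a
        _composite_over(canvas, layer)
        return
    yy, xx = np.mgrid[-r : r + 1, -r : r + 1]
    disk = (xx ** 2 + yy ** 2) <= r ** 2
    layer = np.zeros_like(canvas)
    a = int(round(255 * opacity))
    for (x, y), color in zip(xy_screen, colors):
        cx, cy = int(round(x)), int(round(y))
        if cx + r < 0 or cx - r >= w or cy + r < 0 or cy - r >= h:
            continue
        y0, y1 = max(cy - r, 0), min(cy + r + 1, h)
        x0, x1 = max(cx - r, 0), min(cx + r + 1, w)
        sub = disk[y0 - (cy - r) : y1 - (cy - r), x0 - (cx - r) : x1 - (cx - r)]
        layer[y0:y1, x0:x1, :3][sub] = color
        layer[y0:y1, x0:x1, 3][sub] = a
    _composite_over(canvas, layer)


def fit_camera(
    bounds: tuple[float, float, float, float], width_px: int, height_px: int
) -> tuple[float, float, float]:
    """(zoom, target_x, target_y) fitting a data rectangle into a panel."""
    x0, y0, x1, y1 = bounds
    w = max(x1 - x0, 1e-9)
    h = max(y1 - y0, 1e-9)
    zoom = math.log2(min(width_px / w, height_px / h) * 0.95)
    return zoom, (x0 + x1) / 2.0, (y0 + y1) / 2.0


def _screen_xy(
    coords: np.ndarray, zoom: float, tx: float, ty: float, w: int, h: int
) -> np.ndarray:
    scale = 2.0 ** zoom
    out = np.empty_like(coords, dtype=float)
    out[:, 0] = (coords[:, 0] - tx) * scale + w / 2.0
    out[:, 1] = (coords[:, 1] - ty) * scale + h / 2.0
    return out


# ---------------------------------------------------------------------------
# per-observation color resolution (shared by scatterplot and spatial)


def _set_leaf_colors(
    sets: SetHierarchy, overrides: dict | None
) -> dict[tuple[str, ...], tuple[int, int, int]]:
    colors: dict[tuple[str, ...], tuple[int, int, int]] = {}
    for i, (path, node) in enumerate(sets.iter_leaves(sets.roots[0])):
        key = "/".join(path)
        if overrides and key in overrides:
            colors[path] = tuple(overrides[key])
        elif node.color is not None:
            colors[path] = node.color
        else:
            colors[path] = SET_PALETTE[i % len(SET_PALETTE)]
    return colors


def resolve_obs_colors(
    state: dict[str, Any],
    obs_ids: Sequence[str],
    matrix: Optional[ChunkedMatrixHandle] = None,
    sets: Optional[SetHierarchy] = None,
) -> tuple[np.ndarray, Optional[str]]:
    """Per-observation RGB under the view's resolved coordination state.

    Returns (colors, label) where label names the encoding source (the
    selected feature, or the set root). This single code path serving
    every view is what makes linked views color identically.
    """
    mode = state.get("obsColorEncoding", "setMembership")
    n = len(obs_ids)
    if mode == "static":
        return np.tile(np.array((180, 180, 180), np.uint8), (n, 1)), None
    if mode == "featureValue":
        selection = state.get("featureSelection")
        if not selection:
            raise RenderError(
                "featureValue color encoding requires a selected feature"
            )
        if matrix is None:
            raise RenderError("featureValue color encoding requires a matrix")
        # a linked selection may span modalities: color by the first
        # selected feature this matrix actually has, missing-grey if none
        known = set(matrix.feature_ids)
        present = [f for f in selection if f in known]
        feature = present[0] if present else selection[0]
        if present:
            col = matrix.load_subset([feature])[:, 0].astype(float)
            by_id = dict(zip(matrix.obs_ids, col))
            values = np.array([by_id.get(o, np.nan) for o in obs_ids])
        else:
            values = np.full(n, np.nan)
        rng = state.get("featureValueColormapRange") or {}
        enc = ColorEncoding(
            mode="featureValue",
            colormap=state.get("featureValueColormap", "viridis"),
            quantiles=(rng.get("min", 0.0), rng.get("max", 1.0)),
        )
        return map_values_to_colors(values, enc), feature
    if mode == "setMembership":
        if sets is None:
            raise RenderError("setMembership color encoding requires obs sets")
        leaf_colors = _set_leaf_colors(sets, state.get("obsSetColor"))
        member = sets.membership(0)
        selected = state.get("obsSetSelection")
        allowed = {tuple(s.split("/")) for s in selected} if selected else None
        colors = np.tile(np.array(MISSING_COLOR, np.uint8), (n, 1))
        for i, oid in enumerate(obs_ids):
            path = member.get(oid)
            if path is None:
                continue
            if allowed is not None and path not in allowed:
                continue
            colors[i] = leaf_colors.get(path, MISSING_COLOR)
        return colors, sets.roots[0].name
    raise RenderError(f"unknown obsColorEncoding {mode!r}")


# ---------------------------------------------------------------------------
# spatial view


@dataclass
class SpatialLayer:
    """One layer of a spatial stack: points, spots, segmentations or image."""

    kind: str  # points | spots | segmentations | image
    payload: Any  # coords (N,2) for points/spots, ImagePyramid otherwise
    visible: bool = True
    opacity: float = 1.0
    obs_colors: Optional[np.ndarray] = None
    radius: float = 4.0
    channels: Optional[list[int]] = None
    channel_colors: Optional[dict] = None
    channel_windows: Optional[dict] = None

    KINDS = ("points", "spots", "segmentations", "image")

    def __post_init__(self) -> None:
        if self.kind not in self.KINDS:
            raise RenderError(f"unknown spatial layer kind {self.kind!r}")
        if not 0.0 <= self.opacity <= 1.0:
            raise RenderError("layer opacity must lie in [0, 1]")


def _level_window(
    pyramid: ImagePyramid, viewport: Viewport
) -> tuple[int, np.ndarray, int, int]:
    """Pick a level, fetch exactly its visible tiles, and return the
    assembled window plus its level-pixel origin."""
    levels = [
        PyramidLevel(i, pyramid.level_shape(i)[1:], pyramid.tile_size)
        for i in range(pyramid.n_levels)
    ]
    li = select_pyramid_level(viewport, levels)
    level = levels[li]
    tiles = visible_tiles(viewport, level)
    if not tiles:
        return li, np.empty((pyramid.n_channels, 0, 0)), 0, 0
    txs = sorted({t[0] for t in tiles})
    tys = sorted({t[1] for t in tiles})
    ts = level.tile_size
    h, w = level.shape
    y0, y1 = tys[0] * ts, min((tys[-1] + 1) * ts, h)
    x0, x1 = txs[0] * ts, min((txs[-1] + 1) * ts, w)
    window = np.zeros((pyramid.n_channels, y1 - y0, x1 - x0), dtype=pyramid.levels[li].dtype)
    for tx, ty in tiles:
        tile = pyramid.load_tile(li, tx, ty)
        oy, ox = ty * ts - y0, tx * ts - x0
        window[:, oy : oy + tile.shape[1], ox : ox + tile.shape[2]] = tile
    return li, window, x0, y0


def _sample_window(
    window: np.ndarray, x0: int, y0: int, factor: int, viewport: Viewport
) -> tuple[np.ndarray, np.ndarray]:
    """Nearest-neighbor lookup indices from screen pixels into a level
    window; returns (index array (H,W) into flattened YX, valid mask)."""
    w_px, h_px = viewport.width_px, viewport.height_px
    xs = (np.arange(w_px) + 0.5 - w_px / 2.0) / viewport.scale + viewport.target_x
    ys = (np.arange(h_px) + 0.5 - h_px / 2.0) / viewport.scale + viewport.target_y
    lx = np.floor(xs / factor).astype(int) - x0
    ly = np.floor(ys / factor).astype(int) - y0
    wh, ww = window.shape[-2:]
    vx = (lx >= 0) & (lx < ww)
    vy = (ly >= 0) & (ly < wh)
    mask = vy[:, None] & vx[None, :]
    lx = np.clip(lx, 0, max(ww - 1, 0))
    ly = np.clip(ly, 0, max(wh - 1, 0))
    idx = ly[:, None] * max(ww, 1) + lx[None, :]
    return idx, mask


def _render_image_layer(
    layer: SpatialLayer, viewport: Viewport
) -> np.ndarray:
    pyramid: ImagePyramid = layer.payload
    li, window, x0, y0 = _level_window(pyramid, viewport)
    out = np.zeros((viewport.height_px, viewport.width_px, 4), dtype=np.uint8)
    if window.size == 0:
        return out
    idx, mask = _sample_window(window, x0, y0, 2 ** li, viewport)
    channels = layer.channels
    if channels is None:
        channels = list(range(pyramid.n_channels))
    acc = np.zeros((viewport.height_px, viewport.width_px, 3), dtype=np.float64)
    for k, c in enumerate(channels):
        plane = window[c].reshape(-1)[idx]
        win = None
        if layer.channel_windows:
            win = layer.channel_windows.get(str(c)) or layer.channel_windows.get(c)
        if win is None:
            if np.issubdtype(plane.dtype, np.integer):
                win = (0.0, float(np.iinfo(plane.dtype).max))
            else:
                win = (0.0, 1.0)
        lo, hi = float(win[0]), float(win[1])
        norm = np.clip((plane.astype(np.float64) - lo) / max(hi - lo, 1e-12), 0, 1)
        color = None
        if layer.channel_colors:
            color = layer.channel_colors.get(str(c)) or layer.channel_colors.get(c)
        if color is None:
            color = CHANNEL_PALETTE[k % len(CHANNEL_PALETTE)]
        acc += norm[..., None] * np.asarray(color, dtype=np.float64)
    rgb = np.clip(acc, 0, 255).astype(np.uint8)
    out[..., :3] = rgb
    out[..., 3] = np.where(mask, int(round(255 * layer.opacity)), 0)
    return out


def _render_segmentation_layer(
    layer: SpatialLayer, viewport: Viewport
) -> np.ndarray:
    pyramid: ImagePyramid = layer.payload
    if not pyramid.is_bitmask:
        raise RenderError("segmentation layer requires a bitmask pyramid")
    if layer.obs_colors is None:
        raise RenderError("segmentation layer requires per-observation colors")
    li, window, x0, y0 = _level_window(pyramid, viewport)
    out = np.zeros((viewport.height_px, viewport.width_px, 4), dtype=np.uint8)
    if window.size == 0:
        return out
    idx, mask = _sample_window(window, x0, y0, 2 ** li, viewport)
    labels = window[0].reshape(-1)[idx].astype(np.int64)
    n_obs = len(layer.obs_colors)
    # label L (1-based) -> observation L-1; 0 and out-of-range transparent
    lut = np.zeros((n_obs + 1, 4), dtype=np.uint8)
    lut[1:, :3] = layer.obs_colors
    lut[1:, 3] = int(round(255 * layer.opacity))
    labels = np.where((labels < 0) | (labels > n_obs), 0, labels)
    out[:] = lut[labels]
    out[~mask] = 0
    return out


def render_spatial(
    state: dict[str, Any],
    layers: Sequence[SpatialLayer],
    width_px: int,
    height_px: int,
) -> Raster:
    """Composite a spatial layer stack under a resolved view state.

    Layers are composited back-to-front in stack order with alpha;
    invisible layers and zero-opacity layers leave the raster untouched.
    """
    viewport = Viewport(
        target_x=float(state.get("spatialTargetX", 0.0)),
        target_y=float(state.get("spatialTargetY", 0.0)),
        zoom=float(state.get("spatialZoom", 0.0)),
        width_px=width_px,
        height_px=height_px,
    )
    raster = Raster.blank(width_px, height_px)
    for i, layer in enumerate(layers):
        if not layer.visible or layer.opacity == 0.0:
            continue
        try:
            if layer.kind == "image":
                src = _render_image_layer(layer, viewport)
            elif layer.kind == "segmentations":
                src = _render_segmentation_layer(layer, viewport)
            elif layer.kind in ("spots", "points"):
                coords = np.asarray(layer.payload, dtype=float)
                if layer.obs_colors is None:
                    raise RenderError(
                        f"{layer.kind} layer requires per-observation colors"
                    )
                xy = _screen_xy(
                    coords,
                    viewport.zoom,
                    viewport.target_x,
                    viewport.target_y,
                    width_px,
                    height_px,
                )
                radius = layer.radius if layer.kind == "spots" else 0.0
                _paint_disks(
                    raster.pixels, xy, layer.obs_colors, radius, layer.opacity
                )
                continue
            else:  # pragma: no cover - guarded by SpatialLayer
                raise RenderError(f"unknown layer kind {layer.kind!r}")
        except RenderError as exc:
            raise RenderError(f"layer {i} ({layer.kind}): {exc}") from exc
        _composite_over(raster.pixels, src)
    return raster


# ---------------------------------------------------------------------------
# heatmap


HEATMAP_MARGIN_PX = 12


def heatmap_window(
    n_obs: int, n_feat: int, state: dict[str, Any]
) -> tuple[int, int, int, int]:
    """Visible (row0, row1, col0, col1) half-open window of the matrix
    under the heatmap camera; zoom 0 shows everything."""
    zx = float(state.get("heatmapZoomX", 0.0))
    zy = float(state.get("heatmapZoomY", 0.0))
    ncols = max(1, int(math.ceil(n_feat / (2.0 ** zx))))
    nrows = max(1, int(math.ceil(n_obs / (2.0 ** zy))))
    col0 = int(np.clip(round(float(state.get("heatmapTargetX", 0.0))), 0, n_feat - ncols))
    row0 = int(np.clip(round(float(state.get("heatmapTargetY", 0.0))), 0, n_obs - nrows))
    return row0, row0 + nrows, col0, col0 + ncols


def render_heatmap(
    state: dict[str, Any],
    matrix: ChunkedMatrixHandle,
    width_px: int,
    height_px: int,
) -> Raster:
    """Aggregate the visible matrix window to pixels, then color it.

    Drawing is clipped to the matrix body area (margins carry axis tick
    marks chosen by the zoom-aware tick policy); aggregation uses the
    anti-aliasing bin reduction, so a constant matrix renders as one
    flat color at any zoom.
    """
    n_obs, n_feat = matrix.shape
    if n_obs == 0 or n_feat == 0:
        raise RenderError("cannot render a heatmap of an empty matrix")
    selection = state.get("featureSelection")
    feat_ids = list(matrix.feature_ids)
    if selection:
        known = [f for f in selection if f in set(feat_ids)]
        if known:
            feat_ids = known
    r0, r1, c0, c1 = heatmap_window(n_obs, len(feat_ids), state)
    block = matrix.load_subset(feat_ids[c0:c1], (r0, r1))
    body_w = max(width_px - HEATMAP_MARGIN_PX, 1)
    body_h = max(height_px - HEATMAP_MARGIN_PX, 1)
    agg = state.get("heatmapAggregation", "mean")
    pix = aggregate_matrix_to_pixels(
        block, min(body_h, block.shape[0]), min(body_w, block.shape[1]), agg
    )
    enc = ColorEncoding(
        colormap=state.get("featureValueColormap", "viridis"), quantiles=(0.0, 1.0)
    )
    colors = map_values_to_colors(pix.ravel(), enc).reshape(
        pix.shape[0], pix.shape[1], 3
    )
    raster = Raster.blank(width_px, height_px)
    # nearest-neighbor upscale of the aggregated grid to the body area
    ri = (np.arange(body_h) * pix.shape[0]) // body_h
    ci = (np.arange(body_w) * pix.shape[1]) // body_w
    body = colors[ri][:, ci]
    m = HEATMAP_MARGIN_PX
    raster.pixels[m:, m:, :3] = body
    raster.pixels[m:, m:, 3] = 255
    # tick marks from the zoom-aware policy
    row_labels = [str(o) for o in matrix.obs_ids[r0:r1]]
    col_labels = [str(f) for f in feat_ids[c0:c1]]
    for idx in axis_tick_policy(float(state.get("heatmapZoomY", 0.0)), row_labels, body_h):
        y = m + int((idx + 0.5) * body_h / max(len(row_labels), 1))
        raster.pixels[min(y, height_px - 1), m - 4 : m, :3] = 0
    for idx in axis_tick_policy(float(state.get("heatmapZoomX", 0.0)), col_labels, body_w):
        x = m + int((idx + 0.5) * body_w / max(len(col_labels), 1))
        raster.pixels[m - 4 : m, min(x, width_px - 1), :3] = 0
    return raster


# ---------------------------------------------------------------------------
# scatterplot and statistical views


def render_scatterplot(
    state: dict[str, Any],
    embedding: ObservationTable,
    width_px: int,
    height_px: int,
    matrix: Optional[ChunkedMatrixHandle] = None,
    sets: Optional[SetHierarchy] = None,
) -> Raster:
    """Draw embedding coordinates as colored markers.

    Positions come only from the embedding and the embedding camera;
    colors come only from the color encoding — changing the selected
    feature recolors without repositioning.
    """
    cols = list(embedding.frame.columns[:2])
    coords = embedding.coords(cols)
    colors, _ = resolve_obs_colors(state, embedding.obs_ids, matrix, sets)
    raster = Raster.blank(width_px, height_px)
    xy = _screen_xy(
        coords,
        float(state.get("embeddingZoom", 0.0)),
        float(state.get("embeddingTargetX", 0.0)),
        float(state.get("embeddingTargetY", 0.0)),
        width_px,
        height_px,
    )
    _paint_disks(
        raster.pixels,
        xy,
        colors,
        float(state.get("embeddingObsRadius", 1.0)),
        float(state.get("embeddingObsOpacity", 1.0)),
    )
    return raster


def render_set_sizes(
    state: dict[str, Any], sets: SetHierarchy, width_px: int, height_px: int
) -> Raster:
    """Bar chart of observation-set sizes, colored by set color."""
    leaf_colors = _set_leaf_colors(sets, state.get("obsSetColor"))
    leaves = list(sets.iter_leaves(sets.roots[0]))
    raster = Raster.blank(width_px, height_px)
    if not leaves:
        return raster
    sizes = [len(n.obs_ids or []) for _, n in leaves]
    peak = max(max(sizes), 1)
    n = len(leaves)
    for i, ((path, _node), size) in enumerate(zip(leaves, sizes)):
        x0 = int(i * width_px / n) + 2
        x1 = max(int((i + 1) * width_px / n) - 2, x0 + 1)
        bh = int(round((height_px - 8) * size / peak))
        raster.pixels[height_px - 4 - bh : height_px - 4, x0:x1, :3] = leaf_colors[path]
    return raster


def render_histogram(
    state: dict[str, Any],
    matrix: ChunkedMatrixHandle,
    width_px: int,
    height_px: int,
    bins: int = 24,
) -> Raster:
    """Histogram of the selected feature's values across observations."""
    selection = state.get("featureSelection") or [matrix.feature_ids[0]]
    values = matrix.load_subset([selection[0]])[:, 0].astype(float)
    counts, _edges = np.histogram(values[np.isfinite(values)], bins=bins)
    raster = Raster.blank(width_px, height_px)
    peak = max(counts.max(initial=0), 1)
    for i, c in enumerate(counts):
        x0 = int(i * width_px / bins)
        x1 = max(int((i + 1) * width_px / bins) - 1, x0 + 1)
        bh = int(round((height_px - 8) * c / peak))
        raster.pixels[height_px - 4 - bh : height_px - 4, x0:x1, :3] = (90, 90, 160)
    return raster


def render_violin(
    state: dict[str, Any],
    matrix: ChunkedMatrixHandle,
    sets: SetHierarchy,
    width_px: int,
    height_px: int,
    bins: int = 16,
) -> Raster:
    """Per-set symmetric value-distribution silhouettes for one feature."""
    selection = state.get("featureSelection") or [matrix.feature_ids[0]]
    values = matrix.load_subset([selection[0]])[:, 0].astype(float)
    by_id = dict(zip(matrix.obs_ids, values))
    leaf_colors = _set_leaf_colors(sets, state.get("obsSetColor"))
    leaves = list(sets.iter_leaves(sets.roots[0]))
    raster = Raster.blank(width_px, height_px)
    if not leaves:
        return raster
    finite = values[np.isfinite(values)]
    lo, hi = (float(finite.min()), float(finite.max())) if finite.size else (0, 1)
    if hi <= lo:
        hi = lo + 1.0
    n = len(leaves)
    for i, (path, node) in enumerate(leaves):
        vals = np.array([by_id[o] for o in (node.obs_ids or []) if o in by_id])
        vals = vals[np.isfinite(vals)]
        if not vals.size:
            continue
        counts, _ = np.histogram(vals, bins=bins, range=(lo, hi))
        center = int((i + 0.5) * width_px / n)
        half_max = max(int(width_px / (2.2 * n)), 1)
        peak = max(counts.max(), 1)
        for b, c in enumerate(counts):
            y0 = height_px - 4 - int((b + 1) * (height_px - 8) / bins)
            y1 = height_px - 4 - int(b * (height_px - 8) / bins)
            half = int(round(half_max * c / peak))
            raster.pixels[y0:y1, center - half : center + half + 1, :3] = leaf_colors[
                path
            ]
    return raster


# ---------------------------------------------------------------------------
# full-config snapshot


@dataclass
class PanelReport:
    """What one panel rendered from: view identity, geometry, resolved
    coordination state, and any failure."""

    uid: str
    component: str
    rect_px: tuple[int, int, int, int]  # (x, y, w, h)
    resolved: dict[str, Any] = field(default_factory=dict)
    color_label: Optional[str] = None
    error: Optional[str] = None


@dataclass
class Snapshot:
    """A rendered layout: the composed raster plus per-panel reports."""

    raster: Raster
    panels: list[PanelReport]

    @property
    def failed_panels(self) -> list[PanelReport]:
        return [p for p in self.panels if p.error is not None]

    def save(self, path: str | Path) -> Path:
        return self.raster.save(path)


def _spatial_layers_for(
    state: dict[str, Any], report, base_dir: Optional[str]
) -> tuple[list[SpatialLayer], Optional[str]]:
    """Build the spatial layer stack from matched accessors, bottom-up:
    images, then segmentations, spots, points."""
    layers: list[SpatialLayer] = []
    matrix = None
    sets = None
    if "obsFeatureMatrix" in report.matched:
        matrix = open_matrix(report.matched["obsFeatureMatrix"], base_dir)
    if "obsSets" in report.matched:
        sets = load_full(report.matched["obsSets"], base_dir)
    color_label = None
    chan_sel = state.get("imageChannelSelection") or {}
    if "image" in report.matched:
        pyramid = open_pyramid(report.matched["image"], base_dir)
        layers.append(
            SpatialLayer(
                "image",
                pyramid,
                visible=bool(state.get("imageLayerVisible", True)),
                opacity=float(state.get("imageLayerOpacity", 1.0)),
                channels=list(chan_sel.get("c", range(pyramid.n_channels))),
                channel_colors=state.get("imageChannelColor"),
                channel_windows=state.get("imageChannelWindow"),
            )
        )
    obs_colors = None
    if "obsSegmentations" in report.matched:
        seg = open_pyramid(report.matched["obsSegmentations"], base_dir)
        seg_obs_ids = None
        if matrix is not None:
            seg_obs_ids = matrix.obs_ids
        elif "obsLocations" in report.matched:
            seg_obs_ids = load_full(report.matched["obsLocations"], base_dir).obs_ids
        if seg_obs_ids is None:
            raise RenderError(
                "segmentation layer needs a matrix or locations accessor to "
                "identify observations"
            )
        obs_colors, color_label = resolve_obs_colors(
            state, seg_obs_ids, matrix, sets
        )
        layers.append(
            SpatialLayer(
                "segmentations",
                seg,
                visible=bool(state.get("segmentationLayerVisible", True)),
                opacity=float(state.get("segmentationLayerOpacity", 1.0)),
                obs_colors=obs_colors,
            )
        )
    if "obsLocations" in report.matched:
        table = load_full(report.matched["obsLocations"], base_dir)
        coords = table.coords(("x", "y"))
        pt_colors, label = resolve_obs_colors(state, table.obs_ids, matrix, sets)
        color_label = color_label or label
        if bool(state.get("spotLayerVisible", True)):
            layers.append(
                SpatialLayer(
                    "spots",
                    coords,
                    opacity=float(state.get("spotLayerOpacity", 1.0)),
                    obs_colors=pt_colors,
                    radius=float(state.get("spotRadius", 4.0)),
                )
            )
        if bool(state.get("pointLayerVisible", True)):
            layers.append(
                SpatialLayer(
                    "points",
                    coords,
                    opacity=float(state.get("pointLayerOpacity", 1.0)),
                    obs_colors=pt_colors,
                )
            )
    return layers, color_label


def _render_panel(
    config, item, state: dict[str, Any], base_dir: Optional[str],
    width_px: int, height_px: int,
) -> tuple[Raster, Optional[str]]:
    manifest = dataset_manifest(config.get_dataset(item.dataset))
    entity = EntityTriple(
        state.get("obsType"), state.get("featureType"), state.get("featureValueType")
    )
    report = match_view_to_data(item.component, entity, manifest)
    comp = item.component
    if comp == "scatterplot":
        emb = load_full(report.require("obsEmbedding"), base_dir)
        matrix = (
            open_matrix(report.matched["obsFeatureMatrix"], base_dir)
            if "obsFeatureMatrix" in report.matched
            else None
        )
        sets = (
            load_full(report.matched["obsSets"], base_dir)
            if "obsSets" in report.matched
            else None
        )
        label = None
        if state.get("obsColorEncoding") == "featureValue" and state.get(
            "featureSelection"
        ):
            label = state["featureSelection"][0]
        return (
            render_scatterplot(state, emb, width_px, height_px, matrix, sets),
            label,
        )
    if comp == "spatial":
        if report.missing and not report.matched:
            raise RenderError("; ".join(report.missing))
        layers, label = _spatial_layers_for(state, report, base_dir)
        if not layers:
            raise RenderError(
                "spatial view matched no image, segmentation or location data"
            )
        return render_spatial(state, layers, width_px, height_px), label
    if comp == "heatmap":
        matrix = open_matrix(report.require("obsFeatureMatrix"), base_dir)
        label = (state.get("featureSelection") or [None])[0]
        return render_heatmap(state, matrix, width_px, height_px), label
    if comp == "obsSetSizes":
        sets = load_full(report.require("obsSets"), base_dir)
        return render_set_sizes(state, sets, width_px, height_px), None
    if comp == "featureValueHistogram":
        matrix = open_matrix(report.require("obsFeatureMatrix"), base_dir)
        label = (state.get("featureSelection") or [None])[0]
        return render_histogram(state, matrix, width_px, height_px), label
    if comp == "obsSetFeatureValueDistribution":
        matrix = open_matrix(report.require("obsFeatureMatrix"), base_dir)
        sets = load_full(report.require("obsSets"), base_dir)
        label = (state.get("featureSelection") or [None])[0]
        return render_violin(state, matrix, sets, width_px, height_px), label
    # controller views carry coordination state but no raster content
    raster = Raster.blank(width_px, height_px, color=(245, 245, 245, 255))
    raster.pixels[0, :, :3] = 200
    raster.pixels[-1, :, :3] = 200
    return raster, None


def render_snapshot(
    config,
    data_root: Optional[str] = None,
    px_per_unit: int = PX_PER_GRID_UNIT,
) -> Snapshot:
    """Render every view of a config onto the layout grid.

    Panel placement is proportional to each view's (x, y, w, h) grid
    rectangle. A failing panel is recorded in its report (and drawn as
    a hatched error panel) without aborting the other panels. An empty
    layout yields an empty (1x1) figure.
    """
    if not config.layout:
        return Snapshot(Raster.blank(1, 1), [])
    gw = max(v.x + v.w for v in config.layout)
    gh = max(v.y + v.h for v in config.layout)
    figure = Raster.blank(gw * px_per_unit, gh * px_per_unit)
    panels: list[PanelReport] = []
    for item in config.layout:
        rect = (
            item.x * px_per_unit,
            item.y * px_per_unit,
            item.w * px_per_unit,
            item.h * px_per_unit,
        )
        panel = PanelReport(uid=item.uid, component=item.component, rect_px=rect)
        try:
            state = resolve_view_state(config, item.uid).resolved
            panel.resolved = state
            raster, label = _render_panel(
                config, item, state, data_root, rect[2], rect[3]
            )
            panel.color_label = label
        except Exception as exc:  # noqa: BLE001 - per-panel fault isolation
            panel.error = f"{type(exc).__name__}: {exc}"
            raster = Raster.blank(rect[2], rect[3], color=(250, 235, 235, 255))
            raster.pixels[::8, :, :3] = (200, 120, 120)
        x, y, w, h = rect
        figure.pixels[y : y + h, x : x + w] = raster.pixels
        panels.append(panel)
    return Snapshot(figure, panels)
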