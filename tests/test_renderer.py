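import numpy as np
import pytest

from cellviews.errors import RenderError
from cellviews.loaders import ChunkedMatrixHandle, DenseMatrix, ImagePyramid, SetHierarchy
from cellviews.renderer import (
    ColorEncoding,
    SpatialLayer,
    colormap_table,
    map_values_to_colors,
    render_heatmap,
    render_scatterplot,
    render_spatial,
    resolve_obs_colors,
)
from cellviews.tiling import aggregate_matrix_to_pixels


class TestColorMapping:
    def test_domain_boundaries(self):
        table = colormap_table("viridis")
        enc = ColorEncoding(domain=(0.0, 10.0))
        colors = map_values_to_colors([-5.0, 0.0, 10.0, 25.0], enc)
        np.testing.assert_array_equal(colors[0], table[0])
        np.testing.assert_array_equal(colors[1], table[0])
        np.testing.assert_array_equal(colors[2], table[-1])
        np.testing.assert_array_equal(colors[3], table[-1])

    def test_all_equal_values_single_color_no_error(self):
        colors = map_values_to_colors([4.2] * 7, ColorEncoding())
        assert len(np.unique(colors, axis=0)) == 1

    def test_nan_gets_missing_color(self):
        enc = ColorEncoding(domain=(0, 1), missing_color=(128, 128, 128))
        colors = map_values_to_colors([np.nan], enc)
        np.testing.assert_array_equal(colors[0], [128, 128, 128])

    def test_matches_piecewise_linear_oracle(self):
        rng = np.random.default_rng(19)
        table = rng.integers(0, 255, size=(10, 3)).astype(np.uint8)
        enc = ColorEncoding(colormap=table, domain=(0.0, 1.0))
        values = rng.uniform(-0.2, 1.2, size=200)
        got = map_values_to_colors(values, enc)
        t = np.clip(values, 0, 1)
        xp = np.linspace(0, 1, 10)
        expected = np.column_stack(
            [np.interp(t, xp, table[:, c].astype(float)) for c in range(3)]
        )
        assert np.abs(got.astype(float) - expected).max() <= 0.5 + 1e-9

    def test_feature_value_without_selection_is_error(self):
        state = {"obsColorEncoding": "featureValue", "featureSelection": None}
        with pytest.raises(RenderError, match="selected feature"):
            resolve_obs_colors(state, ["o1"], matrix=None, sets=None)


def _bitmask_pyramid(labels):
    return ImagePyramid.from_array(
        labels[None, :, :].astype(np.uint32), n_levels=1, is_bitmask=True
    )


def _identity_state(w, h):
    # camera centered on the image so data px == screen px
    return {"spatialZoom": 0.0, "spatialTargetX": w / 2, "spatialTargetY": h / 2}


class TestSpatial:
    def test_segmentation_pixel_classes(self):
        labels = np.zeros((20, 20), dtype=np.uint32)
        labels[2:8, 2:8] = 1
        labels[12:18, 12:18] = 2
        layer = SpatialLayer(
            "segmentations",
            _bitmask_pyramid(labels),
            obs_colors=np.array([[255, 0, 0], [0, 0, 255]], dtype=np.uint8),
        )
        raster = render_spatial(_identity_state(20, 20), [layer], 20, 20)
        seen = {tuple(px) for px in raster.pixels.reshape(-1, 4)}
        assert seen == {
            (255, 255, 255, 255),  # background composited on white
            (255, 0, 0, 255),
            (0, 0, 255, 255),
        }
        # non-background colors come only from labels present in the mask
        assert (raster.pixels[..., :3] == (255, 0, 0)).all(-1).sum() == 36
        assert (raster.pixels[..., :3] == (0, 0, 255)).all(-1).sum() == 36

    def test_zero_opacity_layer_is_identity(self):
        labels = np.zeros((16, 16), dtype=np.uint32)
        labels[4:12, 4:12] = 1
        colors = np.array([[10, 200, 30]], dtype=np.uint8)
        base = SpatialLayer("segmentations", _bitmask_pyramid(labels), obs_colors=colors)
        ghost = SpatialLayer(
            "segmentations",
            _bitmask_pyramid(labels),
            obs_colors=np.array([[255, 0, 0]], dtype=np.uint8),
            opacity=0.0,
        )
        state = _identity_state(16, 16)
        with_ghost = render_spatial(state, [base, ghost], 16, 16)
        without = render_spatial(state, [base], 16, 16)
        np.testing.assert_array_equal(with_ghost.pixels, without.pixels)

    def test_superimposed_vs_juxtaposed(self):
        """The same layers rendered apart or stacked share per-layer
        pixels: wherever the top layer is transparent, the superimposed
        raster equals the bottom layer's solo render."""
        rng = np.random.default_rng(23)
        img = rng.integers(0, 255, size=(1, 16, 16)).astype(np.uint8)
        image_layer = SpatialLayer(
            "image", ImagePyramid.from_array(img, 1), channel_colors={"0": (255, 255, 255)}
        )
        labels = np.zeros((16, 16), dtype=np.uint32)
        labels[2:6, 2:6] = 1
        seg_layer = SpatialLayer(
            "segmentations",
            _bitmask_pyramid(labels),
            obs_colors=np.array([[0, 255, 0]], dtype=np.uint8),
        )
        state = _identity_state(16, 16)
        solo_img = render_spatial(state, [image_layer], 16, 16)
        solo_seg = render_spatial(state, [seg_layer], 16, 16)
        stacked = render_spatial(state, [image_layer, seg_layer], 16, 16)
        covered = labels > 0
        np.testing.assert_array_equal(stacked.pixels[covered], solo_seg.pixels[covered])
        np.testing.assert_array_equal(stacked.pixels[~covered], solo_img.pixels[~covered])

    def test_layer_error_names_layer_index(self):
        plain = ImagePyramid.from_array(np.zeros((1, 8, 8), dtype=np.uint8), 1)
        layer = SpatialLayer("segmentations", plain, obs_colors=np.zeros((1, 3), np.uint8))
        with pytest.raises(RenderError, match="layer 0"):
            render_spatial(_identity_state(8, 8), [layer], 8, 8)

    def test_spots_drawn_at_coordinates(self):
        coords = np.array([[8.0, 8.0]])
        layer = SpatialLayer(
            "spots", coords, obs_colors=np.array([[200, 10, 10]], np.uint8), radius=2
        )
        raster = render_spatial(_identity_state(16, 16), [layer], 16, 16)
        np.testing.assert_array_equal(raster.pixels[8, 8, :3], [200, 10, 10])


def _handle(values, features=None):
    n, m = values.shape
    return ChunkedMatrixHandle.in_memory(
        DenseMatrix(
            [f"o{i}" for i in range(n)],
            features or [f"f{j}" for j in range(m)],
            values,
        )
    )


class TestHeatmap:
    def test_constant_matrix_single_color_body(self):
        raster = render_heatmap({}, _handle(np.full((30, 10), 5.0)), 60, 60)
        body = raster.pixels[12:, 12:, :3].reshape(-1, 3)
        assert len(np.unique(body, axis=0)) == 1

    def test_2x2_matrix_renders_four_blocks_in_order(self):
        values = np.array([[0.0, 1.0], [2.0, 3.0]])
        raster = render_heatmap({}, _handle(values), 52, 52)
        body = raster.pixels[12:, 12:, :3]
        quads = [
            body[0, 0],
            body[0, -1],
            body[-1, 0],
            body[-1, -1],
        ]
        table = colormap_table("viridis")
        np.testing.assert_array_equal(quads[0], table[0])
        np.testing.assert_array_equal(quads[3], table[-1])
        assert not np.array_equal(quads[1], quads[2])

    def test_coarse_render_equals_aggregate_then_color_oracle(self):
        rng = np.random.default_rng(29)
        values = rng.normal(size=(40, 30))
        h = _handle(values)
        w_px = h_px = 12 + 10  # tiny body forces aggregation
        raster = render_heatmap({}, h, w_px, h_px)
        body = raster.pixels[12:, 12:, :3]
        agg = aggregate_matrix_to_pixels(values, 10, 10, "mean")
        lo, hi = agg.min(), agg.max()
        enc = ColorEncoding(domain=(float(lo), float(hi)))
        expected = map_values_to_colors(agg.ravel(), enc).reshape(10, 10, 3)
        np.testing.assert_array_equal(body, expected)

    def test_empty_matrix_is_render_error(self):
        with pytest.raises(RenderError):
            render_heatmap({}, _handle(np.empty((0, 0))), 40, 40)


class TestScatterplot:
    def _embedding(self, coords):
        import pandas as pd
        from cellviews.loaders import ObservationTable

        return ObservationTable(
            pd.DataFrame(
                coords,
                index=[f"o{i}" for i in range(len(coords))],
                columns=["x", "y"],
            )
        )

    def test_point_at_target_lands_at_center(self):
        emb = self._embedding([[3.0, 4.0]])
        state = {
            "embeddingTargetX": 3.0,
            "embeddingTargetY": 4.0,
            "obsColorEncoding": "static",
        }
        raster = render_scatterplot(state, emb, 21, 21)
        assert tuple(raster.pixels[10, 10, :3]) == (180, 180, 180)

    def test_selection_changes_colors_not_positions(self):
        rng = np.random.default_rng(41)
        coords = rng.normal(size=(30, 2)) * 3
        emb = self._embedding(coords)
        matrix = _handle(
            np.column_stack([np.arange(30.0), 30.0 - np.arange(30.0)]),
            features=["GZMB", "PRF1"],
        )
        base = {
            "obsColorEncoding": "featureValue",
            "embeddingZoom": 3.0,
            "embeddingObsRadius": 1.0,
        }
        r1 = render_scatterplot(dict(base, featureSelection=["GZMB"]), emb, 64, 64, matrix)
        r2 = render_scatterplot(dict(base, featureSelection=["PRF1"]), emb, 64, 64, matrix)
        drawn1 = (r1.pixels[..., :3] != 255).any(-1)
        drawn2 = (r2.pixels[..., :3] != 255).any(-1)
        np.testing.assert_array_equal(drawn1, drawn2)  # same positions
        assert (r1.pixels != r2.pixels).any()  # different colors

    def test_set_membership_uses_at_most_set_count_colors(self):
        coords = [[float(i), 0.0] for i in range(9)]
        emb = self._embedding(coords)
        sets = SetHierarchy.from_dict(
            {
                "tree": [
                    {
                        "name": "root",
                        "children": [
                            {"name": "a", "set": ["o0", "o1", "o2"]},
                            {"name": "b", "set": ["o3", "o4", "o5"]},
                            {"name": "c", "set": ["o6", "o7", "o8"]},
                        ],
                    }
                ]
            }
        )
        state = {"obsColorEncoding": "setMembership", "embeddingZoom": 2.0}
        raster = render_scatterplot(state, emb, 64, 64, sets=sets)
        drawn = raster.pixels[(raster.pixels[..., :3] != 255).any(-1)][:, :3]
        assert len(np.unique(drawn, axis=0)) <= 3

    def test_linked_views_color_identically(self):
        """Two views resolving the same state produce identical
        per-observation colors (coordination fidelity)."""
        matrix = _handle(np.arange(20.0).reshape(10, 2), features=["a", "b"])
        state = {"obsColorEncoding": "featureValue", "featureSelection": ["b"]}
        obs = [f"o{i}" for i in range(10)]
        c1, l1 = resolve_obs_colors(dict(state), obs, matrix)
        c2, l2 = resolve_obs_colors(dict(state), obs, matrix)
        np.testing.assert_array_equal(c1, c2)
        assert l1 == l2 == "b"
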