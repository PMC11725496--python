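import numpy as np
import pytest

from cellviews.data_model import Accessor, EntityTriple
from cellviews.errors import (
    DataIOError,
    DataValidationError,
    RequestError,
)
from cellviews.loaders import (
    ChunkedMatrixHandle,
    DenseMatrix,
    ImagePyramid,
    SetHierarchy,
    chunks_intersecting,
    load_full,
    load_image_tile,
    load_matrix_subset,
    open_matrix,
)
from cellviews.store_export import ChunkPlan, export_image_pyramid, export_matrix


def _acc(url, file_type, data_type, options=None):
    return Accessor(data_type, file_type, str(url), options or {}, EntityTriple())


@pytest.fixture()
def matrix_store(tmp_path):
    rng = np.random.default_rng(3)
    values = rng.integers(0, 50, size=(1000, 100)).astype(np.int32)
    m = DenseMatrix(
        [f"o{i}" for i in range(1000)], [f"f{j}" for j in range(100)], values
    )
    export_matrix(m, tmp_path / "store", ChunkPlan((250, 10)))
    return tmp_path / "store", m


class TestCSV:
    def test_matrix_csv_shape(self, tmp_path):
        rng = np.random.default_rng(0)
        lines = ["obsId," + ",".join(f"g{j}" for j in range(10))]
        for i in range(50):
            lines.append(f"c{i}," + ",".join(str(v) for v in rng.integers(0, 9, 10)))
        p = tmp_path / "m.csv"
        p.write_text("\n".join(lines) + "\n")
        m = load_full(_acc(p, "obsFeatureMatrix.csv", "obsFeatureMatrix"))
        assert m.shape == (50, 10)
        assert m.obs_ids[0] == "c0" and m.feature_ids[-1] == "g9"

    def test_header_only_csv_is_empty_not_error(self, tmp_path):
        p = tmp_path / "m.csv"
        p.write_text("obsId,g0,g1,g2\n")
        m = load_full(_acc(p, "obsFeatureMatrix.csv", "obsFeatureMatrix"))
        assert m.shape == (0, 3)

    def test_non_numeric_matrix_rejected(self, tmp_path):
        p = tmp_path / "m.csv"
        p.write_text("obsId,g0\nc0,hello\n")
        with pytest.raises(DataValidationError):
            load_full(_acc(p, "obsFeatureMatrix.csv", "obsFeatureMatrix"))

    def test_missing_file_is_io_not_validation(self, tmp_path):
        with pytest.raises(DataIOError):
            load_full(_acc(tmp_path / "no.csv", "obsLocations.csv", "obsLocations"))

    def test_duplicate_obs_ids_rejected(self, tmp_path):
        p = tmp_path / "loc.csv"
        p.write_text("obsId,x,y\nc0,1,2\nc0,3,4\n")
        with pytest.raises(DataValidationError, match="duplicate"):
            load_full(_acc(p, "obsLocations.csv", "obsLocations"))

    def test_remote_urls_not_supported(self):
        with pytest.raises(NotImplementedError):
            load_full(_acc("https://x.org/m.csv", "obsFeatureMatrix.csv", "obsFeatureMatrix"))


class TestSets:
    def test_cycle_detected(self):
        node = {"name": "a", "children": []}
        node["children"].append(node)
        with pytest.raises(DataValidationError, match="cycle"):
            SetHierarchy.from_dict({"tree": [node]})

    def test_duplicate_membership_within_root(self):
        doc = {
            "tree": [
                {
                    "name": "root",
                    "children": [
                        {"name": "a", "set": ["c1", "c2"]},
                        {"name": "b", "set": ["c2"]},
                    ],
                }
            ]
        }
        with pytest.raises(DataValidationError, match="c2"):
            SetHierarchy.from_dict(doc)

    def test_same_obs_allowed_across_roots(self):
        doc = {
            "tree": [
                {"name": "r1", "set": ["c1"]},
                {"name": "r2", "set": ["c1"]},
            ]
        }
        h = SetHierarchy.from_dict(doc)
        assert h.membership(0) == {"c1": ("r1",)}

    def test_round_trip(self):
        doc = {
            "tree": [
                {
                    "name": "Clusters",
                    "children": [
                        {"name": "C1", "color": [255, 0, 0], "set": ["a", "b"]}
                    ],
                }
            ]
        }
        h = SetHierarchy.from_dict(doc)
        assert SetHierarchy.from_dict(h.to_dict()).to_dict() == h.to_dict()


class TestMatrixSubsets:
    def test_single_feature_touches_one_chunk_column(self, matrix_store):
        path, _ = matrix_store
        h = ChunkedMatrixHandle.open_store(path)
        load_matrix_subset(h, ["f3"])
        assert sorted(h.access_log) == [(0, 0), (1, 0), (2, 0), (3, 0)]

    def test_second_feature_same_chunk_column_is_free(self, matrix_store):
        path, _ = matrix_store
        h = ChunkedMatrixHandle.open_store(path)
        load_matrix_subset(h, ["f3", "f7"])
        assert len(h.access_log) == 4

    def test_cache_absorbs_repeat_requests(self, matrix_store):
        path, _ = matrix_store
        h = ChunkedMatrixHandle.open_store(path)
        load_matrix_subset(h, ["f3"])
        n = len(h.access_log)
        load_matrix_subset(h, ["f3"])
        assert len(h.access_log) == n  # fetches, not cache hits

    def test_unknown_features_listed(self, matrix_store):
        path, _ = matrix_store
        h = ChunkedMatrixHandle.open_store(path)
        with pytest.raises(RequestError, match="nope1.*nope2"):
            load_matrix_subset(h, ["nope1", "f1", "nope2"])

    def test_bad_obs_range(self, matrix_store):
        path, _ = matrix_store
        h = ChunkedMatrixHandle.open_store(path)
        with pytest.raises(RequestError):
            load_matrix_subset(h, ["f0"], (500, 5000))

    def test_subsets_match_full_load_and_laziness_oracle(self, matrix_store):
        """Random requests: values equal full-load slices bit-exactly and
        the fetched chunks are exactly those intersecting the request."""
        path, m = matrix_store
        rng = np.random.default_rng(9)
        for _ in range(25):
            h = ChunkedMatrixHandle.open_store(path)
            k = int(rng.integers(1, 6))
            feats = [f"f{j}" for j in rng.choice(100, size=k, replace=False)]
            lo = int(rng.integers(0, 900))
            hi = int(rng.integers(lo + 1, 1001))
            block = load_matrix_subset(h, feats, (lo, hi))
            cols = [int(f[1:]) for f in feats]
            np.testing.assert_array_equal(block, m.values[lo:hi][:, cols])
            expected = chunks_intersecting(
                h.shape, h.chunk_shape, range(lo, hi), cols
            )
            log = h.access_log
            assert set(log) == expected
            assert len(log) == len(expected)  # each chunk at most once

    def test_requested_column_order_preserved(self, matrix_store):
        path, m = matrix_store
        h = ChunkedMatrixHandle.open_store(path)
        block = load_matrix_subset(h, ["f9", "f1", "f9"], (0, 5))
        np.testing.assert_array_equal(block, m.values[:5][:, [9, 1, 9]])


class TestAnnDataJoint:
    def test_matrix_embedding_locations_from_one_store(self, anndata_store):
        path, x = anndata_store
        acc_m = _acc(path, "anndata.zarr", "obsFeatureMatrix", {"matrixPath": "X"})
        m = load_full(acc_m)
        np.testing.assert_array_equal(m.values, x)
        assert m.obs_ids[0] == "cell_00"
        h = open_matrix(acc_m)
        np.testing.assert_array_equal(
            h.load_subset(["gene_2"]), x[:, [2]]
        )
        emb = load_full(
            _acc(path, "anndata.zarr", "obsEmbedding", {"embeddingPath": "obsm/X_umap"})
        )
        assert emb.coords(("x", "y")).shape == (20, 2)
        loc = load_full(
            _acc(path, "anndata.zarr", "obsLocations", {"locationsPath": "obsm/spatial"})
        )
        assert loc.obs_ids == m.obs_ids


class TestImageTiles:
    @pytest.fixture()
    def pyramid(self, tmp_path):
        rng = np.random.default_rng(21)
        img = rng.integers(0, 255, size=(2, 96, 130)).astype(np.uint8)
        export_image_pyramid(img, tmp_path / "img", n_levels=2, tile_size=64)
        return ImagePyramid.open_store(tmp_path / "img"), img

    def test_tile_equals_crop_of_source(self, pyramid):
        pyr, img = pyramid
        tile = load_image_tile(pyr, 0, 0, 0)
        np.testing.assert_array_equal(tile, img[:, :64, :64])
        edge = load_image_tile(pyr, 0, 2, 1)  # ragged edge tile
        np.testing.assert_array_equal(edge, img[:, 64:96, 128:130])

    def test_out_of_grid_is_range_error(self, pyramid):
        pyr, _ = pyramid
        with pytest.raises(RequestError):
            load_image_tile(pyr, 0, 9, 0)
        with pytest.raises(RequestError):
            load_image_tile(pyr, 5, 0, 0)

    def test_only_requested_tile_chunks_read(self, pyramid):
        pyr, _ = pyramid
        load_image_tile(pyr, 0, 1, 0, channels=[1])
        log = pyr.access_log(0)
        assert set(log) == {(1, 0, 1)}  # (c, ty, tx) chunk of that tile only

    def test_bitmask_loads_by_identical_path(self, tmp_path):
        labels = np.zeros((1, 64, 64), dtype=np.uint32)
        labels[0, 5:15, 5:15] = 7
        export_image_pyramid(
            labels, tmp_path / "seg", n_levels=2, tile_size=32, is_bitmask=True
        )
        pyr = ImagePyramid.open_store(tmp_path / "seg")
        assert pyr.is_bitmask
        tile = load_image_tile(pyr, 0, 0, 0)
        assert set(np.unique(tile)) <= {0, 7}
        lvl1 = load_image_tile(pyr, 1, 0, 0)
        assert set(np.unique(lvl1)) <= {0, 7}  # stride keeps label values

    def test_channel_selection(self, pyramid):
        pyr, img = pyramid
        tile = load_image_tile(pyr, 0, 0, 0, channels=[1])
        np.testing.assert_array_equal(tile[0], img[1, :64, :64])
        with pytest.raises(RequestError):
            load_image_tile(pyr, 0, 0, 0, channels=[5])


class TestValidationMutations:
    def test_store_with_mismatched_ids(self, tmp_path):
        m = DenseMatrix(["a", "b"], ["x"], np.zeros((2, 1)))
        export_matrix(m, tmp_path / "s", ChunkPlan((2, 1)))
        import zarr

        root = zarr.open_group(str(tmp_path / "s"), mode="a")
        root.attrs["obsIds"] = ["a"]  # break the invariant
        with pytest.raises(DataValidationError):
            ChunkedMatrixHandle.open_store(tmp_path / "s")

    def test_dense_matrix_duplicate_ids(self):
        with pytest.raises(DataValidationError):
            DenseMatrix(["a", "a"], ["x"], np.zeros((2, 1)))

    def test_dense_matrix_shape_mismatch(self):
        with pytest.raises(DataValidationError):
            DenseMatrix(["a"], ["x"], np.zeros((2, 1)))
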