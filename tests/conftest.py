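import numpy as np
import pytest
import zarr

from cellviews import FixtureSpec, generate_dataset
from cellviews.config import ViewConfig
from cellviews.coordination import DEFAULT_REGISTRY
from cellviews.data_model import FILE_TYPES, VIEW_TYPES


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory):
    """One shared synthetic dataset for the whole session."""
    out = tmp_path_factory.mktemp("fixture")
    generate_dataset(FixtureSpec(seed=7), out)
    return out


@pytest.fixture()
def minimal_config_doc():
    return {
        "version": "spec-1.0",
        "name": "minimal",
        "description": "",
        "datasets": [{"uid": "A", "name": "", "files": []}],
        "coordinationSpace": {},
        "layout": [
            {
                "component": "scatterplot",
                "dataset": "A",
                "uid": "v0",
                "x": 0,
                "y": 0,
                "w": 2,
                "h": 2,
            }
        ],
    }


@pytest.fixture(scope="session")
def anndata_store(tmp_path_factory):
    """A tiny AnnData-style obs/var/obsm chunked store (synthetic stand-in
    for a real AnnData export: same group layout, minimal metadata)."""
    import numcodecs

    path = tmp_path_factory.mktemp("joint") / "adata.zarr"
    root = zarr.open_group(str(path), mode="w", zarr_format=2)
    rng = np.random.default_rng(11)
    x = rng.poisson(2.0, size=(20, 6)).astype(np.int32)
    comp = numcodecs.Zlib(5)
    arr = root.create_array("X", shape=x.shape, chunks=(10, 3), dtype=x.dtype, compressors=comp)
    arr[:] = x
    obs = root.create_group("obs")
    oi = obs.create_array("_index", shape=(20,), dtype="<U10", compressors=comp)
    oi[:] = np.array([f"cell_{i:02d}" for i in range(20)])
    var = root.create_group("var")
    vi = var.create_array("_index", shape=(6,), dtype="<U10", compressors=comp)
    vi[:] = np.array([f"gene_{j}" for j in range(6)])
    obsm = root.create_group("obsm")
    emb = obsm.create_array("X_umap", shape=(20, 2), dtype="f8", compressors=comp)
    emb[:] = rng.normal(size=(20, 2))
    loc = obsm.create_array("spatial", shape=(20, 2), dtype="f8", compressors=comp)
    loc[:] = rng.uniform(0, 50, size=(20, 2))
    return path, x


# ---------------------------------------------------------------------------
# random valid config generation (shared by round-trip property tests)

_WORDS = ["alpha", "beta", "gamma", "delta", "umap", "tsne", "lymph", "cortex"]

_SIMPLE_FILE_TYPES = [
    ("obsFeatureMatrix.csv", {}),
    ("obsLocations.csv", {}),
    ("obsEmbedding.csv", {"embeddingType": "umap"}),
    ("obsSets.json", {}),
    ("obsFeatureMatrix.zarr", {"path": "matrix"}),
    ("image.ome-zarr", {}),
    ("obsSegmentations.ome-zarr", {}),
]


def _random_value(rng: np.random.Generator, kind: str):
    if kind == "number":
        return float(np.round(rng.uniform(-100, 100), 6))
    if kind == "string":
        return str(rng.choice(_WORDS))
    if kind == "string-list":
        return [str(w) for w in rng.choice(_WORDS, size=rng.integers(1, 4))]
    if kind == "mapping":
        return {str(rng.choice(_WORDS)): float(np.round(rng.uniform(0, 1), 6))}
    if kind == "boolean":
        return bool(rng.integers(0, 2))
    raise AssertionError(kind)


def make_random_config_doc(rng: np.random.Generator) -> dict:
    """A random document satisfying every schema invariant."""
    n_ds = int(rng.integers(1, 4))
    uids = [f"ds{i}" for i in range(n_ds)]
    datasets = []
    for uid in uids:
        files = []
        for _ in range(int(rng.integers(0, 4))):
            ftype, opts = _SIMPLE_FILE_TYPES[
                int(rng.integers(0, len(_SIMPLE_FILE_TYPES)))
            ]
            f = {"url": f"data/{rng.integers(0, 999)}.bin", "fileType": ftype}
            if opts and rng.integers(0, 2):
                f["options"] = dict(opts)
            if rng.integers(0, 2):
                f["entity"] = {"obsType": str(rng.choice(["cell", "spot", "molecule"]))}
            files.append(f)
        datasets.append({"uid": uid, "name": str(rng.choice(_WORDS)), "files": files})
    ctype_names = [str(c) for c in rng.choice(DEFAULT_REGISTRY.names(), size=6, replace=False)]
    cspace: dict = {}
    for ct in ctype_names:
        kind = DEFAULT_REGISTRY[ct].value_kind
        cspace[ct] = {
            name: _random_value(rng, kind)
            for name in ["A", "B"][: int(rng.integers(1, 3))]
        }
    view_types = list(VIEW_TYPES)
    layout = []
    for i in range(int(rng.integers(0, 5))):
        scopes = {}
        for ct in ctype_names:
            if rng.integers(0, 2):
                scopes[ct] = str(rng.choice(list(cspace[ct])))
        item = {
            "component": str(rng.choice(view_types)),
            "dataset": str(rng.choice(uids)),
            "uid": f"view-{i}",
            "x": int(rng.integers(0, 8)),
            "y": int(rng.integers(0, 8)),
            "w": int(rng.integers(1, 5)),
            "h": int(rng.integers(1, 5)),
        }
        if scopes:
            item["coordinationScopes"] = scopes
        layout.append(item)
    return {
        "version": "spec-1.0",
        "name": str(rng.choice(_WORDS)),
        "description": "",
        "datasets": datasets,
        "coordinationSpace": cspace,
        "layout": layout,
    }
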