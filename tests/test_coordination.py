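import itertools
import json

import numpy as np
import pytest

from cellviews.config import ConfigBuilder, deserialize, serialize
from cellviews.coordination import (
    DEFAULT_REGISTRY,
    CoordinationSpace,
    CoordinationType,
    link_views,
    resolve_view_state,
    scope_name_sequence,
    set_value,
    snapshot,
)
from cellviews.errors import (
    CoordinationError,
    DanglingScopeError,
    RegistryError,
)


def _two_view_config():
    b = ConfigBuilder()
    b.add_dataset("A")
    b.add_view("scatterplot", "A", uid="sc")
    b.add_view("heatmap", "A", x=2, uid="hm")
    return b.build()


class TestRegistry:
    def test_many_linkable_parameters(self):
        """Views can be linked on well over fifty distinct properties."""
        assert len(DEFAULT_REGISTRY) >= 51

    def test_register_and_resolve_default(self):
        reg = DEFAULT_REGISTRY.copy()
        reg.register(CoordinationType("myZoom", "number", 0.0))
        assert reg["myZoom"].default == 0.0

    def test_duplicate_name_rejected(self):
        reg = DEFAULT_REGISTRY.copy()
        with pytest.raises(RegistryError):
            reg.register(CoordinationType("spatialZoom", "number", 0.0))

    def test_default_must_conform(self):
        with pytest.raises(ValueError):
            CoordinationType("bad", "number", "not-a-number")

    def test_scope_names_spreadsheet_order(self):
        names = list(itertools.islice(scope_name_sequence(), 28))
        assert names[:3] == ["A", "B", "C"]
        assert names[25:28] == ["Z", "AA", "AB"]


class TestLinking:
    def test_linked_views_resolve_shared_selection(self):
        cfg = _two_view_config()
        link_views(cfg, ["sc", "hm"], "featureSelection", ["Lamp5", "Rorb"])
        for uid in ("sc", "hm"):
            assert resolve_view_state(cfg, uid)["featureSelection"] == [
                "Lamp5",
                "Rorb",
            ]

    def test_single_view_scope_is_fine(self):
        cfg = _two_view_config()
        scope = link_views(cfg, ["sc"], "embeddingZoom", 2.5)
        assert cfg.coordination_space.get("embeddingZoom", scope) == 2.5

    def test_wrong_value_kind_rejected(self):
        cfg = _two_view_config()
        with pytest.raises(CoordinationError):
            link_views(cfg, ["sc"], "featureSelection", 3.0)

    def test_unknown_view_or_type(self):
        cfg = _two_view_config()
        with pytest.raises(CoordinationError):
            link_views(cfg, ["nope"], "featureSelection", ["x"])
        with pytest.raises(RegistryError):
            link_views(cfg, ["sc"], "notAType", 1.0)


class TestSetValue:
    def test_update_reaches_exactly_linked_views(self):
        """Three views on one scope, one on another: mutating the first
        scope changes the three and leaves the fourth untouched."""
        b = ConfigBuilder()
        b.add_dataset("A")
        for i in range(4):
            b.add_view("scatterplot", "A", x=i, uid=f"v{i}")
        cfg = b.build()
        sa = link_views(cfg, ["v0", "v1", "v2"], "embeddingZoom", 1.0)
        sb = link_views(cfg, ["v3"], "embeddingZoom", 5.0)
        before = {u: resolve_view_state(cfg, u).resolved for u in "v0 v1 v2 v3".split()}
        set_value(cfg.coordination_space, "embeddingZoom", sa, 2.0)
        after = {u: resolve_view_state(cfg, u).resolved for u in "v0 v1 v2 v3".split()}
        for u in ("v0", "v1", "v2"):
            assert before[u]["embeddingZoom"] == 1.0
            assert after[u]["embeddingZoom"] == 2.0
        assert after["v3"] == before["v3"]
        # and no other coordination type moved
        for u in ("v0", "v1", "v2"):
            changed = {
                k for k in after[u] if after[u][k] != before[u][k]
            }
            assert changed == {"embeddingZoom"}
        assert cfg.coordination_space.get("embeddingZoom", sb) == 5.0

    def test_idempotent_set(self):
        space = CoordinationSpace()
        space.add_scope("spatialZoom", 3.0, name="A")
        before = space.to_dict()
        set_value(space, "spatialZoom", "A", 3.0)
        assert space.to_dict() == before

    def test_unknown_scope_rejected(self):
        space = CoordinationSpace()
        with pytest.raises(DanglingScopeError):
            set_value(space, "spatialZoom", "Q", 1.0)


class TestResolve:
    def test_unlinked_view_gets_all_defaults(self):
        cfg = _two_view_config()
        state = resolve_view_state(cfg, "sc")
        relevant = {"embeddingZoom", "featureSelection", "obsColorEncoding"}
        assert relevant <= set(state.resolved)
        assert state["embeddingZoom"] == 0.0
        assert state["featureSelection"] is None
        assert state["obsColorEncoding"] == "setMembership"

    def test_resolved_covers_exactly_relevant_types(self):
        from cellviews.data_model import VIEW_TYPES

        cfg = _two_view_config()
        state = resolve_view_state(cfg, "hm")
        assert set(state.resolved) == set(VIEW_TYPES["heatmap"].coordination_types)

    def test_linked_selection_resolves(self):
        cfg = _two_view_config()
        link_views(cfg, ["sc"], "featureSelection", ["CD56"])
        assert resolve_view_state(cfg, "sc")["featureSelection"] == ["CD56"]

    def test_deleted_scope_is_a_loud_error(self):
        cfg = _two_view_config()
        scope = link_views(cfg, ["sc"], "featureSelection", ["CD56"])
        cfg.coordination_space.delete_scope("featureSelection", scope)
        with pytest.raises(DanglingScopeError):
            resolve_view_state(cfg, "sc")


class TestSnapshot:
    def test_snapshot_restore_reproduces_states(self):
        cfg = _two_view_config()
        scope = link_views(cfg, ["sc", "hm"], "featureSelection", ["GZMB"])
        saved = snapshot(cfg)
        originals = {
            u: resolve_view_state(cfg, u).resolved for u in ("sc", "hm")
        }
        set_value(cfg.coordination_space, "featureSelection", scope, ["PRF1"])
        restored = deserialize(saved)
        for u in ("sc", "hm"):
            assert resolve_view_state(restored, u).resolved == originals[u]

    def test_snapshot_is_valid_config(self):
        from cellviews.config import validate_config

        cfg = _two_view_config()
        assert validate_config(json.loads(snapshot(cfg))).valid

    def test_snapshot_diff_localized_to_changed_scope(self):
        cfg = _two_view_config()
        scope = link_views(cfg, ["sc", "hm"], "featureSelection", ["GZMB"])
        before = json.loads(snapshot(cfg))
        set_value(cfg.coordination_space, "featureSelection", scope, ["PRF1"])
        after = json.loads(snapshot(cfg))
        assert before != after
        after["coordinationSpace"]["featureSelection"][scope] = ["GZMB"]
        assert before == after


class TestCoordinationGraph:
    def test_views_agree_iff_same_scope(self):
        """Coordination is an equivalence through scopes: two views
        resolve the same value for a type exactly when they reference
        the same scope (random link graphs)."""
        rng = np.random.default_rng(42)
        for _ in range(60):
            b = ConfigBuilder()
            b.add_dataset("A")
            n = int(rng.integers(2, 6))
            uids = [b.add_view("scatterplot", "A", x=i) for i in range(n)]
            cfg = b.build()
            n_scopes = int(rng.integers(1, 4))
            values = [float(k + 1) * 10 for k in range(n_scopes)]
            assignment = {}
            scope_names = []
            groups = [rng.integers(0, n_scopes) for _ in uids]
            for k in range(n_scopes):
                members = [u for u, g in zip(uids, groups) if g == k]
                if not members:
                    continue
                s = link_views(cfg, members, "embeddingZoom", values[k])
                scope_names.append(s)
                for m in members:
                    assignment[m] = s
            for u1, u2 in itertools.combinations(uids, 2):
                v1 = resolve_view_state(cfg, u1)["embeddingZoom"]
                v2 = resolve_view_state(cfg, u2)["embeddingZoom"]
                same_scope = assignment[u1] == assignment[u2]
                assert (v1 == v2) == same_scope
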