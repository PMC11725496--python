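"""Coordinated-multiple-views state model.

Views are never linked to each other directly. Each linkable property is a
*coordination type* (``spatialZoom``, ``featureSelection``, ...), and the
coordination space holds named values of those types called *coordination
scopes*. Two views are coordinated on a property exactly when their layout
entries reference the same scope name for that coordination type; updating
the scope's value updates every linked view, and no other.

There is no event loop here: "propagation" is expressed purely as state
resolution — :func:`resolve_view_state` recomputes what a view sees from
the current space, falling back to registry defaults for unlinked types.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field
from typing import Any, Iterable, Mapping

from .errors import CoordinationError, DanglingScopeError, RegistryError

__all__ = [
    "CoordinationType",
    "CoordinationTypeRegistry",
    "CoordinationSpace",
    "ViewState",
    "DEFAULT_REGISTRY",
    "register_coordination_type",
    "link_views",
    "set_value",
    "resolve_view_state",
    "snapshot",
    "scope_name_sequence",
]

#: Allowed value kinds for coordination values. Coordination values are
#: user-facing state (camera positions, selections, visibility flags), so
#: they are plain JSON-representable values, never arrays.
VALUE_KINDS = ("number", "string", "string-list", "mapping", "boolean")


def _conforms(value: Any, kind: str, nullable: bool) -> bool:
    if value is None:
        return nullable
    if kind == "number":
        return isinstance(value, (int, float)) and not isinstance(value, bool)
    if kind == "string":
        return isinstance(value, str)
    if kind == "string-list":
        return isinstance(value, (list, tuple)) and all(
            isinstance(v, str) for v in value
        )
    if kind == "mapping":
        return isinstance(value, Mapping)
    if kind == "boolean":
        return isinstance(value, bool)
    raise ValueError(f"unknown value kind {kind!r}")


@dataclass(frozen=True)
class CoordinationType:
    """A named, typed property that views can be linked on."""

    name: str
    value_kind: str
    default: Any = None
    nullable: bool = False

    def __post_init__(self) -> None:
        if self.value_kind not in VALUE_KINDS:
            raise ValueError(f"unknown value kind {self.value_kind!r}")
        if not _conforms(self.default, self.value_kind, nullable=True):
            raise ValueError(
                f"default for {self.name!r} does not conform to kind "
                f"{self.value_kind!r}"
            )

    def conforms(self, value: Any) -> bool:
        return _conforms(value, self.value_kind, self.nullable)


class CoordinationTypeRegistry:
    """Registry of coordination types; names are unique."""

    def __init__(self) -> None:
        self._types: dict[str, CoordinationType] = {}

    def register(self, ctype: CoordinationType) -> CoordinationType:
        if ctype.name in self._types:
            raise RegistryError(
                f"coordination type {ctype.name!r} is already registered"
            )
        self._types[ctype.name] = ctype
        return ctype

    def __contains__(self, name: str) -> bool:
        return name in self._types

    def __getitem__(self, name: str) -> CoordinationType:
        try:
            return self._types[name]
        except KeyError:
            raise RegistryError(f"unknown coordination type {name!r}") from None

    def __len__(self) -> int:
        return len(self._types)

    def names(self) -> list[str]:
        return list(self._types)

    def copy(self) -> "CoordinationTypeRegistry":
        new = CoordinationTypeRegistry()
        new._types = dict(self._types)
        return new


def _build_default_registry() -> CoordinationTypeRegistry:
    reg = CoordinationTypeRegistry()
    num, s, sl, m, b = "number", "string", "string-list", "mapping", "boolean"
    entries: list[tuple] = [
        # entity identifiers
        ("dataset", s, None, True),
        ("obsType", s, "cell", False),
        ("featureType", s, "gene", False),
        ("featureValueType", s, "expression", False),
        # spatial camera
        ("spatialZoom", num, 0.0, False),
        ("spatialTargetX", num, 0.0, False),
        ("spatialTargetY", num, 0.0, False),
        ("spatialTargetZ", num, 0.0, False),
        ("spatialRotationX", num, 0.0, False),
        ("spatialRotationY", num, 0.0, False),
        ("spatialRotationZ", num, 0.0, False),
        ("spatialAxisFixed", b, False, False),
        # embedding (dimensionality-reduction scatterplot) camera
        ("embeddingType", s, None, True),
        ("embeddingZoom", num, 0.0, False),
        ("embeddingTargetX", num, 0.0, False),
        ("embeddingTargetY", num, 0.0, False),
        ("embeddingObsRadius", num, 1.0, False),
        ("embeddingObsOpacity", num, 1.0, False),
        # heatmap camera
        ("heatmapZoomX", num, 0.0, False),
        ("heatmapZoomY", num, 0.0, False),
        ("heatmapTargetX", num, 0.0, False),
        ("heatmapTargetY", num, 0.0, False),
        ("heatmapAggregation", s, "mean", False),
        # selections and highlights
        ("featureSelection", sl, None, True),
        ("featureHighlight", s, None, True),
        ("obsHighlight", s, None, True),
        ("obsSetSelection", sl, None, True),
        ("obsSetHighlight", s, None, True),
        ("obsFilter", sl, None, True),
        ("obsLabelsType", s, None, True),
        # color encodings
        ("obsColorEncoding", s, "setMembership", False),
        ("featureValueColormap", s, "viridis", False),
        ("featureValueColormapRange", m, {"min": 0.0, "max": 1.0}, False),
        ("obsSetColor", m, {}, False),
        # image layer
        ("imageLayerVisible", b, True, False),
        ("imageLayerOpacity", num, 1.0, False),
        ("imageChannelSelection", m, {"c": [0], "t": 0, "z": 0}, False),
        ("imageChannelColor", m, {}, False),
        ("imageChannelWindow", m, {}, False),
        # segmentation layer
        ("segmentationLayerVisible", b, True, False),
        ("segmentationLayerOpacity", num, 1.0, False),
        ("segmentationFilled", b, True, False),
        # point layer (e.g. individual molecules)
        ("pointLayerVisible", b, True, False),
        ("pointLayerOpacity", num, 1.0, False),
        ("pointRadius", num, 1.0, False),
        # spot layer (e.g. capture locations)
        ("spotLayerVisible", b, True, False),
        ("spotLayerOpacity", num, 1.0, False),
        ("spotRadius", num, 4.0, False),
        # genomic camera placeholders
        ("genomicZoomX", num, 0.0, False),
        ("genomicZoomY", num, 0.0, False),
        ("genomicTargetX", num, 0.0, False),
        ("genomicTargetY", num, 0.0, False),
        # user preferences
        ("tooltipsVisible", b, True, False),
        ("legendVisible", b, True, False),
    ]
    for name, kind, default, nullable in entries:
        reg.register(CoordinationType(name, kind, default, nullable))
    return reg


#: The built-in registry. Views can be linked on any subset of these
#: (well over fifty) properties.
DEFAULT_REGISTRY = _build_default_registry()


def register_coordination_type(
    name: str,
    value_kind: str,
    default: Any = None,
    nullable: bool = False,
    *,
    registry: CoordinationTypeRegistry = DEFAULT_REGISTRY,
) -> CoordinationType:
    """Register a new coordination type. Duplicate names are an error."""
    return registry.register(CoordinationType(name, value_kind, default, nullable))


def scope_name_sequence() -> Iterable[str]:
    """Yield scope names in creation order: A, B, ..., Z, AA, AB, ..."""
    import itertools
    import string

    for size in itertools.count(1):
        for letters in itertools.product(string.ascii_uppercase, repeat=size):
            yield "".join(letters)


class CoordinationSpace:
    """Map of coordination type name -> scope name -> value."""

    def __init__(
        self,
        values: Mapping[str, Mapping[str, Any]] | None = None,
        *,
        registry: CoordinationTypeRegistry = DEFAULT_REGISTRY,
    ) -> None:
        self.registry = registry
        self._values: dict[str, dict[str, Any]] = {}
        if values:
            for ctype, scopes in values.items():
                for scope, value in scopes.items():
                    self.add_scope(ctype, value, name=scope)

    def to_dict(self) -> dict[str, dict[str, Any]]:
        return copy.deepcopy(self._values)

    def types(self) -> list[str]:
        return list(self._values)

    def scopes(self, ctype: str) -> dict[str, Any]:
        return dict(self._values.get(ctype, {}))

    def has_scope(self, ctype: str, scope: str) -> bool:
        return scope in self._values.get(ctype, {})

    def get(self, ctype: str, scope: str) -> Any:
        try:
            return self._values[ctype][scope]
        except KeyError:
            raise DanglingScopeError(
                f"coordination scope {scope!r} of type {ctype!r} does not exist"
            ) from None

    def add_scope(self, ctype: str, value: Any, name: str | None = None) -> str:
        """Add a scope holding ``value``; auto-names it if ``name`` is None."""
        ct = self.registry[ctype]
        if not ct.conforms(value):
            raise CoordinationError(
                f"value {value!r} does not conform to coordination type "
                f"{ctype!r} (kind {ct.value_kind})"
            )
        scopes = self._values.setdefault(ctype, {})
        if name is None:
            for candidate in scope_name_sequence():
                if candidate not in scopes:
                    name = candidate
                    break
        elif name in scopes:
            raise CoordinationError(
                f"scope {name!r} already exists for type {ctype!r}"
            )
        scopes[name] = copy.deepcopy(value)
        return name

    def set(self, ctype: str, scope: str, value: Any) -> None:
        if not self.has_scope(ctype, scope):
            raise DanglingScopeError(
                f"cannot set unknown scope {scope!r} of type {ctype!r}"
            )
        ct = self.registry[ctype]
        if not ct.conforms(value):
            raise CoordinationError(
                f"value {value!r} does not conform to coordination type "
                f"{ctype!r} (kind {ct.value_kind})"
            )
        self._values[ctype][scope] = copy.deepcopy(value)

    def delete_scope(self, ctype: str, scope: str) -> None:
        if not self.has_scope(ctype, scope):
            raise DanglingScopeError(
                f"cannot delete unknown scope {scope!r} of type {ctype!r}"
            )
        del self._values[ctype][scope]

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, CoordinationSpace) and self._values == other._values
        )


@dataclass
class ViewState:
    """The coordination values a single view resolves to."""

    view_uid: str
    resolved: dict[str, Any] = field(default_factory=dict)

    def __getitem__(self, ctype: str) -> Any:
        return self.resolved[ctype]


def _find_view(config, view_uid: str):
    for item in config.layout:
        if item.uid == view_uid:
            return item
    raise CoordinationError(f"unknown view {view_uid!r}")


def link_views(config, view_uids: list[str], ctype: str, initial: Any) -> str:
    """Link views on ``ctype`` through a fresh scope holding ``initial``.

    Returns the auto-assigned scope name; each view's coordinationScopes
    mapping is pointed at it.
    """
    items = [_find_view(config, uid) for uid in view_uids]
    scope = config.coordination_space.add_scope(ctype, initial)
    for item in items:
        item.coordination_scopes[ctype] = scope
    return scope


def set_value(space: CoordinationSpace, ctype: str, scope: str, value: Any) -> CoordinationSpace:
    """Set the value held by an existing scope; returns the space."""
    space.set(ctype, scope, value)
    return space


def resolve_view_state(
    config, view_uid: str, *, registry: CoordinationTypeRegistry | None = None
) -> ViewState:
    """Resolve the coordination values a view currently sees.

    For each coordination type relevant to the view's type: if the view is
    linked to a scope, the scope's value; otherwise the registry default.
    A reference to a scope that does not exist (e.g. deleted after linking)
    raises :class:`DanglingScopeError` rather than silently falling back.
    """
    from .data_model import VIEW_TYPES

    item = _find_view(config, view_uid)
    space = config.coordination_space
    reg = registry or space.registry
    try:
        relevant = VIEW_TYPES[item.component].coordination_types
    except KeyError:
        raise CoordinationError(f"unknown view type {item.component!r}") from None
    resolved: dict[str, Any] = {}
    for ctype in relevant:
        if ctype in item.coordination_scopes:
            scope = item.coordination_scopes[ctype]
            resolved[ctype] = copy.deepcopy(space.get(ctype, scope))
        else:
            resolved[ctype] = copy.deepcopy(reg[ctype].default)
    return ViewState(view_uid=view_uid, resolved=resolved)


def snapshot(config) -> str:
    """Canonical JSON of the full config state.

    Because all view state lives in the config (coordination space plus
    per-view scope references), the snapshot *is* a serialized config:
    deserializing it and re-resolving every view reproduces identical
    view states.
    """
    from .config import serialize

    return serialize(config)
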