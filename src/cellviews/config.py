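"""The declarative view-configuration document.

A view config is a single JSON document that fully describes a
visualization: the datasets and files it draws from, the coordination
space that links views, and a grid layout of views. Because all state
lives in the document, a config *is* a snapshot — it can be serialized
canonically, diffed, and shared as a self-contained URL fragment with
no server involved.

Canonical serialization: sorted keys, UTF-8, no insignificant
whitespace, non-finite numbers rejected. Two structurally equal configs
therefore serialize to byte-identical text.
"""

from __future__ import annotations

import base64
import json
import zlib
from dataclasses import dataclass, field
from typing import Any, Mapping, Optional

from .coordination import DEFAULT_REGISTRY, CoordinationSpace, CoordinationTypeRegistry
from .data_model import VIEW_TYPES, EntityTriple, FILE_TYPES
from .errors import (
    ConfigBuildError,
    ConfigParseError,
    ConfigValidationError,
    SerializationError,
    ShareURLError,
)

__all__ = [
    "SCHEMA_VERSION",
    "FileSpec",
    "DatasetSpec",
    "LayoutItem",
    "ViewConfig",
    "Violation",
    "ValidationReport",
    "validate_config",
    "serialize",
    "deserialize",
    "to_share_url",
    "from_share_url",
    "ConfigBuilder",
]

#: The one schema version this package reads and writes. Unknown
#: versions are rejected rather than guessed at.
SCHEMA_VERSION = "spec-1.0"


@dataclass
class FileSpec:
    url: str
    file_type: str
    options: dict[str, Any] = field(default_factory=dict)
    entity: Optional[EntityTriple] = None

    def to_dict(self) -> dict[str, Any]:
        out: dict[str, Any] = {"url": self.url, "fileType": self.file_type}
        if self.options:
            out["options"] = dict(self.options)
        if self.entity is not None and self.entity.to_dict():
            out["entity"] = self.entity.to_dict()
        return out

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "FileSpec":
        entity = (
            EntityTriple.from_dict(d["entity"]) if "entity" in d else None
        )
        return cls(d["url"], d["fileType"], dict(d.get("options", {})), entity)


@dataclass
class DatasetSpec:
    uid: str
    name: str = ""
    files: list[FileSpec] = field(default_factory=list)

    def to_dict(self) -> dict[str, Any]:
        return {
            "uid": self.uid,
            "name": self.name,
            "files": [f.to_dict() for f in self.files],
        }

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "DatasetSpec":
        return cls(
            d["uid"],
            d.get("name", ""),
            [FileSpec.from_dict(f) for f in d.get("files", [])],
        )


@dataclass
class LayoutItem:
    component: str
    dataset: str
    x: int = 0
    y: int = 0
    w: int = 1
    h: int = 1
    uid: str = ""
    coordination_scopes: dict[str, str] = field(default_factory=dict)

    def to_dict(self) -> dict[str, Any]:
        out: dict[str, Any] = {
            "component": self.component,
            "dataset": self.dataset,
            "uid": self.uid,
            "x": self.x,
            "y": self.y,
            "w": self.w,
            "h": self.h,
        }
        if self.coordination_scopes:
            out["coordinationScopes"] = dict(self.coordination_scopes)
        return out

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "LayoutItem":
        return cls(
            d["component"],
            d["dataset"],
            d.get("x", 0),
            d.get("y", 0),
            d.get("w", 1),
            d.get("h", 1),
            d.get("uid", ""),
            dict(d.get("coordinationScopes", {})),
        )


@dataclass
class ViewConfig:
    version: str = SCHEMA_VERSION
    name: str = ""
    description: str = ""
    datasets: list[DatasetSpec] = field(default_factory=list)
    coordination_space: CoordinationSpace = field(
        default_factory=CoordinationSpace
    )
    layout: list[LayoutItem] = field(default_factory=list)

    def to_dict(self) -> dict[str, Any]:
        return {
            "version": self.version,
            "name": self.name,
            "description": self.description,
            "datasets": [d.to_dict() for d in self.datasets],
            "coordinationSpace": self.coordination_space.to_dict(),
            "layout": [v.to_dict() for v in self.layout],
        }

    @classmethod
    def from_dict(
        cls,
        d: Mapping[str, Any],
        *,
        registry: CoordinationTypeRegistry = DEFAULT_REGISTRY,
    ) -> "ViewConfig":
        return cls(
            version=d.get("version", ""),
            name=d.get("name", ""),
            description=d.get("description", ""),
            datasets=[DatasetSpec.from_dict(x) for x in d.get("datasets", [])],
            coordination_space=CoordinationSpace(
                d.get("coordinationSpace", {}), registry=registry
            ),
            layout=[LayoutItem.from_dict(x) for x in d.get("layout", [])],
        )

    def get_dataset(self, uid: str) -> DatasetSpec:
        for ds in self.datasets:
            if ds.uid == uid:
                return ds
        raise KeyError(uid)

    def get_view(self, uid: str) -> LayoutItem:
        for item in self.layout:
            if item.uid == uid:
                return item
        raise KeyError(uid)


@dataclass(frozen=True)
class Violation:
    path: str  # JSON-pointer-style, e.g. "/layout/0/dataset"
    message: str


@dataclass
class ValidationReport:
    violations: list[Violation] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    @property
    def valid(self) -> bool:
        return not self.violations

    def add(self, path: str, message: str) -> None:
        self.violations.append(Violation(path, message))

    def to_dict(self) -> dict[str, Any]:
        return {
            "valid": self.valid,
            "violations": [
                {"path": v.path, "message": v.message} for v in self.violations
            ],
            "warnings": list(self.warnings),
        }


def _is_str(x: Any) -> bool:
    return isinstance(x, str)


def _is_nonneg_int(x: Any) -> bool:
    return isinstance(x, int) and not isinstance(x, bool) and x >= 0


def validate_config(
    document: Any,
    *,
    registry: CoordinationTypeRegistry = DEFAULT_REGISTRY,
) -> ValidationReport:
    """Validate a JSON-like mapping against the view-config schema.

    Returns a report listing every violation with a JSON-pointer-style
    path; an empty violation list means the document is valid. Benign
    oddities (overlapping grid rectangles) are reported as warnings,
    not violations.
    """
    rep = ValidationReport()
    if not isinstance(document, Mapping):
        rep.add("", "config must be a JSON object")
        return rep

    version = document.get("version")
    if version is None:
        rep.add("/version", "missing required key 'version'")
    elif version != SCHEMA_VERSION:
        rep.add(
            "/version",
            f"unsupported schema version {version!r}; expected {SCHEMA_VERSION!r}",
        )
    for key in ("name", "description"):
        if key in document and not _is_str(document[key]):
            rep.add(f"/{key}", "must be a string")

    # --- datasets ---
    uids: list[str] = []
    datasets = document.get("datasets")
    if datasets is None:
        rep.add("/datasets", "missing required key 'datasets'")
        datasets = []
    elif not isinstance(datasets, list):
        rep.add("/datasets", "must be a list")
        datasets = []
    for i, ds in enumerate(datasets):
        p = f"/datasets/{i}"
        if not isinstance(ds, Mapping):
            rep.add(p, "dataset must be an object")
            continue
        uid = ds.get("uid")
        if not (_is_str(uid) and uid):
            rep.add(f"{p}/uid", "dataset uid must be a nonempty string")
        elif uid in uids:
            rep.add(f"{p}/uid", f"duplicate dataset uid {uid!r}")
        else:
            uids.append(uid)
        files = ds.get("files", [])
        if not isinstance(files, list):
            rep.add(f"{p}/files", "must be a list")
            files = []
        for j, fs in enumerate(files):
            fp = f"{p}/files/{j}"
            if not isinstance(fs, Mapping):
                rep.add(fp, "file must be an object")
                continue
            if not (_is_str(fs.get("url")) and fs.get("url")):
                rep.add(f"{fp}/url", "file url must be a nonempty string")
            ftype = fs.get("fileType")
            if not _is_str(ftype):
                rep.add(f"{fp}/fileType", "missing or non-string fileType")
            elif ftype not in FILE_TYPES:
                rep.add(f"{fp}/fileType", f"unregistered file type {ftype!r}")
            else:
                opts = fs.get("options", {})
                if not isinstance(opts, Mapping):
                    rep.add(f"{fp}/options", "options must be an object")
                else:
                    allowed = set(FILE_TYPES[ftype].options_schema)
                    for k in sorted(set(opts) - allowed):
                        rep.add(
                            f"{fp}/options/{k}",
                            f"option {k!r} not declared by file type {ftype!r}",
                        )
            ent = fs.get("entity", {})
            if not isinstance(ent, Mapping):
                rep.add(f"{fp}/entity", "entity must be an object")
            else:
                for k, v in ent.items():
                    if k not in ("obsType", "featureType", "featureValueType"):
                        rep.add(f"{fp}/entity/{k}", f"unknown entity component {k!r}")
                    elif not (_is_str(v) and v):
                        rep.add(f"{fp}/entity/{k}", "must be a nonempty identifier")

    # --- coordination space ---
    cspace = document.get("coordinationSpace", {})
    if not isinstance(cspace, Mapping):
        rep.add("/coordinationSpace", "must be an object")
        cspace = {}
    for ctype, scopes in cspace.items():
        cp = f"/coordinationSpace/{ctype}"
        if ctype not in registry:
            rep.add(cp, f"unknown coordination type {ctype!r}")
            continue
        if not isinstance(scopes, Mapping):
            rep.add(cp, "scopes must be an object")
            continue
        ct = registry[ctype]
        for scope, value in scopes.items():
            if not ct.conforms(value):
                rep.add(
                    f"{cp}/{scope}",
                    f"value does not conform to kind {ct.value_kind!r}",
                )

    # --- layout ---
    layout = document.get("layout", [])
    if not isinstance(layout, list):
        rep.add("/layout", "must be a list")
        layout = []
    rects = []
    view_uids: list[str] = []
    for i, item in enumerate(layout):
        p = f"/layout/{i}"
        if not isinstance(item, Mapping):
            rep.add(p, "layout item must be an object")
            continue
        comp = item.get("component")
        if not _is_str(comp):
            rep.add(f"{p}/component", "missing or non-string component")
        elif comp not in VIEW_TYPES:
            rep.add(f"{p}/component", f"unregistered view type {comp!r}")
        ds_ref = item.get("dataset")
        if not _is_str(ds_ref):
            rep.add(f"{p}/dataset", "missing or non-string dataset reference")
        elif ds_ref not in uids:
            rep.add(
                f"{p}/dataset",
                f"references dataset uid {ds_ref!r} absent from datasets",
            )
        vuid = item.get("uid", "")
        if vuid:
            if vuid in view_uids:
                rep.add(f"{p}/uid", f"duplicate view uid {vuid!r}")
            view_uids.append(vuid)
        for key in ("x", "y", "w", "h"):
            if key in item and not _is_nonneg_int(item[key]):
                rep.add(f"{p}/{key}", "must be a nonnegative integer")
        w, h = item.get("w", 1), item.get("h", 1)
        if _is_nonneg_int(w) and w == 0:
            rep.add(f"{p}/w", "view width must be > 0")
        if _is_nonneg_int(h) and h == 0:
            rep.add(f"{p}/h", "view height must be > 0")
        if all(_is_nonneg_int(item.get(k, 1)) for k in ("x", "y", "w", "h")):
            rects.append(
                (i, item.get("x", 0), item.get("y", 0), item.get("w", 1), item.get("h", 1))
            )
        scopes_map = item.get("coordinationScopes", {})
        if not isinstance(scopes_map, Mapping):
            rep.add(f"{p}/coordinationScopes", "must be an object")
            continue
        for ctype, scope in scopes_map.items():
            sp = f"{p}/coordinationScopes/{ctype}"
            if ctype not in registry:
                rep.add(sp, f"unknown coordination type {ctype!r}")
                continue
            present = (
                isinstance(cspace.get(ctype), Mapping)
                and scope in cspace[ctype]
            )
            if not present and registry[ctype].default is None and not registry[ctype].nullable:
                rep.add(
                    sp,
                    f"scope {scope!r} absent from coordinationSpace and type "
                    f"{ctype!r} has no usable default",
                )

    # overlap is legal on the abstract grid, but usually unintended
    for a in range(len(rects)):
        for b in range(a + 1, len(rects)):
            ia, xa, ya, wa, ha = rects[a]
            ib, xb, yb, wb, hb = rects[b]
            if xa < xb + wb and xb < xa + wa and ya < yb + hb and yb < ya + ha:
                rep.warnings.append(
                    f"views at layout[{ia}] and layout[{ib}] overlap on the grid"
                )
    return rep


def canonical_json(obj: Any) -> str:
    """Canonical JSON text: sorted keys, compact, non-finite rejected."""
    try:
        return json.dumps(
            obj,
            sort_keys=True,
            separators=(",", ":"),
            ensure_ascii=False,
            allow_nan=False,
        )
    except ValueError as exc:
        raise SerializationError(f"value not representable in JSON: {exc}") from exc


def serialize(config: ViewConfig) -> str:
    """Serialize a config to canonical JSON; refuses invalid configs."""
    doc = config.to_dict()
    report = validate_config(doc, registry=config.coordination_space.registry)
    if not report.valid:
        raise ConfigValidationError(report)
    return canonical_json(doc)


def deserialize(
    text: str, *, registry: CoordinationTypeRegistry = DEFAULT_REGISTRY
) -> ViewConfig:
    """Parse and validate canonical (or any) config JSON text."""
    try:
        doc = json.loads(text)
    except json.JSONDecodeError as exc:
        raise ConfigParseError(f"not parseable as JSON: {exc}") from exc
    report = validate_config(doc, registry=registry)
    if not report.valid:
        raise ConfigValidationError(report)
    return ViewConfig.from_dict(doc, registry=registry)


_FRAGMENT_KEY = "cfg"


def to_share_url(config: ViewConfig, base: str) -> str:
    """Encode a config into a self-contained shareable URL.

    The canonical JSON is DEFLATE-compressed and base64url-encoded into
    the URL fragment, so the link needs no server-side state.
    """
    if "#" in base:
        raise ShareURLError("base URL must not already carry a fragment")
    payload = base64.urlsafe_b64encode(
        zlib.compress(serialize(config).encode("utf-8"), 9)
    ).decode("ascii")
    return f"{base}#{_FRAGMENT_KEY}={payload}"


def from_share_url(
    url: str, *, registry: CoordinationTypeRegistry = DEFAULT_REGISTRY
) -> ViewConfig:
    """Decode a config from a share URL produced by :func:`to_share_url`."""
    if "#" not in url:
        raise ShareURLError("URL carries no embedded config (no fragment)")
    fragment = url.split("#", 1)[1]
    payload = None
    for part in fragment.split("&"):
        if part.startswith(_FRAGMENT_KEY + "="):
            payload = part[len(_FRAGMENT_KEY) + 1 :]
            break
    if not payload:
        raise ShareURLError(
            f"URL fragment carries no {_FRAGMENT_KEY!r} config payload"
        )
    try:
        text = zlib.decompress(
            base64.urlsafe_b64decode(payload.encode("ascii"))
        ).decode("utf-8")
    except Exception as exc:
        raise ShareURLError(f"config payload is not decodable: {exc}") from exc
    return deserialize(text, registry=registry)


class ConfigBuilder:
    """Fluent programmatic construction of view configs.

    >>> b = ConfigBuilder(name="demo")
    >>> _ = b.add_dataset("A")
    >>> v1 = b.add_view("scatterplot", "A")
    >>> cfg = b.build()
    """

    def __init__(
        self,
        name: str = "",
        description: str = "",
        *,
        registry: CoordinationTypeRegistry = DEFAULT_REGISTRY,
    ) -> None:
        self._config = ViewConfig(
            name=name,
            description=description,
            coordination_space=CoordinationSpace(registry=registry),
        )
        self._n_views = 0

    def add_dataset(self, uid: str, name: str = "") -> "ConfigBuilder":
        if not uid:
            raise ConfigBuildError("dataset uid must be nonempty")
        if any(ds.uid == uid for ds in self._config.datasets):
            raise ConfigBuildError(f"dataset uid {uid!r} already added")
        self._config.datasets.append(DatasetSpec(uid=uid, name=name))
        return self

    def add_file(
        self,
        dataset: str,
        url: str,
        file_type: str,
        options: Mapping[str, Any] | None = None,
        entity: EntityTriple | Mapping[str, str] | None = None,
    ) -> "ConfigBuilder":
        try:
            ds = self._config.get_dataset(dataset)
        except KeyError:
            raise ConfigBuildError(
                f"cannot add file to unknown dataset {dataset!r}"
            ) from None
        if file_type not in FILE_TYPES:
            raise ConfigBuildError(f"unregistered file type {file_type!r}")
        if entity is not None and not isinstance(entity, EntityTriple):
            entity = EntityTriple.from_dict(entity)
        ds.files.append(FileSpec(url, file_type, dict(options or {}), entity))
        return self

    def add_view(
        self,
        component: str,
        dataset: str,
        x: int = 0,
        y: int = 0,
        w: int = 1,
        h: int = 1,
        uid: str | None = None,
    ) -> str:
        """Add a view; returns its uid (auto-assigned if not given)."""
        if component not in VIEW_TYPES:
            raise ConfigBuildError(f"unregistered view type {component!r}")
        if not any(ds.uid == dataset for ds in self._config.datasets):
            raise ConfigBuildError(
                f"cannot add view for unknown dataset uid {dataset!r}"
            )
        if uid is None:
            uid = f"{component}-{self._n_views}"
        if any(v.uid == uid for v in self._config.layout):
            raise ConfigBuildError(f"view uid {uid!r} already in layout")
        self._n_views += 1
        self._config.layout.append(
            LayoutItem(component, dataset, x, y, w, h, uid=uid)
        )
        return uid

    def link_views(self, view_uids: list[str], ctype: str, initial: Any) -> str:
        """Link views on a coordination type; returns the new scope name."""
        from .coordination import link_views as _link

        return _link(self._config, view_uids, ctype, initial)

    def build(self) -> ViewConfig:
        report = validate_config(
            self._config.to_dict(),
            registry=self._config.coordination_space.registry,
        )
        if not report.valid:
            raise ConfigValidationError(report)
        return self._config
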