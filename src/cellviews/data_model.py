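"""Data types, file types and the entity-triple rules that match views to data.

The data model follows the observation-by-feature conventions of the
single-cell ecosystem: *observations* are the entities being measured
(cells, molecules, spots, beads, nuclei), *features* are the measured
characteristics (genes, proteins, peaks), and *feature values* are the
measured quantities (expression, counts, intensities). A view is matched
to data by comparing these identifiers — but only the components the
view's type actually consults: a heatmap is identified by all three,
while a feature list is identified by feature type alone.

A *data type* is a semantic payload category (``obsFeatureMatrix``,
``obsLocations``, ...); a *file type* pairs a data type with a file
format. A joint file type exposes several data types from a single file
(URL and options stated once), the canonical example being an
AnnData-style chunked store holding a matrix, embeddings and spatial
coordinates together.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Any, Mapping, Optional, Sequence

from .errors import DataMatchError, RegistryError

__all__ = [
    "EntityTriple",
    "DataTypeDescriptor",
    "FileTypeDescriptor",
    "Accessor",
    "Requirement",
    "ViewTypeDescriptor",
    "MatchReport",
    "DATA_TYPES",
    "FILE_TYPES",
    "VIEW_TYPES",
    "DEFAULT_ENTITY",
    "expand_joint_file_type",
    "dataset_manifest",
    "match_view_to_data",
]


@dataclass(frozen=True)
class EntityTriple:
    """(observation type, feature type, feature-value type), each optional."""

    obs_type: Optional[str] = None
    feature_type: Optional[str] = None
    feature_value_type: Optional[str] = None

    COMPONENTS = ("obs_type", "feature_type", "feature_value_type")

    def __post_init__(self) -> None:
        for comp in self.COMPONENTS:
            v = getattr(self, comp)
            if v is not None and (not isinstance(v, str) or not v):
                raise ValueError(f"{comp} must be a nonempty identifier, got {v!r}")

    def with_defaults(self, defaults: "EntityTriple") -> "EntityTriple":
        return EntityTriple(
            self.obs_type or defaults.obs_type,
            self.feature_type or defaults.feature_type,
            self.feature_value_type or defaults.feature_value_type,
        )

    def to_dict(self) -> dict[str, str]:
        out = {}
        if self.obs_type is not None:
            out["obsType"] = self.obs_type
        if self.feature_type is not None:
            out["featureType"] = self.feature_type
        if self.feature_value_type is not None:
            out["featureValueType"] = self.feature_value_type
        return out

    @classmethod
    def from_dict(cls, d: Mapping[str, str]) -> "EntityTriple":
        return cls(
            d.get("obsType"), d.get("featureType"), d.get("featureValueType")
        )


#: The dominant single-cell case; fills unspecified components of a file's
#: entity triple so that minimal configs work out of the box.
DEFAULT_ENTITY = EntityTriple("cell", "gene", "expression")


@dataclass(frozen=True)
class DataTypeDescriptor:
    """A semantic payload category and the entity axes that identify it."""

    name: str
    axes: tuple[str, ...]  # subset of EntityTriple.COMPONENTS


_ALL_AXES = EntityTriple.COMPONENTS

DATA_TYPES: dict[str, DataTypeDescriptor] = {
    d.name: d
    for d in [
        DataTypeDescriptor("obsFeatureMatrix", _ALL_AXES),
        DataTypeDescriptor("obsLocations", ("obs_type",)),
        DataTypeDescriptor("obsEmbedding", ("obs_type",)),
        DataTypeDescriptor("obsSegmentations", ("obs_type",)),
        DataTypeDescriptor("obsSets", ("obs_type",)),
        DataTypeDescriptor("image", ()),
    ]
}


@dataclass(frozen=True)
class FileTypeDescriptor:
    """A (data type, file format) pairing; joint types expose several."""

    name: str
    data_types: tuple[str, ...]
    options_schema: tuple[str, ...] = ()  # allowed option keys

    @property
    def joint(self) -> bool:
        return len(self.data_types) > 1


FILE_TYPES: dict[str, FileTypeDescriptor] = {
    f.name: f
    for f in [
        FileTypeDescriptor("obsFeatureMatrix.csv", ("obsFeatureMatrix",)),
        FileTypeDescriptor("obsLocations.csv", ("obsLocations",)),
        FileTypeDescriptor(
            "obsEmbedding.csv", ("obsEmbedding",), ("embeddingType",)
        ),
        FileTypeDescriptor("obsSets.json", ("obsSets",)),
        FileTypeDescriptor("obsFeatureMatrix.zarr", ("obsFeatureMatrix",), ("path",)),
        FileTypeDescriptor("image.ome-zarr", ("image",)),
        FileTypeDescriptor("image.ome-tiff", ("image",)),
        FileTypeDescriptor("obsSegmentations.ome-zarr", ("obsSegmentations",)),
        FileTypeDescriptor(
            "anndata.zarr",
            ("obsFeatureMatrix", "obsEmbedding", "obsLocations", "obsSets"),
            (
                "matrixPath",
                "embeddingPath",
                "embeddingType",
                "locationsPath",
                "setsPath",
            ),
        ),
    ]
}

#: Option key that routes each data type inside the AnnData-style joint
#: store. A data type whose option is absent is simply not exposed.
_ANNDATA_COMPONENT_OPTIONS = {
    "obsFeatureMatrix": "matrixPath",
    "obsEmbedding": "embeddingPath",
    "obsLocations": "locationsPath",
    "obsSets": "setsPath",
}


@dataclass(frozen=True)
class Accessor:
    """One loadable (data type, entity triple) unit exposed by a file."""

    data_type: str
    file_type: str
    url: str
    options: Mapping[str, Any]
    entity: EntityTriple
    file_index: int = 0
    ambiguous: bool = False

    def key(self) -> tuple:
        return (self.data_type, self.entity)


def expand_joint_file_type(filespec, file_index: int = 0) -> list[Accessor]:
    """Expand a file spec into one accessor per data type it exposes.

    The URL and options are stated once on the file and propagated to
    every accessor. A simple file type yields exactly one accessor; a
    joint type yields one per constituent data type present (for the
    AnnData-style store, presence is signalled by the per-component path
    option).
    """
    try:
        ft = FILE_TYPES[filespec.file_type]
    except KeyError:
        raise RegistryError(
            f"unregistered file type {filespec.file_type!r}"
        ) from None
    options = dict(filespec.options or {})
    unknown = sorted(set(options) - set(ft.options_schema))
    if unknown:
        raise RegistryError(
            f"file type {ft.name!r} does not accept options {unknown}"
        )
    entity = (filespec.entity or EntityTriple()).with_defaults(DEFAULT_ENTITY)
    accessors = []
    for dt in ft.data_types:
        if ft.name == "anndata.zarr":
            opt_key = _ANNDATA_COMPONENT_OPTIONS[dt]
            if opt_key not in options:
                continue
        accessors.append(
            Accessor(
                data_type=dt,
                file_type=ft.name,
                url=filespec.url,
                options=options,
                entity=entity,
                file_index=file_index,
            )
        )
    return accessors


def dataset_manifest(dataset) -> list[Accessor]:
    """Expand every file of a dataset into a flat accessor table.

    Order is deterministic: file order, then data-type name. Duplicate
    accessors for the same (data type, entity triple) are all listed but
    flagged ambiguous.
    """
    rows: list[Accessor] = []
    for i, fs in enumerate(dataset.files):
        try:
            accs = expand_joint_file_type(fs, file_index=i)
        except RegistryError as exc:
            raise RegistryError(f"file[{i}]: {exc}") from exc
        rows.extend(sorted(accs, key=lambda a: a.data_type))
    seen: dict[tuple, int] = {}
    for a in rows:
        seen[a.key()] = seen.get(a.key(), 0) + 1
    return [
        replace(a, ambiguous=seen[a.key()] > 1) for a in rows
    ]


@dataclass(frozen=True)
class Requirement:
    """One data need of a view type: which data type, matched on which
    entity components, and whether the view can render without it."""

    data_type: str
    components: tuple[str, ...]
    optional: bool = False


@dataclass(frozen=True)
class ViewTypeDescriptor:
    name: str
    requirements: tuple[Requirement, ...]
    coordination_types: tuple[str, ...]


_ENTITY_CTYPES = ("dataset", "obsType", "featureType", "featureValueType")
_SELECTION_CTYPES = (
    "featureSelection",
    "featureHighlight",
    "obsHighlight",
    "obsSetSelection",
    "obsSetHighlight",
    "obsFilter",
)
_COLOR_CTYPES = (
    "obsColorEncoding",
    "featureValueColormap",
    "featureValueColormapRange",
    "obsSetColor",
)
_IMAGE_LAYER_CTYPES = (
    "imageLayerVisible",
    "imageLayerOpacity",
    "imageChannelSelection",
    "imageChannelColor",
    "imageChannelWindow",
)
_SEG_LAYER_CTYPES = (
    "segmentationLayerVisible",
    "segmentationLayerOpacity",
    "segmentationFilled",
)
_POINT_LAYER_CTYPES = ("pointLayerVisible", "pointLayerOpacity", "pointRadius")
_SPOT_LAYER_CTYPES = ("spotLayerVisible", "spotLayerOpacity", "spotRadius")
_PREF_CTYPES = ("tooltipsVisible", "legendVisible")

VIEW_TYPES: dict[str, ViewTypeDescriptor] = {
    v.name: v
    for v in [
        ViewTypeDescriptor(
            "scatterplot",
            (
                Requirement("obsEmbedding", ("obs_type",)),
                Requirement("obsFeatureMatrix", _ALL_AXES, optional=True),
                Requirement("obsSets", ("obs_type",), optional=True),
            ),
            _ENTITY_CTYPES
            + (
                "embeddingType",
                "embeddingZoom",
                "embeddingTargetX",
                "embeddingTargetY",
                "embeddingObsRadius",
                "embeddingObsOpacity",
            )
            + _SELECTION_CTYPES
            + _COLOR_CTYPES
            + _PREF_CTYPES,
        ),
        ViewTypeDescriptor(
            "spatial",
            (
                Requirement("obsLocations", ("obs_type",), optional=True),
                Requirement("obsSegmentations", ("obs_type",), optional=True),
                Requirement("image", (), optional=True),
                Requirement("obsFeatureMatrix", _ALL_AXES, optional=True),
                Requirement("obsSets", ("obs_type",), optional=True),
            ),
            _ENTITY_CTYPES
            + (
                "spatialZoom",
                "spatialTargetX",
                "spatialTargetY",
                "spatialTargetZ",
                "spatialRotationX",
                "spatialRotationY",
                "spatialRotationZ",
                "spatialAxisFixed",
            )
            + _SELECTION_CTYPES
            + _COLOR_CTYPES
            + _IMAGE_LAYER_CTYPES
            + _SEG_LAYER_CTYPES
            + _POINT_LAYER_CTYPES
            + _SPOT_LAYER_CTYPES
            + _PREF_CTYPES,
        ),
        ViewTypeDescriptor(
            "heatmap",
            (
                Requirement("obsFeatureMatrix", _ALL_AXES),
                Requirement("obsSets", ("obs_type",), optional=True),
            ),
            _ENTITY_CTYPES
            + (
                "heatmapZoomX",
                "heatmapZoomY",
                "heatmapTargetX",
                "heatmapTargetY",
                "heatmapAggregation",
            )
            + _SELECTION_CTYPES
            + _COLOR_CTYPES
            + _PREF_CTYPES,
        ),
        ViewTypeDescriptor(
            "featureList",
            (Requirement("obsFeatureMatrix", ("feature_type",)),),
            ("dataset", "featureType", "featureSelection", "featureHighlight"),
        ),
        ViewTypeDescriptor(
            "obsSets",
            (Requirement("obsSets", ("obs_type",)),),
            _ENTITY_CTYPES
            + ("obsSetSelection", "obsSetHighlight", "obsSetColor"),
        ),
        ViewTypeDescriptor(
            "obsSetSizes",
            (Requirement("obsSets", ("obs_type",)),),
            _ENTITY_CTYPES
            + ("obsSetSelection", "obsSetColor", "legendVisible"),
        ),
        ViewTypeDescriptor(
            "featureValueHistogram",
            (Requirement("obsFeatureMatrix", _ALL_AXES),),
            _ENTITY_CTYPES + ("featureSelection", "legendVisible"),
        ),
        ViewTypeDescriptor(
            "obsSetFeatureValueDistribution",
            (
                Requirement("obsFeatureMatrix", _ALL_AXES),
                Requirement("obsSets", ("obs_type",)),
            ),
            _ENTITY_CTYPES
            + (
                "featureSelection",
                "obsSetSelection",
                "obsSetColor",
                "legendVisible",
            ),
        ),
        ViewTypeDescriptor(
            "layerController",
            (
                Requirement("image", (), optional=True),
                Requirement("obsSegmentations", ("obs_type",), optional=True),
            ),
            _ENTITY_CTYPES
            + _IMAGE_LAYER_CTYPES
            + _SEG_LAYER_CTYPES
            + _POINT_LAYER_CTYPES
            + _SPOT_LAYER_CTYPES,
        ),
        ViewTypeDescriptor("description", (), ("dataset",)),
    ]
}


@dataclass
class MatchReport:
    """Result of matching one view's requirements against a manifest."""

    view_type: str
    entity: EntityTriple
    matched: dict[str, Accessor] = field(default_factory=dict)
    candidates: dict[str, list[Accessor]] = field(default_factory=dict)
    missing: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    def require(self, data_type: str) -> Accessor:
        try:
            return self.matched[data_type]
        except KeyError:
            raise DataMatchError(
                f"no matching data of type {data_type!r} for view "
                f"{self.view_type!r} with entity {self.entity.to_dict()}"
            ) from None


def _accessor_matches(acc: Accessor, req: Requirement, entity: EntityTriple) -> bool:
    if acc.data_type != req.data_type:
        return False
    for comp in req.components:
        if getattr(acc.entity, comp) != getattr(entity, comp):
            return False
    return True


def match_view_to_data(
    view_type: str,
    entity: EntityTriple,
    manifest: Sequence[Accessor],
) -> MatchReport:
    """Match a view's data requirements against a dataset manifest.

    An accessor matches a requirement iff it has the required data type
    and, for every entity component the requirement declares relevant,
    its component equals the view's resolved component; irrelevant
    components are ignored. When several accessors match, the first in
    manifest order wins and a warning is recorded. A required data type
    with zero matches produces a "no matching data" diagnostic naming
    the triple (an error only when the caller insists via ``require``).
    """
    try:
        vt = VIEW_TYPES[view_type]
    except KeyError:
        raise RegistryError(f"unknown view type {view_type!r}") from None
    entity = entity.with_defaults(DEFAULT_ENTITY)
    report = MatchReport(view_type=view_type, entity=entity)
    for req in vt.requirements:
        hits = [a for a in manifest if _accessor_matches(a, req, entity)]
        report.candidates[req.data_type] = hits
        if hits:
            report.matched[req.data_type] = hits[0]
            if len(hits) > 1:
                report.warnings.append(
                    f"{len(hits)} accessors match {req.data_type!r} for view "
                    f"{view_type!r}; using the first in manifest order"
                )
        elif not req.optional:
            report.missing.append(
                f"no matching data of type {req.data_type!r} for view "
                f"{view_type!r} with entity "
                + str({c: getattr(entity, c) for c in req.components})
            )
    return report
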