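"""Exception hierarchy.

Every error raised by this package derives from :class:`CellViewsError`,
so callers can catch one base class. Parse errors (malformed JSON) are
deliberately distinct from validation errors (well-formed JSON that
violates the schema), and I/O errors are distinct from content
validation errors.
"""


class CellViewsError(Exception):
    """Base class for all cellviews errors."""


class ConfigParseError(CellViewsError):
    """Input could not be parsed as JSON at all."""


class ConfigValidationError(CellViewsError):
    """A view config violates the schema; carries the validation report."""

    def __init__(self, report):
        self.report = report
        super().__init__(
            "invalid view config: "
            + "; ".join(f"{v.path}: {v.message}" for v in report.violations)
        )


class ConfigBuildError(CellViewsError):
    """Invalid builder call (e.g. adding a view for an unknown dataset)."""


class SerializationError(CellViewsError):
    """The config holds a value JSON cannot represent (NaN, infinity)."""


class RegistryError(CellViewsError):
    """Duplicate or unknown name in a registry (coordination/file/view types)."""


class CoordinationError(CellViewsError):
    """Bad coordination operation (unknown scope, value of wrong kind...)."""


class DanglingScopeError(CoordinationError):
    """A view references a coordination scope absent from the space."""


class DataMatchError(CellViewsError):
    """No data accessor matches a view's requirement; names the entity triple."""


class DataValidationError(CellViewsError):
    """Loaded content violates an invariant of its data type."""


class DataIOError(CellViewsError):
    """The file/store could not be read (distinct from content validation)."""


class RequestError(CellViewsError):
    """A subset request is out of range or names unknown identifiers."""


class StoreExportError(CellViewsError):
    """Refusal to write a chunked store (e.g. non-finite values)."""


class ShareURLError(CellViewsError):
    """Share URL carries no config payload or an undecodable one."""


class RenderError(CellViewsError):
    """A view could not be rendered (layer/data mismatch...)."""


class FixtureError(CellViewsError):
    """The synthetic fixture cannot be generated or is incomplete."""
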