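"""Exception hierarchy shared across the package."""


class DtocfError(Exception):
    """Base class for all package-specific errors."""


class ParseError(DtocfError):
    """A text input file could not be parsed; message names the line."""


class UnitError(DtocfError):
    """An IC50 record carries a concentration unit the reader cannot convert."""


class FormatError(DtocfError):
    """A structurally valid file violates a declared-format constraint."""


class DataError(DtocfError):
    """Inputs are inconsistent with each other (e.g. a missing self bit score)."""


class ShapeError(DtocfError):
    """Array dimensions disagree with the vocabularies they index."""


class DegenerateError(DtocfError):
    """A fit is requested on inputs that make the estimator undefined."""


class ConfigurationError(DtocfError):
    """A parameter combination is outside the supported domain."""


class GenerationError(DtocfError):
    """A synthetic-data specification produced an unusable dataset."""
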