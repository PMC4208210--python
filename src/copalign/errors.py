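"""Exception hierarchy.

``DataError`` covers malformed or inconsistent input files and maps to CLI
exit code 3; the others subclass it so callers can catch one base type.
"""


class DataError(Exception):
    """Malformed, inconsistent, or insufficient input data."""


class FormatError(DataError):
    """A file does not conform to the declared dialect."""


class DegenerateGeometryError(DataError):
    """Markers collinear/coincident, or a point cloud without spread."""


class InsufficientDataError(DataError):
    """Too few valid frames for the requested fit."""
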