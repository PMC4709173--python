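"""Error hierarchy shared by all pathclip modules.

CLI exit codes: 0 success, 2 invalid path geometry, 3 I/O error,
4 numeric/degeneracy failure.
"""


class PathclipError(Exception):
    """Base class for all pathclip errors."""

    exit_code = 1


class InvalidInputError(PathclipError):
    """Malformed in-memory input (non-finite coordinates, bad indices)."""

    exit_code = 2


class DegeneratePathError(PathclipError):
    """Clipping-path geometry violates an invariant (parallel neighbours,
    widget plane parallel to the transection plane, ...)."""

    exit_code = 2


class OrientationError(DegeneratePathError):
    """No consistent inside-side assignment exists for the path."""


class TransectionError(DegeneratePathError):
    """A widget plane cannot be transected by the plane beta."""


class StructuralError(PathclipError):
    """Malformed expression tree or serialization."""

    exit_code = 2


class MeshIOError(PathclipError):
    """Unreadable, unwritable or malformed mesh/path/fiducial file."""

    exit_code = 3


class NumericError(PathclipError):
    """Non-finite values or unresolved numerical degeneracy."""

    exit_code = 4


class GenerationError(PathclipError):
    """A synthetic fixture could not be generated (rejection limit hit)."""

    exit_code = 4
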