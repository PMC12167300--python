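"""Exception hierarchy shared across the package.

Exit-code mapping for the CLI: validation errors exit 2, computation
(geometry/numerical) errors exit 3, I/O errors exit 4.
"""


class PmaaError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class ValidationError(PmaaError):
    """Malformed input, invalid configuration or contract violation."""

    exit_code = 2


class ComputationError(PmaaError):
    """A well-formed input on which the computation is undefined."""

    exit_code = 3


class DegenerateGeometryError(ComputationError):
    """Parallel rays, degenerate projection, zero-length screw axes."""


class EmptySceneError(ComputationError):
    """The view metric is undefined for a scene with no objects."""


class InfeasibleSceneError(ComputationError):
    """Rejection sampling could not place objects under the constraints."""


class PmaaIOError(PmaaError):
    """File reading/writing failure."""

    exit_code = 4
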