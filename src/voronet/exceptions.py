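"""Exception hierarchy.

All voronet errors derive from :class:`VoronetError` so callers can catch
the package's failures with a single except clause while still
distinguishing degenerate *inputs* (bad tables, duplicate coordinates)
from undefined *results* (risk requested for an unclustered gene).
"""


class VoronetError(Exception):
    """Base class for all voronet errors."""


class InputError(VoronetError, ValueError):
    """Malformed or out-of-contract input (bad scores, missing columns...)."""


class DegenerateInputError(InputError):
    """Input that is well-formed but leaves a quantity undefined.

    Examples: a gene whose variant scores sum to zero (0/0 disease
    ratio), an all-collinear site set, a tessellation with no bounded
    cell, a constant-valued background sample.
    """


class FitError(VoronetError, RuntimeError):
    """The background-model optimisation failed at every start point."""


class GeneNotFoundError(VoronetError, KeyError):
    """The requested gene is not on the map / tessellation."""


class NoRiskDefinedError(VoronetError, ValueError):
    """The gene exists but carries no risk score (unclustered or unbounded).

    Kept distinct from :class:`GeneNotFoundError`: absence of network
    support is a result, not a lookup failure.
    """
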