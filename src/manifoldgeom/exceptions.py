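"""Exception hierarchy.

``InputError`` (a ``ValueError``) covers everything a caller can fix by
changing inputs; subclasses make the failure mode explicit so pipelines can
flag rather than crash where the contract allows it.
"""


class InputError(ValueError):
    """Invalid user input (bad shapes, missing columns, out-of-range values)."""


class ParseError(InputError):
    """A delimited input file could not be parsed into an ActivityDataset."""


class ConfigError(InputError):
    """A run configuration is incomplete or inconsistent."""


class DegenerateManifoldError(InputError):
    """A concept cloud has zero total variance; its geometry is undefined."""


class SignalDirectionError(InputError):
    """Two concept centroids coincide; the signal direction is undefined."""


class UndefinedBoundaryError(InputError):
    """Two prototypes coincide; the classification boundary is undefined."""


class UndefinedCorrelationError(InputError):
    """A correlation was requested on a constant (zero-variance) input."""


class FitError(RuntimeError):
    """A regression could not be fitted (e.g. rank-deficient design)."""
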