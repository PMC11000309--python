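"""Exception hierarchy.

Mapped to CLI exit codes: ConfigError -> 2, SchemaError/DataError -> 3,
ModelingError -> 4.
"""


class RespsegError(Exception):
    """Base class for all package errors."""


class ConfigError(RespsegError):
    """Invalid configuration (grids, run options, simulation settings)."""


class SchemaError(RespsegError):
    """Input table does not conform to the documented patient schema."""


class DataError(RespsegError):
    """Data are structurally valid but unusable (empty file, degenerate
    labels, impossible stratification, missing BOR where required)."""


class ModelingError(RespsegError):
    """A statistical fit could not be produced (single-class outcome,
    rank-deficient design, non-convergence)."""
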