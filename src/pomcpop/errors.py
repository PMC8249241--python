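"""Exception hierarchy shared by every pipeline stage.

The CLI maps these onto exit codes: validation problems (bad tables,
inconsistent configuration) exit 2, analysis failures (degenerate data
that cannot be processed) exit 3.
"""


class PomcpopError(Exception):
    """Base class for all package errors."""


class ConfigurationError(PomcpopError):
    """A simulation or pipeline configuration violates its invariants."""


class InputError(PomcpopError):
    """An input table, trace or window is malformed or out of range."""


class SchemaError(InputError):
    """A delimited table does not match its declared schema."""


class AnalysisError(PomcpopError):
    """The data are valid but the requested analysis is undefined on them."""
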