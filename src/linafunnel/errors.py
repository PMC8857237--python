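"""Exception hierarchy shared across the pipeline.

``InputError`` maps to CLI exit code 2 (bad or inconsistent inputs),
``StageError`` to exit code 3 (a pipeline stage failed mid-run).
"""


class LinafunnelError(Exception):
    """Base class for all package errors."""


class InputError(LinafunnelError, ValueError):
    """Invalid, malformed, or mutually inconsistent input data."""


class StageError(LinafunnelError, RuntimeError):
    """A pipeline stage failed after inputs were accepted."""
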