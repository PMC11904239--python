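"""Exception hierarchy for pfvmkit."""


class PfvmkitError(Exception):
    """Base class for all pfvmkit errors."""


class FormatError(PfvmkitError, ValueError):
    """A file could not be parsed in the expected format."""


class ValidationError(PfvmkitError, ValueError):
    """An input violates a documented precondition."""


class AssemblyError(PfvmkitError, RuntimeError):
    """Fragment assembly could not be completed."""


class PipelineError(PfvmkitError, RuntimeError):
    """An end-to-end run failed; carries per-stage diagnostics."""
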