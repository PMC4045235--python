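"""Exception hierarchy shared across the pipeline."""


class InteromixError(Exception):
    """Base class for all package-specific errors."""


class FormatError(InteromixError, ValueError):
    """A file did not conform to its expected tabular/text format."""


class ValidationError(InteromixError, ValueError):
    """An in-memory value violated a documented invariant."""


class ConfigError(InteromixError, ValueError):
    """An analysis or simulation configuration is inconsistent."""


class PipelineError(InteromixError, RuntimeError):
    """A pipeline stage failed; the message names the stage."""
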