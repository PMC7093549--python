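"""Exception hierarchy for the essentiality pipeline."""


class EssentialomicsError(Exception):
    """Base class for all package errors."""


class ConfigurationError(EssentialomicsError):
    """A simulation or pipeline configuration is invalid."""


class ValidationError(EssentialomicsError):
    """An input table violates a documented invariant."""


class PipelineError(EssentialomicsError):
    """A pipeline stage failed; the message names the stage."""
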