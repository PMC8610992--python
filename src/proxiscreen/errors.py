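"""Exception types shared across the pipeline."""


class ProxiscreenError(Exception):
    """Base class for all package errors."""


class ValidationError(ProxiscreenError, ValueError):
    """Input data violates a structural invariant (bad counts, ids, bounds)."""


class ConfigurationError(ProxiscreenError, ValueError):
    """A parameter set or run selection is inconsistent with the data."""


class PipelineStageError(ProxiscreenError, RuntimeError):
    """A pipeline stage failed; carries the stage name for diagnostics."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause
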