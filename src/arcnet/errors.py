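"""Exception hierarchy used across the package."""


class ArcnetError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(ArcnetError, ValueError):
    """A model or scenario parameter violates its constraints."""


class DegenerateInputError(ArcnetError, ValueError):
    """Input data are degenerate for the requested operation (e.g. constant
    intensities passed to a mixture fit, or an all-flat survival curve)."""


class UndefinedValueError(ArcnetError, ValueError):
    """The requested quantity is mathematically undefined for this input
    (e.g. the tiled spike proportion of an empty train)."""


class ConfigurationError(ArcnetError, ValueError):
    """Missing or inconsistent run configuration."""


class PipelineStageError(ArcnetError, RuntimeError):
    """A pipeline stage failed; carries the stage name for diagnostics."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")
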