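"""Exception types shared across the package."""


class CfsKitError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(CfsKitError, ValueError):
    """Invalid simulation or analysis parameters."""


class FormatError(CfsKitError, ValueError):
    """An input file does not conform to the expected dialect."""


class ConfigError(CfsKitError, ValueError):
    """Invalid or inconsistent run configuration."""


class GatingError(CfsKitError, RuntimeError):
    """Cell-cycle gating could not be performed automatically."""


class GenerationError(CfsKitError, RuntimeError):
    """A synthetic-data generator could not satisfy its constraints."""


class PipelineError(CfsKitError, RuntimeError):
    """A pipeline stage failed.

    Attributes
    ----------
    stage : str
        Name of the failing stage.
    code : str
        Machine-readable error code.
    """

    def __init__(self, stage: str, code: str, message: str):
        super().__init__(f"[{stage}:{code}] {message}")
        self.stage = stage
        self.code = code
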