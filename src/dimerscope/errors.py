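"""Exception types shared across the pipeline."""


class DimerscopeError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(DimerscopeError):
    """An input table is missing a mandatory column or has the wrong layout."""


class DataError(DimerscopeError):
    """Input values violate a precondition (e.g. negative LFQ intensities)."""


class ConfigurationError(DimerscopeError):
    """A parameter setting is incompatible with the data or design."""


class PipelineError(DimerscopeError):
    """A pipeline stage failed; carries the stage name and an error code."""

    def __init__(self, stage: str, code: str, message: str):
        self.stage = stage
        self.code = code
        super().__init__(f"[{stage}:{code}] {message}")
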