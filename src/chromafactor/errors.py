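"""Exception hierarchy shared across the package."""


class ChromaFactorError(Exception):
    """Base class for all package-specific errors."""


class FormatError(ChromaFactorError):
    """A plain-text input file violates the documented layout."""


class EmptyResultError(ChromaFactorError):
    """An operation removed every record (e.g. QC filtered all cells)."""


class ConfigError(ChromaFactorError):
    """A run configuration is internally inconsistent or references missing inputs."""


class PipelineError(ChromaFactorError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage '{stage}' failed: {message}")
        self.stage = stage
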