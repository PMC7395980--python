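"""Package-wide exception types."""


class MvsirError(Exception):
    """Base class for package errors."""


class ConfigurationError(MvsirError, ValueError):
    """Invalid parameters or geometry configuration."""


class StageError(MvsirError, RuntimeError):
    """A pipeline stage failed; carries the stage name for context."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage '{stage}': {message}")
        self.stage = stage
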