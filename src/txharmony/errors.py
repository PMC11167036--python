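"""Exception types shared across the pipeline."""


class TxHarmonyError(Exception):
    """Base class for all package errors."""


class ConfigurationError(TxHarmonyError):
    """An input configuration violates its invariants."""


class DataError(TxHarmonyError):
    """Input data violate a precondition of an operation."""


class StageError(TxHarmonyError):
    """A pipeline stage failed; carries the stage name for context."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}': {message}")
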