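"""Exception types shared across the pipeline."""


class RadForgeError(Exception):
    """Base class for pipeline errors."""


class ConfigurationError(RadForgeError):
    """Invalid or inconsistent configuration (duplicate barcodes, unknown keys...)."""


class PlacementError(RadForgeError):
    """The synthetic genome is too short/crowded to place a requested feature."""


class InputError(RadForgeError):
    """Malformed or inconsistent input data."""


class PipelineStageError(RadForgeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")
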