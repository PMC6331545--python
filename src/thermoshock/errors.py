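"""Exception hierarchy shared across the pipeline."""


class ThermoshockError(Exception):
    """Base class for all package-specific errors."""


class UnsupportedImageError(ThermoshockError):
    """Image file cannot be read as an 8-bit grayscale/RGB raster."""


class EmptySilhouetteError(ThermoshockError):
    """No nonzero pixels: the body silhouette cannot be located."""


class UndefinedCPDError(ThermoshockError):
    """CPD percentage is undefined (non-positive abdomen median)."""


class MissingVitalsError(ThermoshockError):
    """No usable vitals samples inside the requested time window."""


class StageError(ThermoshockError):
    """A pipeline stage failed; carries the stage name for diagnostics."""

    def __init__(self, stage: str, message: str = ""):
        self.stage = stage
        super().__init__(f"[{stage}] {message}" if message else f"[{stage}]")
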