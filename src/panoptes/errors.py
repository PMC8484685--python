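"""Exception hierarchy shared across the pipeline stages."""


class PanoptesError(Exception):
    """Base class for all package errors."""


class SlideFormatError(PanoptesError):
    """File is not a readable pyramidal slide."""


class RegionBoundsError(PanoptesError):
    """A requested region falls outside the slide's level-0 bounds."""


class UnstainableTileError(PanoptesError):
    """Too few tissue pixels to estimate a stain basis for this tile."""


class SplitInfeasibleError(PanoptesError):
    """No patient split can satisfy the stratification constraints."""


class UndefinedMetricError(PanoptesError):
    """A metric is undefined for the given table (e.g. one class absent)."""


class WiringError(PanoptesError):
    """Model inputs inconsistent with the architecture configuration."""


class ManifestError(PanoptesError):
    """Record store manifest missing, corrupt, or checksum mismatch."""


class PipelineStageError(PanoptesError):
    """A pipeline stage failed; carries the stage name and config digest."""

    def __init__(self, stage: str, fingerprint: str, message: str):
        self.stage = stage
        self.fingerprint = fingerprint
        super().__init__(f"stage '{stage}' (config {fingerprint[:12]}): {message}")
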