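"""Exception hierarchy.

Every failure mode the pipeline can hit on structurally bad input gets its
own class so callers (and the CLI) can tell configuration mistakes apart
from genuinely degenerate data.
"""


class FtlQuantError(Exception):
    """Base class for all ftlquant errors."""


class PlacementError(FtlQuantError):
    """Cells could not be placed inside the ROI within the attempt budget."""


class DesignError(FtlQuantError):
    """Study design is unbalanced or structurally invalid."""


class AlignmentError(FtlQuantError):
    """Rasters that must share dimensions do not."""


class InvalidPolygonError(FtlQuantError):
    """ROI polygon has < 3 vertices, self-intersects, or leaves the image."""


class EmptyRoiError(FtlQuantError):
    """A rasterized ROI contains no interior pixels."""


class MissingRoiError(FtlQuantError):
    """A section has no matching ROI polygon."""


class InsufficientSampleError(FtlQuantError):
    """Fewer than two pixels available for threshold estimation."""


class NoInteractionTestError(FtlQuantError):
    """Fewer than two replicates per cell: the interaction is untestable."""


class DegenerateResidualError(FtlQuantError):
    """Residual mean square is zero; post-hoc comparisons are undefined."""


class ConfigError(FtlQuantError):
    """Run configuration is invalid."""


class PipelineStageError(FtlQuantError):
    """A pipeline stage failed for a specific section.

    Carries the section id and stage name so multi-section runs can be
    audited; the original exception is chained as ``__cause__``.
    """

    def __init__(self, section_id: str, stage: str, message: str):
        self.section_id = section_id
        self.stage = stage
        super().__init__(f"[section={section_id} stage={stage}] {message}")
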