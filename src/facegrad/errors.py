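"""Exception hierarchy for facegrad.

All errors derive from :class:`FacegradError` so callers can catch the
package's failures with a single except clause while still distinguishing
the analysis-specific conditions (rank-deficient designs, unlocalizable
ROIs, degenerate zero-variance inputs) that the pipeline treats differently.
"""


class FacegradError(Exception):
    """Base class for all facegrad errors."""


class RankDeficientError(FacegradError):
    """Design matrix does not have full column rank; OLS is not identified."""


class ROINotFoundError(FacegradError):
    """No suprathreshold voxel inside the anatomical search zone."""


class EmptyROIError(FacegradError):
    """A filtering step removed every voxel of an ROI."""


class ZeroVarianceError(FacegradError):
    """An input that must vary across voxels/subjects is constant."""


class InsufficientDataError(FacegradError):
    """Fewer runs/subjects/voxels than the statistic requires."""


class IncompleteDataError(FacegradError):
    """A subject x condition table has missing cells."""


class AlignmentError(FacegradError):
    """Two patterns do not share the same voxel set."""
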