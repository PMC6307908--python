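"""Named error types raised by the analysis pipeline.

Every precondition violation in the public API maps to one of these, so that
callers (and the CLI) can distinguish bad inputs from genuine bugs.
"""


class XenovascError(Exception):
    """Base class for all package-specific errors."""


class ChannelCountMismatchError(XenovascError):
    """A declared channel index is outside the channels present in the data."""


class UnknownRoleError(XenovascError):
    """A channel role (graft/vessel/macrophage) is not declared on the stack."""


class NonPositiveVoxelSizeError(XenovascError):
    """A voxel-size component is zero or negative."""


class ZeroAxisError(XenovascError):
    """The CCV axis vector has (near-)zero length and cannot be normalised."""


class TrajectoryGapError(XenovascError):
    """The tip trajectory is missing a frame inside the analysis window."""


class EmptyGraftError(XenovascError):
    """No graft voxels/objects — graft-normalised quantities are undefined."""


class EmptyObjectSetError(XenovascError):
    """An operation requiring at least one detected object received none."""


class TipOutOfBoundsError(XenovascError):
    """The annotated vessel-tip position lies outside the imaged volume."""


class NoAdmissibleControlError(XenovascError):
    """No control-region placement fits inside the graft.

    Raised when no candidate disc at the configured offset lies fully within
    the graft footprint; use a larger graft or a smaller offset/radius.
    """


class SampleSizeError(XenovascError):
    """A statistical routine received fewer observations than it requires."""


class ZeroWindowError(XenovascError):
    """A speed-comparison window has zero duration."""


class NoTipCellTracksError(XenovascError):
    """Revisit fraction is undefined without any tip-cell macrophage tracks."""


class UnreachableFractionError(XenovascError):
    """The requested vascular fraction cannot be realised within the graft."""


class AnnotationError(XenovascError):
    """An annotation file is malformed or missing required fields."""
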