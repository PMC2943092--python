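"""Exception taxonomy for the registration pipeline.

Stage failures carry a machine-readable ``stage`` tag so that batch runs can
attribute a failed registration to the stage that caused it.
"""


class FundusRegError(Exception):
    """Base class for all package errors."""

    stage = "error"


class ParameterError(FundusRegError, ValueError):
    """Invalid parameter value (non-positive sigma, theta out of range, ...)."""

    stage = "parameter_error"


class SegmentationFailure(FundusRegError):
    """Vessel detection produced no usable skeleton or graph."""

    stage = "segmentation_failure"


class EmptyGraphError(FundusRegError):
    """A graph operation would leave (or received) a graph without edges."""

    stage = "segmentation_failure"


class DegenerateSampleError(FundusRegError):
    """Transform estimation received degenerate (e.g. coincident) points."""

    stage = "degenerate_sample"


class NoStableStructuresError(FundusRegError):
    """STRUCT-SAC found no local structure sample passing the consistency test.

    Raised as "insufficient stable structures"; the typical cause is that the
    two graphs share fewer than three stable (degree-2/3, correctly matched)
    nodes, e.g. at very low overlap or under heavy structure noise.
    """

    stage = "no_stable_structures"


class IcpDivergenceError(FundusRegError):
    """ICP could not find enough gated point pairs at the finest level."""

    stage = "icp_divergence"


class UndefinedCemError(FundusRegError):
    """No centerline correspondences inside the gate; CEM is undefined."""

    stage = "undefined_cem"


class UndefinedMetricError(FundusRegError):
    """An intensity metric is undefined (empty overlap / zero variance)."""

    stage = "undefined_metric"
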