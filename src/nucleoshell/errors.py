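"""Exception hierarchy.

Every failure mode that a pipeline stage can hit deliberately (as opposed to
a programming error) raises a subclass of :class:`NucleoshellError`, so the
orchestrator can attribute aborts to a stage and an offending object.
"""


class NucleoshellError(Exception):
    """Base class for all package-specific errors."""


class PlacementError(NucleoshellError):
    """Rejection sampling could not place condensates inside a nucleus."""


class NoRegionsError(NucleoshellError):
    """Segmentation produced no regions (degenerate or empty input)."""


class MissingLabelError(NucleoshellError, KeyError):
    """A requested region label does not exist in the mask."""


class ProfilingError(NucleoshellError):
    """Radial profiling cannot proceed (e.g. centroid outside the region)."""


class NucleolusExcluded(NucleoshellError):
    """A nucleolus was excluded from profiling, with a machine-readable reason."""

    def __init__(self, label: int, reason: str):
        self.label = label
        self.reason = reason
        super().__init__(f"nucleolus {label} excluded: {reason}")


class EmptyWindowError(NucleoshellError):
    """A d-window contains no valid samples for a nucleolus."""


class ZeroVarianceError(NucleoshellError):
    """A t statistic is undefined because the sample variance is zero."""


class ConfigError(NucleoshellError):
    """Invalid or inconsistent run configuration."""
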