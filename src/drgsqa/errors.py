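"""Exception hierarchy for the DRGS QA toolkit.

All toolkit errors derive from :class:`DrgsQaError` so callers can catch one
base class at CLI boundaries.
"""


class DrgsQaError(Exception):
    """Base class for all toolkit errors."""


class RTPlanFormatError(DrgsQaError):
    """An RT Plan file is missing an element the toolkit requires."""


class PlanValidationError(DrgsQaError):
    """A plan violates a modeled invariant (e.g. non-monotone weights)."""


class ArcError(DrgsQaError):
    """A beam cannot support arc kinematics (too few CPs, no rotation)."""


class EmptyCohortError(DrgsQaError):
    """No arc segments available to summarize."""


class LayoutError(DrgsQaError):
    """A strip/ROI layout is degenerate or inconsistent with the image."""


class ImageError(DrgsQaError):
    """EPID image pair is unusable (dimension mismatch, fully masked...)."""


class BaselineError(DrgsQaError):
    """Baseline record inconsistent with the measurement."""


class FixtureConfigError(DrgsQaError):
    """Synthetic-fixture configuration violates its invariants."""
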