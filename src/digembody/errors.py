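"""Exception hierarchy.

All package-specific failures derive from :class:`DigembodyError` so callers
(and the command-line layer) can distinguish data problems from usage errors.
"""


class DigembodyError(Exception):
    """Base class for all digembody errors."""


class EmptyStructureError(DigembodyError):
    """A coordinate file parsed successfully but contained no atoms."""


class NotANanobodyError(DigembodyError):
    """A sequence aligned too poorly to the VHH framework reference."""


class DesignError(DigembodyError):
    """A substitution set referenced an IMGT position missing from the query."""


class CorrespondenceError(DigembodyError):
    """Too few shared framework positions to define a superposition."""


class DegenerateGeometryError(DigembodyError):
    """Point sets too degenerate (collinear/coincident) for a rigid fit."""


class GeometryError(DigembodyError):
    """A geometric quantity is undefined for the given atoms."""


class AssemblyError(DigembodyError):
    """A synthetic scene could not be built with the requested parameters."""


class SurveyError(DigembodyError):
    """No entry of a screening library could be processed."""
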