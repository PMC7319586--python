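"""Exception hierarchy shared across the package."""


class IrbindError(Exception):
    """Base class for all package-specific errors."""


class InvalidModelError(IrbindError, ValueError):
    """A promoter binding model violates its invariants (e.g. kd <= 0)."""


class DomainError(IrbindError, ValueError):
    """An argument is outside its physical domain (e.g. negative concentration)."""


class NonIdentifiableError(IrbindError, ValueError):
    """A fit cannot be performed: the data carry no information on the parameters."""


class EmptyLaneError(IrbindError, ValueError):
    """A gel lane has zero total intensity and no fraction can be formed."""


class InsufficientDataError(IrbindError, ValueError):
    """Fewer usable data points than the operation requires."""


class SingularFitError(IrbindError, ValueError):
    """All selected points share one abscissa; the regression is singular."""


class PathologicalFitError(IrbindError, ValueError):
    """The Hill slope came out non-positive; reported rather than silently returned."""


class InputError(IrbindError, ValueError):
    """Malformed or inconsistent user input (labels, lengths, missing columns)."""


class ParseError(IrbindError, ValueError):
    """A file could not be parsed; carries file/line context where available."""


class RangeError(IrbindError, ValueError):
    """Coordinates fall outside the sequence they refer to."""


class DesignError(IrbindError, ValueError):
    """A synthetic-data design is infeasible (e.g. overlapping planted repeats)."""
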