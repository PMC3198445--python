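"""Exception hierarchy for the mirkin pipeline."""


class MirkinError(Exception):
    """Base class for all mirkin errors."""


class MissingDataError(MirkinError):
    """A requested (molecule, condition, day) has no recorded replicates."""


class InvalidControlError(MirkinError):
    """A loading-control (actin) intensity is zero or negative."""


class InsufficientDataError(MirkinError):
    """Fewer knots than the interpolant requires."""


class ExtrapolationError(MirkinError):
    """Recorded days do not span the interpolation grid."""


class TableParseError(MirkinError):
    """A delimited-text input is malformed; carries the offending line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class ConfigurationError(MirkinError):
    """A gene or molecule is missing from the supplied configuration."""


class DependencyError(MirkinError):
    """An architecture references a molecule with no available profile."""


class InversionError(MirkinError):
    """A Hill factor cannot be inverted because the regulator level is zero."""


class DegenerateProfileError(MirkinError):
    """A downstream profile is identically zero; no relative error is defined."""


class AlignmentError(MirkinError):
    """Two profiles do not share the same time grid."""


class BudgetError(MirkinError):
    """The exhaustive candidate set exceeds the configured search budget."""


class ClampError(MirkinError):
    """The integrator produced a negative state beyond numerical tolerance."""


class SimSpecError(MirkinError):
    """A synthetic-campaign specification is inconsistent."""
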