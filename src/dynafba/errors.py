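"""Named exceptions for the dynafba package.

Every contract violation in the public API raises one of these rather than a
bare ValueError, so callers (and the CLI) can distinguish failure modes.
"""


class DynafbaError(Exception):
    """Base class for all package errors."""


class ModelParseError(DynafbaError):
    """A model file could not be parsed."""


class DuplicateIdError(ModelParseError):
    """A metabolite or reaction id appears more than once."""


class UnknownMetaboliteError(ModelParseError):
    """A reaction references a metabolite that is not declared."""


class ModelValidationError(DynafbaError):
    """A structural invariant of the model is violated."""


class InvalidBoundsError(DynafbaError):
    """A constraint patch would produce lb > ub, or contradicts existing bounds."""


class UnknownTargetError(DynafbaError):
    """A genetic-modification target matches no gene or reaction id."""


class BiomassDeletionError(DynafbaError):
    """A genetic modification would delete the biomass reaction."""


class NegativeConcentrationError(DynafbaError):
    """A fermentation state carries a negative concentration."""


class ZeroNitrogenContentError(DynafbaError):
    """A nitrogen compound declares zero mg N per mmol."""


class InvalidFractionError(DynafbaError):
    """A fraction argument lies outside [0, 1], or a composition is inconsistent."""


class SolverError(DynafbaError):
    """The LP backend failed for a reason other than infeasibility."""


class DimensionMismatchError(SolverError):
    """LP matrix dimensions are inconsistent with the model."""


class UnorderedProfileError(DynafbaError):
    """A temperature profile has non-increasing time points."""


class UndefinedScoreError(DynafbaError):
    """An R score is undefined (zero wild-type concentration)."""


class DegenerateSeriesError(DynafbaError):
    """A correlation is undefined because one series has zero variance."""


class InsufficientPointsError(DynafbaError):
    """Fewer than the minimum number of matched time points."""


class DisconnectedNetworkError(DynafbaError):
    """A toy-network spec produces a network that cannot grow."""


class EmptyTrajectoryError(DynafbaError):
    """An operation on a trajectory requires at least one state."""


class ConfigError(DynafbaError):
    """A simulation configuration key is missing or invalid."""
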