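"""Exception hierarchy shared across the package."""


class CommDriversError(Exception):
    """Base class for all package-specific errors."""


class InvalidSpecError(CommDriversError, ValueError):
    """A generator or block specification is malformed."""


class TooFewSitesError(CommDriversError, ValueError):
    """Fewer sites than the operation can work with."""


class InvalidParameterError(CommDriversError, ValueError):
    """A numeric parameter is outside its admissible range."""


class UnknownHostError(CommDriversError, KeyError):
    """A specialist references a host plant absent from the plant list."""


class DomainError(CommDriversError, ValueError):
    """Input values outside the mathematical domain of a transform."""


class CollinearityError(CommDriversError, ValueError):
    """A predictor column is constant or exactly collinear with another."""


class DegenerateResponseError(CommDriversError, ValueError):
    """The response matrix has no variance to model."""


class DegreesOfFreedomError(CommDriversError, ValueError):
    """Not enough residual degrees of freedom for the requested fit."""


class ZeroInformationError(CommDriversError, ValueError):
    """Predictors carry no information beyond the conditioning set."""


class EmptyCandidateError(CommDriversError, ValueError):
    """Forward selection called with no candidate variables."""


class RankError(CommDriversError, ValueError):
    """Requested dimensionality exceeds the rank of the predictors."""


class FoldError(CommDriversError, ValueError):
    """Cross-validation folds cannot be formed from the available sites."""


class OverfitError(CommDriversError, ValueError):
    """More predictor columns than the sample size can support."""


class TooFewSpeciesError(CommDriversError, ValueError):
    """A co-occurrence statistic needs at least two species."""


class ProvenanceError(CommDriversError, ValueError):
    """A null ensemble does not match the matrix it is applied to."""


class BinningError(CommDriversError, ValueError):
    """Invalid histogram binning request."""


class ParseError(CommDriversError, ValueError):
    """A data file violates the expected table dialect."""


class MappingError(CommDriversError, ValueError):
    """The block map and the predictor tables disagree."""


class AlignmentError(CommDriversError, ValueError):
    """Tables that must share a site set do not."""


class StepFailureError(CommDriversError, RuntimeError):
    """A pipeline step failed; partial outputs were persisted."""
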