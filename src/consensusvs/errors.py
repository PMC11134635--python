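"""Exception hierarchy shared across the pipeline."""


class ConsensusVSError(Exception):
    """Base class for all package errors."""


class FormatError(ConsensusVSError):
    """A tabular or log input does not match its documented schema."""


class EmptyInputError(ConsensusVSError):
    """An input that must contain at least one usable row is empty."""


class DuplicateIdError(ConsensusVSError):
    """The same compound id appears more than once where uniqueness is required."""


class DomainError(ConsensusVSError, ValueError):
    """A numeric argument is outside its mathematical domain."""


class ConfigError(ConsensusVSError):
    """An unknown option value or inconsistent configuration."""


class ValidityError(ConsensusVSError):
    """A model fit falls outside the applicability range of the W_new metric
    (an R-squared outside [0, 1])."""


class DegenerateFitError(ConsensusVSError):
    """All three error metrics are zero, so the W_new ratio is undefined."""


class NoValidModelError(ConsensusVSError):
    """Every candidate grid cell was excluded by the R-squared validity gate."""


class DegenerateChannelError(ConsensusVSError):
    """A score channel has zero variance and cannot be z-scored."""


class MissingScoreError(ConsensusVSError):
    """A compound is absent from a channel required for consensus ranking."""
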