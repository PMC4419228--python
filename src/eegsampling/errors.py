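"""Exception hierarchy for corpus parsing, sampling design, and evaluation."""


class EEGSamplingError(Exception):
    """Base class for all package-specific errors."""


class FormatError(EEGSamplingError, ValueError):
    """A channel file contains a line that does not parse as a number."""


class EmptyInputError(EEGSamplingError, ValueError):
    """An operation received an empty file, directory, or sequence."""


class RaggedDataError(EEGSamplingError, ValueError):
    """Channel files within a class directory have unequal lengths."""


class SchemaError(EEGSamplingError, ValueError):
    """A feature-matrix file is missing columns or carries extras."""


class InvalidPartitionError(EEGSamplingError, ValueError):
    """Requested segmentation is impossible (k < 1 or k > signal length)."""


class DomainError(EEGSamplingError, ValueError):
    """A numeric argument is outside its mathematical domain."""


class DegenerateAllocationError(EEGSamplingError, ValueError):
    """All optimum-allocation weights are zero."""


class InfeasibleAllocationError(EEGSamplingError, ValueError):
    """Requested total sample size exceeds the population."""


class OversampleError(EEGSamplingError, ValueError):
    """A without-replacement draw larger than its segment was requested."""


class ParameterError(EEGSamplingError, ValueError):
    """A classifier hyperparameter is incompatible with the data."""


class DegeneratePairError(EEGSamplingError, ValueError):
    """A pairwise binary problem is missing one of its two classes."""


class StratificationError(EEGSamplingError, ValueError):
    """A class has fewer members than the requested number of folds."""


class LabelCollisionError(EEGSamplingError, ValueError):
    """Two feature rows carry the same (class, channel) label."""


class ConvergenceWarning(UserWarning):
    """Optimizer stopped before reaching the gradient tolerance."""
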