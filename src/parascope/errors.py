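"""Exception hierarchy shared across the package."""


class ParascopeError(Exception):
    """Base class for all package-specific errors."""


class StructureParseError(ParascopeError):
    """A structure file could not be read under the requested dialect."""


class EmptyStructureError(ParascopeError):
    """A parsed structure contains no polymer atoms."""


class AssignmentError(ParascopeError):
    """A chain named in a ChainAssignment is absent or inconsistent."""


class EmptyTrackError(ParascopeError):
    """A chain selected for labeling contains zero residues."""


class AlphabetError(ParascopeError):
    """A sequence contains symbols outside the 20 amino acids plus X."""


class ContractViolationError(ParascopeError):
    """An embedding backend broke its declared contract."""


class AlignmentError(ParascopeError):
    """Two per-residue tracks that must align have different lengths."""


class SchemaError(ParascopeError):
    """A metadata table is missing required columns."""


class UndefinedMetricError(ParascopeError):
    """A metric is undefined for the given input (e.g. single-class labels)."""


class UndefinedInputError(ParascopeError):
    """An operation received input on which it is mathematically undefined."""


class NormalizationError(ParascopeError):
    """A set of weights or scores sums to zero and cannot be normalized."""


class ConfigurationError(ParascopeError):
    """A model or training configuration is invalid for the given data."""


class CoverageError(ParascopeError):
    """A region track does not cover exactly the masked positions."""


class EvaluationError(ParascopeError):
    """No scorable complexes were available for evaluation."""


class SpecError(ParascopeError):
    """A synthetic-fixture specification is infeasible."""
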