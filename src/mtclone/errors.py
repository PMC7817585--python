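"""Exception hierarchy for mtclone."""


class MtcloneError(Exception):
    """Base class for all package-specific errors."""


class CoordinateError(MtcloneError):
    """A position falls outside the 1..16569 reference coordinate range."""


class InvalidLocusError(MtcloneError):
    """An operation requiring a protein-coding locus got another type."""


class ReferenceMismatchError(MtcloneError):
    """A variant's REF base disagrees with the reference sequence."""


class FormatError(MtcloneError):
    """A malformed external artifact (FASTA header, variant string, table row)."""


class DuplicateRecordError(FormatError):
    """Two samples with the same patient/tissue in one cohort."""


class InsufficientSequenceError(MtcloneError):
    """A sample sequence too short (or long) to align meaningfully."""


class OracleInapplicableError(MtcloneError):
    """The positional diff oracle requires equal-length, indel-free input."""


class MissingNormalError(MtcloneError):
    """A patient lacks the matched-normal sample required for somatic filtering."""


class EmptyCohortError(MtcloneError):
    """An aggregate operation received zero cases."""


class InconsistencyError(MtcloneError):
    """Patient sets disagree between inputs that must cover the same cohort."""


class UndefinedStatisticError(MtcloneError):
    """A statistic's denominator is empty (e.g. no metachronous cases)."""


class ConfigError(MtcloneError):
    """Invalid simulation or pipeline configuration."""
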