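"""Exception hierarchy for driftmeta."""


class DriftmetaError(Exception):
    """Base class for all driftmeta errors."""


class ConfigurationError(DriftmetaError, ValueError):
    """Invalid simulation or analysis configuration."""


class DataIntegrityError(DriftmetaError, ValueError):
    """Input data contradicts itself (e.g. VCF REF disagrees with the FASTA)."""


class AnnotationError(DriftmetaError, ValueError):
    """CDS annotation violates a structural requirement (frame, ordering)."""


class UndefinedStatisticError(DriftmetaError, ArithmeticError):
    """A statistic is undefined for these inputs (zero denominator etc.).

    Raised rather than silently returning NaN; table-building callers catch
    this and record an explicit flag.
    """
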