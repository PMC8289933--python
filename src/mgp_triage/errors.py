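"""Exception hierarchy for the triage package."""


class TriageError(Exception):
    """Base class for all package-specific errors."""


class ParseError(TriageError):
    """A file could not be parsed; message names the offending line/field."""


class CohortValidationError(TriageError):
    """A record violated a domain invariant; message names patient and field."""


class VariantLookupError(TriageError, KeyError):
    """A variant key did not resolve within the patient record."""


class SampleLookupError(TriageError, KeyError):
    """A requested sample is not present in a VCF."""


class VcfFormatError(TriageError):
    """A VCF record lacks the depth/allele-fraction fields needed for AF extraction."""


class ConsistencyError(TriageError):
    """Two linked result sets (ids, counts) disagree."""
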