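"""Exception hierarchy shared across the toolkit."""


class DomestiscanError(Exception):
    """Base class for all toolkit errors."""


class AlignmentError(DomestiscanError):
    """Sequences that should be aligned are not (length mismatch etc.)."""


class MetadataError(DomestiscanError):
    """Panel metadata inconsistent with the sequence records."""


class ConsistencyError(DomestiscanError):
    """Two objects that must describe the same panel do not."""


class ConfigError(DomestiscanError):
    """Invalid simulation or analysis configuration."""


class InconsistencyError(DomestiscanError):
    """Fine-mapping constraint intersection is empty.

    Usually indicates a phenotyping/genotyping error, or that the trait is
    not controlled by a single dominant locus (e.g. two complementary
    dominant genes).
    """
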