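"""Exception hierarchy for the metacortex pipeline."""


class MetacortexError(Exception):
    """Base class for all pipeline errors."""


class FormatError(MetacortexError):
    """A file does not conform to the documented table schema."""


class ValidationError(MetacortexError):
    """Parsed content violates a domain invariant."""


class LinkageError(MetacortexError):
    """A peak table references samples absent from the metadata."""


class MergeError(MetacortexError):
    """Ionization-mode tables cannot be merged (asymmetric sample sets)."""


class NormalizationError(MetacortexError):
    """Normalization is undefined for a sample (e.g. all-zero intensities)."""


class ArgumentError(MetacortexError, ValueError):
    """An operation received an out-of-contract argument."""


class ConfigError(MetacortexError):
    """A configuration object is internally inconsistent or incomplete."""


class AnalysisError(MetacortexError):
    """A statistical procedure cannot be run on the given inputs."""
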