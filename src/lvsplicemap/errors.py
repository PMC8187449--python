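"""Exception hierarchy for lvsplicemap."""


class LvSpliceMapError(Exception):
    """Base class for all package-specific errors."""


class AnnotationError(LvSpliceMapError):
    """Malformed annotation input (BED/FASTA parse problems)."""


class ConfigurationError(LvSpliceMapError):
    """A required feature/parameter is missing or out of range."""


class ConsistencyError(LvSpliceMapError):
    """Two inputs that must agree (e.g. parent/derived genomes) do not."""


class InputError(LvSpliceMapError):
    """Alignment input does not match the supplied genome."""


class EmptyInputError(LvSpliceMapError):
    """No usable records (e.g. zero near-full-length reads)."""
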