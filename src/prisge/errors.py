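"""Exception hierarchy for prisge."""


class PrisgeError(Exception):
    """Base class for all prisge errors."""


class FormatError(PrisgeError):
    """A file did not conform to the expected tabular schema."""


class ValidationError(PrisgeError):
    """Input data violated a structural invariant."""


class ConfigError(PrisgeError):
    """A configuration object is internally inconsistent."""


class LayoutError(PrisgeError):
    """Read layout incompatible with construct sequences or read lengths."""


class PairingError(PrisgeError):
    """Paired inputs (FASTQ mates, treatment/vehicle samples) do not match up."""


class InsufficientDataError(PrisgeError):
    """Too few observations to compute the requested statistic."""
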