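"""Exception hierarchy for crispamp."""


class CrispampError(Exception):
    """Base class for all crispamp errors."""


class GuideNotFoundError(CrispampError):
    """No protospacer+PAM placement within the mismatch budget."""


class AmbiguousGuideError(CrispampError):
    """Two or more equally good guide placements."""


class CutSiteOutsideAmpliconError(CrispampError):
    """A computed cut/nick bond falls outside the amplicon."""


class TargetFileError(CrispampError):
    """Malformed BED/manifest input."""


class UnpairedGuideError(TargetFileError):
    """A guide interval is not contained in any amplicon interval."""


class DonorMismatchError(CrispampError):
    """Donor homology arms do not align to any candidate amplicon."""


class ConfigError(CrispampError):
    """Invalid run configuration."""


class OracleBoundError(CrispampError):
    """Sequences too long for exhaustive alignment enumeration."""


class SequenceTooLongError(CrispampError):
    """Alignment problem exceeds the configured size guard."""
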