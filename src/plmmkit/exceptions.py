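"""Exception hierarchy shared across the package.

Exit-code mapping used by the CLI: usage errors → 2 (click), data/format
integrity problems → 3, numerical failures → 4.
"""


class PlmmError(Exception):
    """Base class for all plmmkit errors."""


class FormatError(PlmmError):
    """A file does not conform to its declared on-disk format."""


class UnsupportedLayoutError(FormatError):
    """A recognized but unsupported variant of a format (e.g. individual-major .bed)."""


class IntegrityError(PlmmError):
    """Internally inconsistent data: mismatched counts, duplicate IDs, bad codings."""


class AlignmentError(PlmmError):
    """Sample or feature identifiers cannot be aligned between inputs."""


class ConfigurationError(PlmmError):
    """An invalid parameter combination was requested."""


class DegenerateDataError(PlmmError):
    """Input data admit no meaningful fit (e.g. constant outcome)."""


class SingularityError(PlmmError):
    """A required matrix is numerically singular."""
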