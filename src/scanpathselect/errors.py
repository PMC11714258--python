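"""Exception taxonomy shared across the package.

Validation problems (bad files, bad parameters) are kept distinct from
runtime failures so the command-line layer can map them to exit codes.
"""


class ScanpathError(Exception):
    """Base class for all package-specific errors."""


class FormatError(ScanpathError, ValueError):
    """A file does not conform to the expected on-disk dialect."""


class ValidationError(ScanpathError, ValueError):
    """An in-memory object violates a documented invariant."""


class DomainError(ScanpathError, ValueError):
    """An operation was called outside its mathematical domain."""
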