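"""Exception hierarchy.

Errors are split so the CLI can map configuration problems to exit code 2
and data problems to exit code 3.
"""


class SeedNIRError(Exception):
    """Base class for all package errors."""


class ConfigurationError(SeedNIRError):
    """Invalid parameter or configuration document."""


class FormatError(SeedNIRError):
    """Malformed spectra table or archive file."""


class LabelError(SeedNIRError):
    """Class labels missing, unknown where a 0/1 code is required, or single-class."""


class DegenerateSpectrumError(SeedNIRError):
    """A per-spectrum transform hit a zero divisor (constant or zero row)."""


class AlignmentError(SeedNIRError):
    """Wavenumber axis of new data does not match the trained axis."""


class ConvergenceError(SeedNIRError):
    """NIPALS failed to converge or ran out of rank."""


class SplitError(SeedNIRError):
    """Requested partition is impossible for the given class sizes."""


class DataError(SeedNIRError):
    """Dataset unusable for the requested operation (empty, unlabelled, ...)."""
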