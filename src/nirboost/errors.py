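"""Exception hierarchy shared across the package."""


class NirboostError(Exception):
    """Base class for all package-specific errors."""


class SpectraFormatError(NirboostError):
    """A spectra file is structurally malformed (header, cells, ordering)."""


class SpectraValidationError(NirboostError):
    """A dataset violates a container invariant (shapes, NaNs, duplicates)."""


class ModelIOError(NirboostError):
    """A model artifact cannot be read or has an incompatible version."""


class FitError(NirboostError):
    """A model cannot be fitted on the given data."""
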