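"""Exception hierarchy shared across the package."""


class CitrusNIRError(Exception):
    """Base class for all package errors."""


class FormatError(CitrusNIRError):
    """A file's layout does not match the expected dialect."""


class GridError(CitrusNIRError):
    """Wavelength header is not a valid uniform grid."""


class ValidationError(CitrusNIRError):
    """Data content violates an invariant (NaNs, duplicate ids, ...)."""


class JoinError(CitrusNIRError):
    """Spectra and reference tables cannot be joined as requested."""


class ParameterError(CitrusNIRError):
    """An operation was called with invalid parameters."""


class TransformError(CitrusNIRError):
    """A fitted transform cannot be applied to the given spectra."""


class FitError(CitrusNIRError):
    """Model fitting failed (degenerate inputs, rank problems, ...)."""


class StateError(CitrusNIRError):
    """An unfitted or incompatible state was used."""


class SerializationError(CitrusNIRError):
    """Persisted artifact cannot be loaded (version mismatch, truncation)."""
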