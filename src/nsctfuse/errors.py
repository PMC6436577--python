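"""Exception types shared across the package."""


class NsctFuseError(Exception):
    """Base class for all package errors."""


class ImageFormatError(NsctFuseError):
    """Unsupported file format, channel count or bit depth."""


class ValidationError(NsctFuseError):
    """An input violates a documented precondition."""


class RegistrationError(ValidationError):
    """The SPECT/CT pair is not pixel-registered (shape mismatch)."""


class ConfigurationError(NsctFuseError):
    """Unknown name or inconsistent configuration values."""


class DimensionError(NsctFuseError):
    """Requested decomposition is too deep for the image size."""


class StructureError(NsctFuseError):
    """Pyramids or bands are structurally incompatible."""
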