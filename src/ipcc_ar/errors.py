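"""Exception hierarchy for the registration pipeline.

Registration of a surgical frame can fail for benign reasons (a frame with
too few visible vessels, an instrument covering most of the field); callers
distinguish recoverable per-frame failures (:class:`RegistrationError`) from
misuse of the API (:class:`ParameterError`, :class:`UnsupportedFormatError`).
"""


class IPCCError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(IPCCError, ValueError):
    """A parameter is outside its documented domain."""


class UnsupportedFormatError(IPCCError, ValueError):
    """An input raster has a channel layout the pipeline cannot consume."""


class DegeneratePatchError(IPCCError):
    """A patch has zero intensity variance and cannot be correlated."""


class DegenerateGeometryError(IPCCError):
    """Correspondence points coincide; no similarity transform is defined."""


class RegistrationError(IPCCError):
    """Frame-level registration failure (no eligible patch pair)."""


class GenerationError(IPCCError):
    """The synthetic vessel generator could not satisfy its density contract."""
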