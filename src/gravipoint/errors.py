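"""Exception hierarchy shared across pipeline stages."""


class GravipointError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(GravipointError):
    """Dataset directory does not follow the documented layout."""


class FormatError(GravipointError):
    """A file exists but its contents violate the declared format."""


class ValidationError(GravipointError):
    """An in-memory record violates a domain invariant."""


class SegmentationError(GravipointError):
    """Touch events do not define a valid movement interval."""
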