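"""Exception hierarchy shared across the pipeline stages."""


class Meth3DLinkError(Exception):
    """Base class for all package errors."""


class MalformedDataError(Meth3DLinkError):
    """A value in an input table violates its domain (e.g. beta outside [0,1])."""


class MetadataError(Meth3DLinkError):
    """Sample metadata does not match the data matrix."""


class MalformedIntervalError(Meth3DLinkError):
    """A genomic interval violates 0-based half-open conventions."""


class ParseError(Meth3DLinkError):
    """A field could not be parsed (e.g. non-numeric score)."""


class InputError(Meth3DLinkError):
    """An operation received inputs outside its preconditions."""


class AnnotationError(Meth3DLinkError):
    """A probe is missing from the manifest."""


class ConfigError(Meth3DLinkError):
    """A configuration value is invalid or inconsistent."""
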