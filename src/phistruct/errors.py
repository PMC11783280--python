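"""Exception hierarchy shared across the toolkit."""


class PhistructError(Exception):
    """Base class for all toolkit errors."""


class ConfigError(PhistructError):
    """Invalid configuration (bad pattern, unknown key, out-of-range value)."""


class InsufficientDataError(PhistructError):
    """An operation received fewer samples than its statistics require."""


class FormatError(PhistructError):
    """A file did not conform to its documented layout."""


class EmptyStructureError(PhistructError):
    """A structure file contained no CA atoms."""
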