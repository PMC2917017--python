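"""Exception types shared across the package."""


class BrcapathError(Exception):
    """Base class for all package errors."""


class ConfigurationError(BrcapathError):
    """A model-parameter file is missing a field, out of range, or inconsistent.

    ``field`` carries a dotted path to the offending entry when known.
    """

    def __init__(self, message: str, field: str | None = None):
        self.field = field
        if field:
            message = f"{field}: {message}"
        super().__init__(message)


class PedigreeError(BrcapathError):
    """A pedigree file or structure is invalid (unknown parent, cycle, ...)."""


class PanelError(BrcapathError):
    """A tumour marker panel is internally inconsistent."""
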