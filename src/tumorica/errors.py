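"""Exception hierarchy shared across the package."""


class TumoricaError(Exception):
    """Base class for all package-specific errors."""


class FormatError(TumoricaError):
    """A file could not be read or parsed as the expected format."""


class ConfigError(TumoricaError):
    """A configuration value violates an invariant of the requested operation."""


class SpecError(TumoricaError):
    """A user-supplied specification (phantom geometry, seed point, ...) is invalid."""


class DataError(TumoricaError):
    """Input data are structurally valid but unusable (non-finite seed, zero variance, ...)."""


class DegenerateMaskError(TumoricaError):
    """A derived mask came out empty where a nonempty mask is required."""


class DegenerateTemplateError(TumoricaError):
    """A tumor template is empty or covers the entire brain mask, so rates are undefined."""


class NoTumorComponentError(TumoricaError):
    """No valid (nonempty after binarization) component was found anywhere in the sweep."""
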