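"""Exception hierarchy for the package."""


class AllostateError(Exception):
    """Base class for all package errors."""


class ConfigurationError(AllostateError):
    """Invalid configuration value or unknown configuration key."""


class FormatError(AllostateError):
    """A file does not parse in the named dialect."""


class SelectionError(AllostateError):
    """An atom selection does not resolve."""


class GeometryError(AllostateError):
    """Degenerate geometry (coincident points, parallel bonds)."""


class FeatureMismatchError(AllostateError):
    """Feature names or dimensionality do not match between objects."""


class EstimationError(AllostateError):
    """Transition-model estimation failed (e.g. empty active set)."""


class DegenerateRangeError(AllostateError):
    """A coordinate has zero observed range; seeds cannot be spaced."""


class IntegrationError(AllostateError):
    """Integrator produced non-finite coordinates."""


class DefinitionError(AllostateError):
    """A macrostate definition does not cover a required microstate."""
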