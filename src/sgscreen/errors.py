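"""Exception types used across the pipeline."""


class SGScreenError(Exception):
    """Base class for pipeline errors."""


class LayoutError(SGScreenError):
    """Requested cell layout cannot be placed on the field grid."""


class ConfigurationError(SGScreenError):
    """Invalid configuration, plate map, or screen setup."""


class NormalizationError(SGScreenError):
    """No usable control wells for percent-of-control normalization."""
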