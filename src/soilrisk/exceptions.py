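"""Exception hierarchy used across the package."""


class SoilRiskError(Exception):
    """Base class for all package-specific errors."""


class FormatError(SoilRiskError):
    """A file does not have the expected layout (missing column, bad header)."""


class ValidationError(SoilRiskError):
    """A value violates a domain invariant; the message names the offender."""


class ConfigError(SoilRiskError):
    """Configuration file contains an unknown key or an invalid value."""


class MeshError(SoilRiskError):
    """Mesh construction or point location failed."""


class FitError(SoilRiskError):
    """Model fitting could not proceed (bad inputs, not non-convergence)."""
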