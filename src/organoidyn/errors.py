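"""Exception hierarchy shared across the package."""


class OrganoidynError(Exception):
    """Base class for all package errors."""


class GeometryError(OrganoidynError, ValueError):
    """Degenerate point configuration (too few points, coplanar cloud, no hull)."""


class DomainError(OrganoidynError, ValueError):
    """Input value outside the mathematical domain of an operation."""


class SchemaError(OrganoidynError, ValueError):
    """A delimited input table is missing required structure."""


class ConfigError(OrganoidynError, ValueError):
    """A run configuration contains unknown or invalid keys."""


class IntegrationError(OrganoidynError, RuntimeError):
    """The stochastic integrator produced a non-finite state."""
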