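"""Package exception types."""


class McfretError(Exception):
    """Base class for all package errors."""


class GeometryError(McfretError):
    """Invalid or singular molecular geometry."""


class ParameterError(McfretError):
    """Invalid physical or numerical parameter."""


class TrajectoryFormatError(McfretError):
    """Malformed trajectory / coupling / geometry file."""


class SamplingError(McfretError):
    """Requested sampling windows do not fit the trajectory."""


class ConfigError(McfretError):
    """Invalid run configuration."""
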