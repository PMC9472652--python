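"""Exception hierarchy shared across the pipeline."""


class NodeMRIError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(NodeMRIError):
    """A configuration or generative spec is invalid; message names the field."""


class DataError(NodeMRIError):
    """Input data violate a precondition (shapes, signs, missing columns)."""
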