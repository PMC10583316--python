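"""Package-wide exception types."""


class OscnetError(Exception):
    """Base class for all oscnet errors."""


class ConfigurationError(OscnetError, ValueError):
    """A configuration object is internally inconsistent or references
    unknown ROIs, networks, bands or groups."""


class InputError(OscnetError, ValueError):
    """Input data violate a precondition (too short, wrong shape,
    missing group, mismatched feature index)."""
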