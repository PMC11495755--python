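"""Exception hierarchy shared across the pipeline stages."""


class NichemapError(Exception):
    """Base class for all nichemap errors."""


class DataFormatError(NichemapError):
    """A file or table does not conform to the expected format."""


class DataIntegrityError(NichemapError):
    """A table violates an internal invariant (e.g. duplicate cell IDs)."""


class ParameterError(NichemapError, ValueError):
    """An operation was called with an out-of-range parameter."""


class GateSpecError(NichemapError):
    """A gating specification references unknown markers or is malformed."""


class ConfigError(NichemapError):
    """A simulation or pipeline configuration is invalid."""


class AssemblyError(NichemapError):
    """Feature assembly cannot proceed (e.g. a patient x region with no images)."""


class ContractError(NichemapError):
    """An operation's precondition was violated (e.g. unlabeled cells)."""
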