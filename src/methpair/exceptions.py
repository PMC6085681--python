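"""Exception types used across the package."""


class MethpairError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(MethpairError):
    """An infeasible or contradictory configuration was supplied."""


class ValidationError(MethpairError):
    """Input data violate a structural precondition (pairing, ranges, coverage)."""
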