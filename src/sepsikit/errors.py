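"""Exception types shared across the package."""


class ConfigError(ValueError):
    """A configuration value is invalid; the message names the offending field."""


class ContractViolation(ValueError):
    """An input violated a documented precondition (e.g. negative event times)."""


class ValidationError(ValueError):
    """Input data failed a validity check; the message lists the offending rows."""
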