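"""Exception hierarchy shared across the toolkit."""


class HQRiskError(Exception):
    """Base class for all toolkit errors."""


class DomainError(HQRiskError, ValueError):
    """A numeric input violates the physical domain of a quantity.

    The message always names the offending field.
    """


class ConfigurationError(HQRiskError, ValueError):
    """A scenario or distribution specification is structurally invalid."""


class ScenarioError(ConfigurationError):
    """A scenario config file failed parsing or schema validation."""
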