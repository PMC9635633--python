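"""Exception hierarchy shared across the toolkit."""


class HaplokitError(Exception):
    """Base class for all toolkit errors."""


class FormatError(HaplokitError):
    """Malformed input file (bad header, missing column, ragged alignment...)."""


class DomainError(HaplokitError):
    """Arguments outside an operation's domain (empty sequence, bad length...)."""


class ConfigError(HaplokitError):
    """Invalid configuration (infeasible packing, bad thresholds...)."""
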