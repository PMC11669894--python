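"""Exception hierarchy for validation and format errors."""


class KellvarError(Exception):
    """Base class for all package-specific errors."""


class ParseError(KellvarError):
    """A substitution string or table row could not be parsed."""


class FormatError(KellvarError):
    """An input file violates its format contract."""


class ConsistencyError(KellvarError):
    """Merged inputs contradict each other (e.g. conflicting wild types)."""


class ConfigError(KellvarError):
    """Invalid configuration (overlapping domains, bad thresholds...)."""
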