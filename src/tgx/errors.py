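"""Exception hierarchy shared across the toolkit."""


class TgxError(Exception):
    """Base class for all toolkit errors."""


class FormatError(TgxError):
    """An input file violates its declared dialect (GMT, TSV layout, tokens)."""


class ValidationError(TgxError):
    """Inputs parse but violate a domain invariant (design, finiteness, keys)."""


class ConfigError(TgxError):
    """A simulation or run configuration is out of its valid range."""
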