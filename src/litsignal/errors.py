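"""Exception hierarchy shared across the package."""


class LitsignalError(Exception):
    """Base class for all package-specific errors."""


class ParseError(LitsignalError, ValueError):
    """An input file does not conform to its documented dialect."""


class ValidationError(LitsignalError, ValueError):
    """Arguments or data violate a documented invariant."""


class UnknownTermError(LitsignalError, KeyError):
    """A descriptor ID was looked up that the terminology does not contain."""


class UnknownSubjectError(LitsignalError, KeyError):
    """A drug ingredient or ATC class is absent from the drug map."""


class ConfigurationError(LitsignalError, ValueError):
    """A requested configuration cannot be satisfied (e.g. a gold-standard
    outcome term is excluded by the chosen abstraction level)."""
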