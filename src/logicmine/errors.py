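"""Exception hierarchy shared across the package."""


class LogicmineError(Exception):
    """Base class for all package errors."""


class ValidationError(LogicmineError):
    """Input violates a documented precondition or invariant."""


class FormatError(LogicmineError):
    """A file or cell could not be parsed; message names the offending location."""


class InapplicableRule(LogicmineError):
    """A rule's antecedent is never true, so its confidence is undefined."""
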