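"""Exception hierarchy.

Configuration problems (bad rule files, invalid generator settings, unknown
method names) raise :class:`ConfigurationError`; malformed input data raises
:class:`InputError`.  The CLI maps these to exit codes 1 and 2 respectively.
"""


class EchocleanError(Exception):
    """Base class for all package errors."""


class ConfigurationError(EchocleanError):
    """A configuration value or rule definition is invalid."""


class InputError(EchocleanError):
    """Input data violates a precondition (e.g. missing identifiers)."""
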