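"""Exception hierarchy for pufselect."""


class PufselectError(Exception):
    """Base class for all pufselect errors."""


class InputError(PufselectError, ValueError):
    """Invalid user-supplied data (bad alphabet, malformed file, empty input)."""


class ConfigurationError(PufselectError, ValueError):
    """Inconsistent configuration (e.g. pattern class without a Kd entry)."""


class UndefinedRatioError(PufselectError, ZeroDivisionError):
    """Compact:extended ratio requested where the extended count is zero."""


class FitError(PufselectError, RuntimeError):
    """Nonlinear binding fit failed to converge or hit a parameter bound."""
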