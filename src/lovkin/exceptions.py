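"""Exception hierarchy for lovkin."""


class LovkinError(Exception):
    """Base class for all lovkin errors."""


class InputError(LovkinError, ValueError):
    """Invalid user-supplied value (negative time, non-positive rate, ...)."""


class DegenerateModelError(InputError):
    """A model configuration with no dynamics where dynamics are required."""


class NumericError(LovkinError, RuntimeError):
    """Numerical routine (integrator, quadrature) failed to converge."""

    def __init__(self, message, diagnostics=None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class FitError(LovkinError, RuntimeError):
    """Nonlinear fit failed to converge; carries best-so-far diagnostics."""

    def __init__(self, message, best=None):
        super().__init__(message)
        self.best = best


class ParseError(LovkinError, ValueError):
    """Malformed trace/spectrum file; names the offending line."""

    def __init__(self, message, path=None, line=None):
        loc = ""
        if path is not None:
            loc = f" [{path}" + (f":{line}" if line is not None else "") + "]"
        super().__init__(message + loc)
        self.path = path
        self.line = line
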