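"""Exception types shared across the package."""


class FirecycleError(Exception):
    """Base class for package errors."""


class InvalidStateError(FirecycleError, ValueError):
    """A system state violates its invariants (e.g. S + F > 1)."""


class DivergenceError(FirecycleError, RuntimeError):
    """Integration left the valid state domain by more than tolerance."""


class ConfigError(FirecycleError, ValueError):
    """A configuration file or parameter set failed validation."""


class ZeroBurnError(FirecycleError, ZeroDivisionError):
    """Percent reduction is undefined because the reference burn is zero."""
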