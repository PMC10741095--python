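"""Exception hierarchy shared across the package.

Everything derives from :class:`EtorqueError` so callers can catch the
package's failures with one clause; the value-like errors also derive from
``ValueError`` and the state-like errors from ``RuntimeError`` so generic
handlers behave sensibly.
"""


class EtorqueError(Exception):
    """Base class for all errors raised by etorque."""


class FormatError(EtorqueError, ValueError):
    """A file does not follow the documented on-disk format."""


class IntegrityError(EtorqueError, ValueError):
    """Inputs are structurally inconsistent (length mismatch, too few samples...)."""


class DomainError(EtorqueError, ValueError):
    """A numeric argument lies outside the operation's admissible domain."""


class SamplingRateError(EtorqueError, ValueError):
    """The sampling rate is too low for the requested filter."""


class ConfigError(EtorqueError, ValueError):
    """A configuration value violates its documented invariant."""


class DegenerateFeatureError(EtorqueError, ValueError):
    """A feature column is constant and cannot be standardized."""


class StateError(EtorqueError, RuntimeError):
    """An operation was called before its prerequisites were established."""


class DivergenceError(EtorqueError, RuntimeError):
    """Training produced a non-finite loss."""
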