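"""Exception hierarchy."""


class RepliscopeError(Exception):
    """Base class for all package errors."""


class SchemaError(RepliscopeError):
    """A dataset file does not match the expected column schema."""


class ValidationError(RepliscopeError):
    """A record violates a type invariant."""


class DomainError(RepliscopeError):
    """An operation was called with arguments outside its domain."""


class UnsupportedStatisticError(DomainError):
    """The reported statistic cannot be converted to an effect estimate."""


class ScaleMismatchError(DomainError):
    """Two effect estimates live on different scales."""


class ConvergenceError(RepliscopeError):
    """MCMC sampling failed the convergence policy."""


class PipelineError(RepliscopeError):
    """A pipeline stage failed or an intermediate file was corrupted."""
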