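"""Typed errors shared across the package."""


class EndokinError(Exception):
    """Base class for all package errors."""


class DomainError(EndokinError, ValueError):
    """Input violates a documented precondition (negative mass, bad shape...)."""


class DegenerateTopologyError(EndokinError):
    """A sequential transfer coefficient is zero: no steady through-flux exists."""


class UndefinedResidenceError(EndokinError):
    """Residence time undefined because the entering flux vanishes."""


class NonIdentifiableError(EndokinError):
    """Data carry no information about the requested parameters (e.g. flat series)."""


class NonConvergenceError(EndokinError):
    """An iterative procedure failed; carries the best point reached so far."""

    def __init__(self, message, best=None):
        super().__init__(message)
        self.best = best


class ConfigError(EndokinError):
    """A run configuration references missing inputs or inconsistent settings."""


class PipelineError(EndokinError):
    """A pipeline stage failed after producing partial results."""
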