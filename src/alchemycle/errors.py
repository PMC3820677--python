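"""Exception hierarchy for schedule, sampling and convergence failures."""

from __future__ import annotations


class AlchemycleError(Exception):
    """Base class for all package-specific errors."""


class ScheduleError(AlchemycleError):
    """A λ schedule is malformed or cannot satisfy a per-window target.

    When a requested per-window free-energy target is unsatisfiable at the
    given window count, ``required_n`` carries the smallest window count that
    would satisfy it.
    """

    def __init__(self, message: str, required_n: int | None = None):
        super().__init__(message)
        self.required_n = required_n


class SampleSizeError(AlchemycleError):
    """Too few samples for the requested statistical operation."""


class ParseError(AlchemycleError):
    """A data file violates its dialect; ``line`` is the 1-based line number."""

    def __init__(self, message: str, line: int | None = None):
        super().__init__(message)
        self.line = line


class ConfigurationError(AlchemycleError):
    """Inconsistent or incomplete run configuration."""


class ConvergenceError(AlchemycleError):
    """Self-consistent iteration failed to converge; carries the residual."""

    def __init__(self, message: str, residual: float | None = None,
                 iterations: int | None = None):
        super().__init__(message)
        self.residual = residual
        self.iterations = iterations


class AnchorError(AlchemycleError):
    """The PMF does not vanish in the region declared to be bulk."""


class IncompleteCycleError(AlchemycleError):
    """A thermodynamic cycle is missing one or more stages."""


class LabelError(AlchemycleError):
    """Stage/channel labels are inconsistent across combined quantities."""
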