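"""Exception hierarchy shared across the package."""


class RhythmforgeError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(RhythmforgeError, ValueError):
    """A parameter value violates its documented domain."""


class InvalidSequenceError(RhythmforgeError, ValueError):
    """An event/interval/ratio sequence violates its invariants."""


class BelowRheobaseError(RhythmforgeError, ValueError):
    """Constant drive too weak for the neuron ever to reach threshold."""


class SimulationTimeoutError(RhythmforgeError, RuntimeError):
    """A simulation failed to produce the requested output within its time budget."""


class DegenerateDistributionError(RhythmforgeError, ValueError):
    """A sample has (near-)zero variance and no density estimate exists."""
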