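"""Synthetic input event trains and the input-frequency-ratio parameterization.

Two stimulus classes drive the generative models: Poisson trains (randomly
distributed temporal events; their rhythm ratios are Uniform(0,1)) and
perfectly isochronous trains. The relative tempo of input and model is
expressed throughout as the dimensionless ratio f_input / (f_input + f_model),
so that 0.5 means matched frequencies, 0.75 a 3:1 (input three times faster)
relation, and values below 0.5 an input slower than the model.

All times are in milliseconds; rates and frequencies in Hz (events/second).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import InvalidParameterError, InvalidSequenceError

EVENT_KINDS = ("stimulus", "spike", "chirp")


@dataclass(frozen=True)
class EventSequence:
    """A strictly increasing sequence of event timestamps (ms).

    The universal currency between modules: stimulus trains enter the models,
    spike/chirp trains come out, and the metrics accept any of them.
    """

    times: np.ndarray
    kind: str = "stimulus"

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        object.__setattr__(self, "times", times)
        if self.kind not in EVENT_KINDS:
            raise InvalidParameterError(f"kind must be one of {EVENT_KINDS}, got {self.kind!r}")
        if times.ndim != 1:
            raise InvalidSequenceError("event times must be a 1-D array")
        if times.size and times[0] < 0:
            raise InvalidSequenceError("event times must be non-negative")
        if times.size >= 2 and not np.all(np.diff(times) > 0):
            raise InvalidSequenceError("event times must be strictly increasing")

    def __len__(self) -> int:
        return int(self.times.size)

    @property
    def n_intervals(self) -> int:
        return max(len(self) - 1, 0)


def generate_poisson(rate: float, n_intervals: int, seed: int | np.random.Generator) -> EventSequence:
    """Generate a Poisson event train with ``n_intervals`` i.i.d. exponential gaps.

    Parameters
    ----------
    rate : float
        Mean event rate in Hz; gaps have mean 1000/rate ms.
    n_intervals : int
        Number of inter-event intervals; the train has ``n_intervals + 1`` events.
    seed : int or numpy Generator
        Source of randomness; a fixed integer makes the train reproducible.
    """
    if rate <= 0:
        raise InvalidParameterError(f"rate must be positive, got {rate}")
    if n_intervals < 1:
        raise InvalidParameterError(f"n_intervals must be >= 1, got {n_intervals}")
    rng = np.random.default_rng(seed)
    gaps = rng.exponential(scale=1000.0 / rate, size=int(n_intervals))
    times = np.concatenate([[0.0], np.cumsum(gaps)])
    return EventSequence(times=times, kind="stimulus")


def generate_isochronous(frequency: float, n_events: int, start: float = 0.0) -> EventSequence:
    """Generate a perfectly isochronous train: gaps all exactly 1000/frequency ms."""
    if frequency <= 0:
        raise InvalidParameterError(f"frequency must be positive, got {frequency}")
    if n_events < 2:
        raise InvalidParameterError(f"n_events must be >= 2, got {n_events}")
    if start < 0:
        raise InvalidParameterError(f"start must be >= 0, got {start}")
    period = 1000.0 / frequency
    times = start + period * np.arange(int(n_events), dtype=float)
    return EventSequence(times=times, kind="stimulus")


def frequency_ratio(f_input: float, f_model: float) -> float:
    """Input-frequency ratio f_input / (f_input + f_model), in (0, 1).

    0.5 means matched frequencies; an input three times faster than the model
    (3:1) gives 0.75; a slower input gives a value below 0.5.
    """
    if f_input <= 0 or f_model <= 0:
        raise InvalidParameterError("frequencies must be positive")
    return f_input / (f_input + f_model)


def input_rate_for_ratio(ratio: float, f_model: float) -> float:
    """Invert :func:`frequency_ratio`: the input rate (Hz) realizing ``ratio``."""
    if not 0.0 < ratio < 1.0:
        raise InvalidParameterError(f"ratio must lie strictly in (0, 1), got {ratio}")
    if f_model <= 0:
        raise InvalidParameterError("f_model must be positive")
    return f_model * ratio / (1.0 - ratio)


def write_events(seq: EventSequence, path: str | Path) -> None:
    """Write an event sequence as two-column CSV ``time_ms,kind`` (with header)."""
    df = pd.DataFrame({"time_ms": seq.times, "kind": seq.kind})
    df.to_csv(path, index=False, float_format="%.10g")


def read_events(path: str | Path, kind: str | None = None) -> EventSequence:
    """Read an event sequence from CSV.

    Accepts the two-column ``time_ms,kind`` dialect written by
    :func:`write_events`, or a headerless single column of onset times.
    """
    path = Path(path)
    first = path.read_text().lstrip().splitlines()[0] if path.stat().st_size else ""
    if "time_ms" in first:
        df = pd.read_csv(path)
        times = df["time_ms"].to_numpy(dtype=float)
        inferred = str(df["kind"].iloc[0]) if "kind" in df.columns and len(df) else "stimulus"
    else:
        times = pd.read_csv(path, header=None).iloc[:, 0].to_numpy(dtype=float)
        inferred = "stimulus"
    return EventSequence(times=times, kind=kind or inferred)
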