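"""Quantification of rhythmic structure in event sequences.

From an event sequence t_0 < t_1 < ... the pipeline computes inter-onset
intervals i_k = t_{k+1} - t_k, rhythm ratios r_k = i_k / (i_k + i_{k+1})
(dimensionless, in (0,1); 0.5 is isochrony, 2/3 a long-short 2:1 pair), and
from the ratio sample three summaries:

* a Gaussian kernel density estimate of the ratio distribution (Scott's rule);
* for each of the seven small-integer ratios 1:3, 1:2, 2:3, 1:1, 3:2, 2:1,
  3:1 a weighted on-integer fraction measuring how concentrated the ratios
  are at that category (inverse ratios such as 1:2 and 2:1 are counted
  separately, never folded);
* the differential entropy of the ratio distribution, estimated by the
  Ebrahimi spacing estimator. On (0,1) the maximum is 0 nats (uniform
  distribution, e.g. ratios of a Poisson train); a perfectly isochronous
  sequence has all ratios identical and scores -inf.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import DegenerateDistributionError, InvalidParameterError, InvalidSequenceError
from .generators import EventSequence

#: The seven small-integer ratio categories, as rhythm-ratio values.
DEFAULT_TARGETS = (0.25, 1.0 / 3.0, 0.4, 0.5, 0.6, 2.0 / 3.0, 0.75)

TARGET_LABELS = {
    0.25: "1:3",
    1.0 / 3.0: "1:2",
    0.4: "2:3",
    0.5: "1:1",
    0.6: "3:2",
    2.0 / 3.0: "2:1",
    0.75: "3:1",
}


def intervals(seq: EventSequence | np.ndarray) -> np.ndarray:
    """Inter-onset interval durations i_k = t_{k+1} - t_k (ms), all positive."""
    times = seq.times if isinstance(seq, EventSequence) else np.asarray(seq, dtype=float)
    if times.size < 2:
        raise InvalidSequenceError("need at least 2 events to form intervals")
    iv = np.diff(times)
    if np.any(iv <= 0):
        raise InvalidSequenceError("event times must be strictly increasing")
    return iv


def rhythm_ratios(iv: np.ndarray) -> np.ndarray:
    """Rhythm ratios r_k = i_k / (i_k + i_{k+1}) of successive intervals."""
    iv = np.asarray(iv, dtype=float)
    if iv.size < 2:
        raise InvalidSequenceError("need at least 2 intervals to form rhythm ratios")
    if np.any(iv <= 0):
        raise InvalidSequenceError("interval durations must be positive")
    return iv[:-1] / (iv[:-1] + iv[1:])


def kde_density(ratios: np.ndarray, grid: np.ndarray | None = None) -> np.ndarray:
    """Gaussian-kernel density estimate of a ratio sample on ``grid``.

    Uses Scott's-rule bandwidth (the conventional default). Raises
    :class:`DegenerateDistributionError` on a zero-variance sample, for which
    no density exists.
    """
    ratios = np.asarray(ratios, dtype=float)
    if np.unique(ratios).size < 2:
        raise DegenerateDistributionError("ratio sample has zero variance; no density estimate")
    if grid is None:
        grid = np.linspace(0.0, 1.0, 512)
    kde = stats.gaussian_kde(ratios)
    return kde(np.asarray(grid, dtype=float))


@dataclass(frozen=True)
class IntegerRatioBins:
    """On/off-integer bins tiling the rhythm-ratio axis around each category.

    Adjacent targets split at their midpoint; within a target's segment the
    on-bin is the central half (half-width one quarter of the distance to each
    neighbor) and the remainder of the segment is off-bin. The outermost
    targets mirror their inner half-width, so the tiling spans
    [0.25 - 1/24, 0.75 + 1/24] for the default seven categories. Per class,
    counts are weighted by the inverse of the class's total width, which makes
    a uniform ratio sample score 0.5.
    """

    targets: tuple[float, ...]
    on_bins: tuple[tuple[float, float], ...]       # (lo, hi) per target
    segments: tuple[tuple[float, float], ...]      # full on+off segment per target


def build_bins(targets: tuple[float, ...] = DEFAULT_TARGETS) -> IntegerRatioBins:
    """Construct the on/off-integer bins for a sorted tuple of target ratios."""
    t = np.asarray(targets, dtype=float)
    if t.size < 2:
        raise InvalidParameterError("need at least 2 targets")
    if np.any(np.diff(t) <= 0):
        raise InvalidParameterError("targets must be sorted and distinct")
    on_bins = []
    segments = []
    for i, target in enumerate(t):
        d_left = t[i] - t[i - 1] if i > 0 else t[i + 1] - t[i]
        d_right = t[i + 1] - t[i] if i < t.size - 1 else t[i] - t[i - 1]
        segments.append((target - d_left / 2.0, target + d_right / 2.0))
        on_bins.append((target - d_left / 4.0, target + d_right / 4.0))
    return IntegerRatioBins(targets=tuple(t), on_bins=tuple(on_bins), segments=tuple(segments))


def on_integer_fraction(
    ratios: np.ndarray, target: float, bins: IntegerRatioBins | None = None
) -> float:
    """Weighted on-integer fraction W_on / (W_on + W_off) for one category.

    W_on is the count of ratios inside the target's on-bin divided by the
    on-bin width; W_off the count in the two flanking off-bins divided by
    their combined width. Returns NaN (undefined) when no ratio falls in any
    of the three bins. Near 1 means the ratio distribution is concentrated on
    the category; a uniform sample scores 0.5.
    """
    if bins is None:
        bins = build_bins()
    matches = [i for i, tg in enumerate(bins.targets) if math.isclose(tg, target, abs_tol=1e-12)]
    if not matches:
        raise InvalidParameterError(f"unknown target {target}; known: {bins.targets}")
    i = matches[0]
    lo_seg, hi_seg = bins.segments[i]
    lo_on, hi_on = bins.on_bins[i]
    r = np.asarray(ratios, dtype=float)
    n_on = int(np.count_nonzero((r >= lo_on) & (r <= hi_on)))
    n_off = int(np.count_nonzero(((r >= lo_seg) & (r < lo_on)) | ((r > hi_on) & (r <= hi_seg))))
    if n_on + n_off == 0:
        return float("nan")
    w_on = n_on / (hi_on - lo_on)
    w_off = n_off / ((lo_on - lo_seg) + (hi_seg - hi_on))
    return w_on / (w_on + w_off)


def differential_entropy(ratios: np.ndarray, method: str = "ebrahimi") -> float:
    """Spacing-based differential entropy estimate of a ratio sample, in nats.

    Window length m = floor(sqrt(n)). A (near-)degenerate sample — more than
    half of the m-spacings exactly zero, as produced by an isochronous event
    sequence — returns -inf rather than raising, matching how such sequences
    are reported (minimal entropy).
    """
    x = np.asarray(ratios, dtype=float)
    if x.size < 10:
        raise InvalidSequenceError(f"need at least 10 ratios, got {x.size}")
    n = x.size
    m = max(1, int(math.isqrt(n)))
    xs = np.sort(x)
    spacings = xs[m:] - xs[:-m]
    # 1e-12 absorbs float jitter in ratios of nominally identical intervals
    if np.mean(spacings <= 1e-12) > 0.5:
        return float("-inf")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # log(0) from residual zero spacings
        est = float(stats.differential_entropy(x, window_length=m, method=method))
    return est if math.isfinite(est) else float("-inf")


def sequence_metrics(seq: EventSequence, bins: IntegerRatioBins | None = None) -> dict[str, float]:
    """One-row summary of a sequence: interval count, entropy, seven on-fractions."""
    if bins is None:
        bins = build_bins()
    iv = intervals(seq)
    r = rhythm_ratios(iv)
    out: dict[str, float] = {
        "n_intervals": float(iv.size),
        "entropy": differential_entropy(r),
    }
    for target in bins.targets:
        label = TARGET_LABELS.get(target, f"{target:.4g}")
        key = "frac_" + label.replace(":", "_")
        out[key] = on_integer_fraction(r, target, bins)
    return out
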