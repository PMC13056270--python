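"""Generative model of cricket stridulation driven through a phase response curve.

The cricket chirps with natural period T0. A stimulus heard at phase
φ = (elapsed time since last chirp) / (current period) rescales the ongoing
cycle by a factor (1 + Δ(φ)), where Δ is a Type II phase response curve (PRC):
a stimulus shortly after a chirp lengthens the cycle (delay), a stimulus
shortly before the next chirp shortens it (advance). If several stimuli fall
in one cycle, only the most recent one counts — each new stimulus recomputes
the cycle from the pre-perturbation period. After a perturbed cycle the
perturbed period is carried forward, and at every chirp the period relaxes a
fraction ρ of the way back toward T0, so ρ=1 restores the natural period
immediately after a perturbation and ρ=0.2 closes 20% of the remaining gap per
chirp (deviations decay geometrically with factor 1−ρ).

The default PRC is a triangular Type II curve (the empirical curve this
mechanism abstracts is known only graphically, so any smooth stand-in with the
extend-early / shorten-late structure is equivalent for qualitative work): Δ
rises linearly from 0 to ``a`` on [0, φ*/2], falls back through 0 at the
breakpoint φ*, and continues linearly down to −``b`` as φ → 1. A sinusoidal
alternative with the same zero crossings is available via ``shape="sine"``.
Optional additive Gaussian noise on Δ models trial-to-trial PRC variability.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidParameterError
from .generators import EventSequence


@dataclass(frozen=True)
class PRCSpec:
    """Shape of the phase response curve Δ(φ), dimensionless.

    ``a`` is the peak delay (period lengthening) for early-phase stimuli,
    ``b`` the peak advance (shortening) for late-phase stimuli, and
    ``phi_star`` the breakpoint where delay turns to advance (Δ(φ*) = 0).
    ``noise_sd`` adds zero-mean Gaussian noise to every evaluation, truncated
    below at Δ = −0.95 so the perturbed period stays positive.
    """

    a: float = 0.5
    b: float = 0.5
    phi_star: float = 0.6
    noise_sd: float = 0.0
    shape: str = "triangular"

    def __post_init__(self) -> None:
        if not 0.0 < self.phi_star < 1.0:
            raise InvalidParameterError("phi_star must lie strictly in (0, 1)")
        if self.a < 0 or not 0.0 <= self.b < 1.0:
            raise InvalidParameterError("need a >= 0 and 0 <= b < 1 (period must stay positive)")
        if self.noise_sd < 0:
            raise InvalidParameterError("noise_sd must be non-negative")
        if self.shape not in ("triangular", "sine"):
            raise InvalidParameterError("shape must be 'triangular' or 'sine'")


@dataclass(frozen=True)
class CricketParams:
    """Natural period, PRC and relaxation rate of the simulated cricket."""

    T0: float = 2000.0                       # natural chirp period (ms)
    prc: PRCSpec = field(default_factory=PRCSpec)
    rho: float = 0.5                         # relaxation rate toward T0, in [0, 1]
    seed: int = 0                            # PRC-noise seed

    def __post_init__(self) -> None:
        if self.T0 <= 0:
            raise InvalidParameterError("T0 must be positive")
        if not 0.0 <= self.rho <= 1.0:
            raise InvalidParameterError("rho must lie in [0, 1]")


def _prc_base(phase: float, spec: PRCSpec) -> float:
    ps = spec.phi_star
    if spec.shape == "sine":
        if phase < ps:
            return spec.a * math.sin(math.pi * phase / ps)
        return -spec.b * math.sin(math.pi * (phase - ps) / (1.0 - ps))
    peak = 0.5 * ps
    if phase < peak:
        return spec.a * phase / peak
    if phase < ps:
        return spec.a * (ps - phase) / (ps - peak)
    return -spec.b * (phase - ps) / (1.0 - ps)


def prc_value(phase: float, spec: PRCSpec, rng: np.random.Generator | None = None) -> float:
    """Fractional period change Δ for a stimulus at ``phase`` ∈ [0, 1).

    Positive Δ lengthens the ongoing cycle (delay), negative Δ shortens it
    (advance). With ``spec.noise_sd > 0`` a Gaussian perturbation is added
    (truncated at Δ > −0.95); pass an ``rng`` for reproducibility.
    """
    if not 0.0 <= phase < 1.0:
        raise InvalidParameterError(f"phase must lie in [0, 1), got {phase}")
    delta = _prc_base(float(phase), spec)
    if spec.noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng()
        delta += spec.noise_sd * rng.standard_normal()
        delta = max(delta, -0.95)
    return delta


def simulate_cricket(
    params: CricketParams,
    input: EventSequence | None,
    n_chirps: int,
    *,
    start_time: float = 0.0,
) -> EventSequence:
    """Simulate ``n_chirps`` chirps of a cricket hearing the given stimulus train.

    The first chirp is emitted at ``start_time``; stimuli before it are
    ignored. A stimulus falling exactly on a chirp time belongs to the new
    cycle (phase 0). If the PRC shortens a cycle so much that the rescheduled
    chirp would precede the stimulus itself, the chirp is emitted immediately
    after the stimulus (a small causality guard of 1e-6 · T0).
    """
    if n_chirps < 2:
        raise InvalidParameterError("n_chirps must be >= 2")
    rng = np.random.default_rng(params.seed)
    stim = input.times if input is not None and len(input) else np.empty(0)
    eps = 1e-6 * params.T0

    chirps = [float(start_time)]
    t_cur = params.T0
    pos = int(np.searchsorted(stim, start_time, side="left"))
    while len(chirps) < n_chirps:
        c = chirps[-1]
        period = t_cur
        perturbed = False
        scheduled = c + period
        while pos < len(stim) and stim[pos] < scheduled:
            s = float(stim[pos])
            pos += 1
            if s < c:  # stale stimulus from a cycle cut short by the guard
                continue
            phase = min((s - c) / t_cur, math.nextafter(1.0, 0.0))
            delta = prc_value(phase, params.prc, rng)
            period = t_cur * (1.0 + delta)
            if period <= 0:
                raise InvalidParameterError("PRC produced a non-positive period")
            if c + period <= s:
                period = (s - c) + eps
            scheduled = c + period
            perturbed = True
        chirps.append(scheduled)
        if perturbed:
            t_cur = period
        t_cur = t_cur + params.rho * (params.T0 - t_cur)
    return EventSequence(times=np.asarray(chirps), kind="chirp")
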