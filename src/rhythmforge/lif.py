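"""Leaky integrate-and-fire neuron with alpha-shaped post-synaptic currents.

Subthreshold dynamics::

    C_m dV/dt = -(C_m / tau_m) (V - E_L) + I_e + I_syn(t)

with ``I_syn`` the sum of alpha currents w · e · (t/tau_syn) · exp(-t/tau_syn)
triggered by incoming excitatory spikes (peak amplitude exactly ``w`` pA at
``t = tau_syn`` after each spike). When V reaches the threshold ``V_th`` the
neuron emits a spike, resets to ``V_reset`` and clamps the potential there for
the refractory period ``t_ref``; synaptic currents keep evolving (and incoming
spikes keep accumulating) during refractoriness, they just cannot move V.

The linear subthreshold system (membrane + alpha-current auxiliary pair) is
integrated by exact exponential propagation on a fixed grid of step ``dt``;
input events are snapped to the nearest grid point and spike times are
reported at the grid point where threshold is crossed, so timing accuracy is
O(dt). This is a Type I oscillator: excitatory input can only advance the next
spike, never delay it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import BelowRheobaseError, InvalidParameterError, SimulationTimeoutError
from .generators import EventSequence

_BLOCK_STEPS = 1 << 16  # max grid steps evaluated per vectorized block


@dataclass(frozen=True)
class LIFParams:
    """Membrane, synapse and drive parameters of the LIF neuron.

    Units: capacitance pF, times ms, potentials mV, currents pA. The defaults
    are the conventional ones for this simulator family; ``I_e`` is typically
    set through :func:`current_for_rate` to realize a target intrinsic rate.
    """

    C_m: float = 250.0        # membrane capacitance (pF)
    tau_m: float = 10.0       # membrane time constant (ms)
    E_L: float = -70.0        # leak / resting potential (mV)
    V_th: float = -55.0       # firing threshold (mV)
    V_reset: float = -70.0    # post-spike reset potential (mV)
    t_ref: float = 2.0        # absolute refractory period (ms)
    I_e: float = 400.0        # constant drive current (pA)
    w: float = 500.0          # connection weight = alpha-current peak (pA)
    tau_syn: float = 2.0      # synaptic rise time (ms)
    dt: float = 0.1           # integration step (ms)

    def __post_init__(self) -> None:
        if min(self.C_m, self.tau_m, self.tau_syn, self.dt) <= 0:
            raise InvalidParameterError("C_m, tau_m, tau_syn and dt must be positive")
        if self.t_ref < 0:
            raise InvalidParameterError("t_ref must be non-negative")
        if self.t_ref > 0 and self.dt > self.t_ref:
            raise InvalidParameterError("dt must not exceed t_ref when t_ref > 0")
        if self.V_th <= self.V_reset:
            raise InvalidParameterError("V_th must exceed V_reset")
        if self.V_th <= self.E_L:
            raise InvalidParameterError("V_th must exceed E_L for finite-rate firing")

    @property
    def v_inf(self) -> float:
        """Steady-state potential under the constant drive alone (mV)."""
        return self.E_L + self.tau_m * self.I_e / self.C_m


def alpha_current(t_since_spike: float | np.ndarray, w: float, tau_syn: float) -> float | np.ndarray:
    """Alpha post-synaptic current kernel, w·e·(t/τ)·exp(−t/τ); 0 for t < 0.

    Peaks at exactly ``w`` pA at ``t_since_spike == tau_syn``.
    """
    if tau_syn <= 0:
        raise InvalidParameterError("tau_syn must be positive")
    t = np.asarray(t_since_spike, dtype=float)
    out = np.where(t >= 0, w * math.e * (t / tau_syn) * np.exp(-np.minimum(t, 7e2 * tau_syn) / tau_syn), 0.0)
    return float(out) if np.isscalar(t_since_spike) else out


def intrinsic_period(params: LIFParams) -> float:
    """Closed-form free-run inter-spike interval (ms) of the unforced neuron.

    t_ref + tau_m · ln((V∞ − V_reset)/(V∞ − V_th)), valid above rheobase.
    """
    v_inf = params.v_inf
    if v_inf <= params.V_th:
        raise BelowRheobaseError(
            f"steady-state potential {v_inf:.3f} mV does not exceed threshold "
            f"{params.V_th:.3f} mV; the neuron never fires"
        )
    return params.t_ref + params.tau_m * math.log((v_inf - params.V_reset) / (v_inf - params.V_th))


def current_for_rate(target_rate: float, params: LIFParams) -> float:
    """Constant drive I_e (pA) whose free-run rate is ``target_rate`` Hz.

    Analytic inversion of the period formula; the round trip through
    :func:`intrinsic_period` is exact to machine precision.
    """
    if target_rate <= 0:
        raise InvalidParameterError("target_rate must be positive")
    period = 1000.0 / target_rate
    if period <= params.t_ref:
        raise InvalidParameterError(
            f"target period {period:.4f} ms not attainable: refractory period is {params.t_ref} ms"
        )
    k = math.exp((period - params.t_ref) / params.tau_m)
    v_inf = (k * params.V_th - params.V_reset) / (k - 1.0)
    return (v_inf - params.E_L) * params.C_m / params.tau_m


def _segment_potentials(v0, y1, y2, k_steps, p: "_Propagators"):
    """V at offsets dt·(1..k_steps) from a state, with no events in between."""
    s = p.dt * np.arange(1, k_steps + 1)
    ea = np.exp(-p.a * s)
    eb = np.exp(-p.b * s)
    if p.degenerate:
        vsyn = ea * (y2 * s + 0.5 * y1 * s * s) / p.C_m
    else:
        d = (eb - ea) / p.c
        vsyn = (y2 * d + y1 * (s * eb / p.c - d / p.c)) / p.C_m
    return p.v_inf + (v0 - p.v_inf) * ea + vsyn, eb, s


class _Propagators:
    """Constants of the exact exponential update, precomputed per simulation."""

    def __init__(self, params: LIFParams):
        self.dt = params.dt
        self.a = 1.0 / params.tau_m
        self.b = 1.0 / params.tau_syn
        self.c = self.a - self.b
        self.degenerate = abs(self.c) < 1e-12
        self.C_m = params.C_m
        self.v_inf = params.v_inf

    def advance(self, v0, y1, y2, n_steps):
        """Exact state after n_steps with no intervening events."""
        s = self.dt * n_steps
        ea = math.exp(-self.a * s)
        eb = math.exp(-self.b * s)
        y1n = y1 * eb
        y2n = (y2 + s * y1) * eb
        if self.degenerate:
            vsyn = ea * (y2 * s + 0.5 * y1 * s * s) / self.C_m
        else:
            d = (eb - ea) / self.c
            vsyn = (y2 * d + y1 * (s * eb / self.c - d / self.c)) / self.C_m
        vn = self.v_inf + (v0 - self.v_inf) * ea + vsyn
        return vn, y1n, y2n


def simulate_lif(
    params: LIFParams,
    input: EventSequence | None,
    n_output_intervals: int,
    *,
    v_init: float | None = None,
    max_duration: float | None = None,
) -> EventSequence:
    """Simulate the forced neuron until it has emitted ``n_output_intervals`` ISIs.

    Parameters
    ----------
    params : LIFParams
        Neuron parameters; ``params.w`` scales every incoming event.
    input : EventSequence or None
        Excitatory input spike train (None or empty for a free run). Events
        are snapped to the nearest grid point; events arriving during
        refractoriness still feed the synaptic state.
    n_output_intervals : int
        Number of output inter-spike intervals required (>= 1); the returned
        train has ``n_output_intervals + 1`` spikes.
    v_init : float, optional
        Initial membrane potential (defaults to E_L).
    max_duration : float, optional
        Simulated-time budget in ms; a silent neuron raises
        :class:`SimulationTimeoutError` once it is exhausted.

    Returns
    -------
    EventSequence
        Output spike times (kind ``"spike"``), reported on the dt grid.
    """
    if n_output_intervals < 1:
        raise InvalidParameterError("n_output_intervals must be >= 1")
    dt = params.dt
    n_spikes_needed = n_output_intervals + 1

    in_times = input.times if input is not None and len(input) else np.empty(0)
    in_idx = np.rint(in_times / dt).astype(np.int64)

    if max_duration is None:
        try:
            per_spike = intrinsic_period(params)
        except BelowRheobaseError:
            mean_gap = float(np.mean(np.diff(in_times))) if in_times.size >= 2 else 1000.0
            per_spike = 10.0 * mean_gap
        max_duration = max(60_000.0, 25.0 * n_spikes_needed * per_spike)
    max_idx = int(math.ceil(max_duration / dt))

    prop = _Propagators(params)
    ref_steps = int(round(params.t_ref / dt))
    kick = params.w * math.e / params.tau_syn  # y1 increment per input event

    v = params.E_L if v_init is None else float(v_init)
    y1 = 0.0
    y2 = 0.0
    t_idx = 0
    ref_until = -1
    spikes: list[int] = []
    ev_pos = 0
    n_ev = in_idx.size

    while len(spikes) < n_spikes_needed:
        if t_idx >= max_idx:
            raise SimulationTimeoutError(
                f"only {max(len(spikes) - 1, 0)} of {n_output_intervals} output intervals "
                f"produced within {max_duration:.0f} ms"
            )
        # apply any input events landing exactly at the current grid point
        while ev_pos < n_ev and in_idx[ev_pos] == t_idx:
            y1 += kick
            ev_pos += 1
        next_ev = in_idx[ev_pos] if ev_pos < n_ev else max_idx
        seg_end = min(max(next_ev, t_idx + 1), t_idx + _BLOCK_STEPS, max_idx)

        if t_idx < ref_until:
            # potential clamped at V_reset; only the synaptic state evolves
            stop = min(seg_end, ref_until)
            _, y1, y2 = prop.advance(v, y1, y2, stop - t_idx)
            t_idx = stop
            continue

        k = seg_end - t_idx
        v_path, _, _ = _segment_potentials(v, y1, y2, k, prop)
        crossing = np.nonzero(v_path >= params.V_th)[0]
        if crossing.size:
            j = int(crossing[0])
            spike_idx = t_idx + j + 1
            spikes.append(spike_idx)
            # propagate synaptic state to the spike time, reset the membrane
            _, y1, y2 = prop.advance(v, y1, y2, j + 1)
            v = params.V_reset
            ref_until = spike_idx + ref_steps
            t_idx = spike_idx
        else:
            v, y1, y2 = prop.advance(v, y1, y2, k)
            t_idx = seg_end

    times = dt * np.asarray(spikes, dtype=float)
    return EventSequence(times=times, kind="spike")
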