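"""Clock-based LIF neuron with adaptive threshold and multiplicative STDP.

The membrane potential obeys tau dV/dt = -V + tau * sum_i w_i delta(t-t_i):
instantaneous synapses, so each input spike through weight w_i raises V by
w_i, and V decays exponentially otherwise.  Integration is forward Euler
with a 0.1 ms bin.

The firing threshold is adaptive: it jumps by a fixed multiple of its
baseline (1.8 * theta0) at each output spike and decays back toward theta0
with time constant tau_theta.  This discourages repeated firing to a single
pattern and is the mechanism that lets one neuron distribute itself over
several patterns.

Plasticity is all-to-all spike STDP with soft bounds.  A presynaptic trace
A_pre_i accumulates dA_pre at each spike of afferent i and decays with
tau_pre.  At each output spike, LTP applies w_i += w_i (1 - w_i) A_pre_i,
then a homeostatic LTD depresses every synapse: w_i += w_i (1 - w_i) w_out
with w_out < 0.  The multiplicative factor w(1-w) makes 0 and 1 fixed
points, so weights converge to binary values.

Two simulation paths are provided: :func:`step`/:func:`run_reference`, a
plain per-bin loop defining the semantics, and :class:`LIFNeuron`, a
vectorized implementation (linear-recurrence filtering between output
spikes) that matches the reference bin for bin and is fast enough for
hours of simulated time.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Optional

import numpy as np
from scipy.signal import lfilter

from .patterns import SpikeData

__all__ = [
    "NeuronConfig",
    "PlasticityConfig",
    "NeuronState",
    "SimulationResult",
    "step",
    "run_reference",
    "LIFNeuron",
    "trace_on_pre",
    "ltp_on_post",
    "ltd_on_post",
    "initial_weights",
]


@dataclass(frozen=True)
class NeuronConfig:
    """LIF and adaptive-threshold constants (times in ms).

    ``theta_jump_factor`` is the multiple of theta0 added to the threshold
    at each output spike; ``reset_potential`` controls whether V is set to
    0 after an output spike (the adaptive threshold, not the reset, is the
    anti-burst mechanism, so both variants are available).
    """

    tau: float
    theta0: float = 0.0
    theta_jump_factor: float = 1.8
    tau_theta: float = 80.0
    dt_sim: float = 0.1
    thresholded: bool = True
    reset_potential: bool = True

    def __post_init__(self) -> None:
        if self.tau <= 0:
            raise ValueError("tau must be > 0")
        if self.dt_sim <= 0:
            raise ValueError("dt_sim must be > 0")
        if self.thresholded and self.theta0 <= 0:
            raise ValueError("theta0 must be > 0 in thresholded mode")


@dataclass(frozen=True)
class PlasticityConfig:
    """STDP constants: trace increment/decay and the homeostatic LTD term."""

    dA_pre: float = 0.1
    tau_pre: float = 20.0
    w_out: float = -6.2e-3
    w_bounds: tuple[float, float] = (0.0, 1.0)

    def __post_init__(self) -> None:
        if self.dA_pre <= 0:
            raise ValueError("dA_pre must be > 0")
        if self.w_out >= 0:
            raise ValueError("w_out must be < 0 (depression)")
        if self.tau_pre <= 0:
            raise ValueError("tau_pre must be > 0")


@dataclass
class NeuronState:
    """Mutable simulation state: potential, threshold, traces, weights."""

    V: float
    theta: float
    w: np.ndarray
    A_pre: np.ndarray
    t: float = 0.0

    @classmethod
    def initial(cls, n_afferents: int, w0, config: NeuronConfig) -> "NeuronState":
        w = np.full(n_afferents, w0, dtype=float) if np.isscalar(w0) else np.asarray(w0, float).copy()
        return cls(V=0.0, theta=config.theta0, w=w, A_pre=np.zeros(n_afferents), t=0.0)


def trace_on_pre(state: NeuronState, afferent: int, plasticity: PlasticityConfig) -> None:
    """Increment the presynaptic trace of one afferent (all-to-all STDP:
    increments accumulate on top of the decayed trace, no reset)."""
    state.A_pre[afferent] += plasticity.dA_pre


def ltp_on_post(state: NeuronState, plasticity: PlasticityConfig) -> None:
    """Potentiate every synapse by its presynaptic trace, soft-bounded:
    w_i <- w_i + w_i (1 - w_i) A_pre_i."""
    w = state.w
    np.clip(w + w * (1.0 - w) * state.A_pre, *plasticity.w_bounds, out=w)


def ltd_on_post(state: NeuronState, plasticity: PlasticityConfig) -> None:
    """Depress every synapse by the homeostatic amount w_out < 0:
    w_i <- w_i + w_i (1 - w_i) w_out."""
    w = state.w
    np.clip(w + w * (1.0 - w) * plasticity.w_out, *plasticity.w_bounds, out=w)


def initial_weights(params, neuron: NeuronConfig) -> float:
    """Uniform initial weight putting the noise potential one sd above threshold.

    With all N afferents connected at weight w0, the noise-period moments
    scale as mean = w0 tau f N and sd = w0 sqrt(tau f N / 2); solving
    mean = theta0 + sd gives

        w0 = theta0 / (tau f N - sqrt(tau f N / 2)),

    clipped to [0, 1].  This starts the neuron firing at a few Hz so that
    STDP has postsynaptic spikes to work with.
    """
    tau_s = neuron.tau / 1000.0
    x = tau_s * params.f * params.N
    denom = x - np.sqrt(x / 2.0)
    if denom <= 0:
        raise ValueError("tau*f*N too small: noise mean does not exceed its sd")
    return float(np.clip(neuron.theta0 / denom, 0.0, 1.0))


def step(
    state: NeuronState,
    spike_afferents: np.ndarray,
    config: NeuronConfig,
    plasticity: Optional[PlasticityConfig] = None,
) -> bool:
    """Advance the neuron by one integration bin.

    Per-bin order: membrane decay, input jumps, threshold decay, trace
    decay + increments, threshold test; on an output spike: LTP, then LTD,
    then reset and threshold jump.  Returns True when an output spike was
    emitted in this bin.
    """
    dt = config.dt_sim
    spike_afferents = np.asarray(spike_afferents, dtype=np.int64)

    state.V *= 1.0 - dt / config.tau
    if spike_afferents.size:
        state.V += state.w[spike_afferents].sum()
    state.theta = config.theta0 + (state.theta - config.theta0) * (1.0 - dt / config.tau_theta)

    if plasticity is not None:
        state.A_pre *= np.exp(-dt / plasticity.tau_pre)
        for i in spike_afferents:
            trace_on_pre(state, i, plasticity)

    fired = False
    if config.thresholded and state.V >= state.theta:
        fired = True
        if plasticity is not None:
            ltp_on_post(state, plasticity)
            ltd_on_post(state, plasticity)
        if config.reset_potential:
            state.V = 0.0
        state.theta += config.theta_jump_factor * config.theta0

    state.t += dt
    return fired


def run_reference(
    stream: SpikeData,
    state: NeuronState,
    config: NeuronConfig,
    plasticity: Optional[PlasticityConfig] = None,
    record_potential: bool = False,
):
    """Bin-by-bin reference simulation (slow; used to pin down semantics)."""
    dt = config.dt_sim
    n_bins = int(round(stream.duration / dt))
    bins = np.minimum((stream.times / dt).astype(np.int64), n_bins - 1)
    spike_times: list[float] = []
    V_trace = np.empty(n_bins) if record_potential else None
    start = 0
    for b in range(n_bins):
        stop = np.searchsorted(bins, b, side="right")
        fired = step(state, stream.afferents[start:stop], config, plasticity)
        start = stop
        if fired:
            spike_times.append((b + 1) * dt)
        if record_potential:
            V_trace[b] = state.V
    return np.asarray(spike_times), V_trace


class SimulationResult(NamedTuple):
    """Output of a (possibly plastic) LIF run."""

    spike_times: np.ndarray
    weights: np.ndarray
    snapshot_times: np.ndarray
    weight_snapshots: np.ndarray
    V_trace: Optional[np.ndarray]


class LIFNeuron:
    """Vectorized clock-based LIF simulator.

    Between output spikes the membrane recurrence V[n] = a V[n-1] + J[n]
    (a = 1 - dt/tau, J the weighted input per bin) is linear, so whole
    stretches are evaluated with a scalar IIR filter; the adaptive
    threshold decays in closed form over the same stretch.  Only at output
    spikes are weights, traces and the threshold updated, after which
    filtering resumes.  This matches :func:`run_reference` bin for bin.
    """

    def __init__(self, config: NeuronConfig, plasticity: Optional[PlasticityConfig] = None):
        self.config = config
        self.plasticity = plasticity

    def run(
        self,
        stream: SpikeData,
        w0,
        record_potential: bool = False,
        snapshot_interval: float = 1000.0,
        state: Optional[NeuronState] = None,
    ) -> SimulationResult:
        """Simulate the full stream; ``w0`` is a scalar or per-afferent vector.

        Weight snapshots are taken every ``snapshot_interval`` ms when
        plasticity is enabled.  ``record_potential`` stores V for every bin
        (memory: one float per 0.1 ms).
        """
        cfg, plast = self.config, self.plasticity
        dt = cfg.dt_sim
        n_bins = int(round(stream.duration / dt))
        if state is None:
            state = NeuronState.initial(stream.n_afferents, w0, cfg)
        w = state.w
        alpha = 1.0 - dt / cfg.tau
        beta = 1.0 - dt / cfg.tau_theta

        bins = np.minimum((stream.times / dt).astype(np.int64), n_bins - 1)
        affs = stream.afferents

        spike_times: list[float] = []
        snap_times: list[float] = []
        snaps: list[np.ndarray] = []
        V_trace = np.empty(n_bins) if record_potential else None

        chunk_bins = max(1, int(round(snapshot_interval / dt)))
        # presynaptic trace is synced lazily: it is only needed at output spikes
        trace_bin = -1  # bin index up to which A_pre is current

        def sync_trace(to_bin: int) -> None:
            nonlocal trace_bin
            if plast is None or to_bin <= trace_bin:
                return
            decay = np.exp(-(to_bin - trace_bin) * dt / plast.tau_pre)
            state.A_pre *= decay
            lo = np.searchsorted(bins, trace_bin, side="right")
            hi = np.searchsorted(bins, to_bin, side="right")
            if hi > lo:
                contrib = plast.dA_pre * np.exp(-(to_bin - bins[lo:hi]) * dt / plast.tau_pre)
                np.add.at(state.A_pre, affs[lo:hi], contrib)
            trace_bin = to_bin

        for chunk_start in range(0, n_bins, chunk_bins):
            chunk_stop = min(chunk_start + chunk_bins, n_bins)
            b = chunk_start
            while b < chunk_stop:
                m = chunk_stop - b
                lo = np.searchsorted(bins, b, side="left")
                hi = np.searchsorted(bins, chunk_stop - 1, side="right")
                J = np.bincount(bins[lo:hi] - b, weights=w[affs[lo:hi]], minlength=m)
                V_seg = lfilter([1.0], [1.0, -alpha], J, zi=[alpha * state.V])[0]
                if not cfg.thresholded:
                    if record_potential:
                        V_trace[b:chunk_stop] = V_seg
                    state.V = V_seg[-1]
                    b = chunk_stop
                    break
                theta_seg = cfg.theta0 + (state.theta - cfg.theta0) * beta ** np.arange(1, m + 1)
                crossing = np.flatnonzero(V_seg >= theta_seg)
                if crossing.size == 0:
                    if record_potential:
                        V_trace[b:chunk_stop] = V_seg
                    state.V = V_seg[-1]
                    state.theta = theta_seg[-1]
                    b = chunk_stop
                    break
                k = int(crossing[0])
                if record_potential:
                    V_trace[b : b + k + 1] = V_seg[: k + 1]
                spike_times.append((b + k + 1) * dt)
                state.theta = theta_seg[k]
                if plast is not None:
                    sync_trace(b + k)
                    ltp_on_post(state, plast)
                    ltd_on_post(state, plast)
                state.V = 0.0 if cfg.reset_potential else V_seg[k]
                if record_potential:
                    V_trace[b + k] = state.V
                state.theta += cfg.theta_jump_factor * cfg.theta0
                b = b + k + 1
            if plast is not None:
                snap_times.append(chunk_stop * dt)
                snaps.append(w.copy())

        state.t = n_bins * dt
        return SimulationResult(
            spike_times=np.asarray(spike_times),
            weights=w,
            snapshot_times=np.asarray(snap_times),
            weight_snapshots=np.asarray(snaps) if snaps else np.empty((0, stream.n_afferents)),
            V_trace=V_trace,
        )
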