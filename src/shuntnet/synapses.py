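"""Spike-driven exponential synaptic conductances and spike-train utilities.

A presynaptic spike increments the conductance by the synaptic weight ``w``;
between spikes the conductance decays exponentially with time constant
``tau``.  The long-run mean under a stationary drive of rate r is
``w * tau * r`` (tau in seconds), the substitution used by the mean-field
reduction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import lfilter


@dataclass(frozen=True)
class SynapseParams:
    tau: float  # conductance time constant (ms)
    w: float    # conductance increment per presynaptic spike (nS)

    def __post_init__(self) -> None:
        if self.tau <= 0:
            raise ValueError("tau must be positive")
        if self.w < 0:
            raise ValueError("w must be non-negative")


@dataclass(frozen=True)
class SpikeTrain:
    """Sorted, non-negative spike times (ms) with an optional source id."""

    times: np.ndarray
    source: int | None = None

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        object.__setattr__(self, "times", times)
        if times.size and np.any(np.diff(times) < 0):
            raise ValueError("spike times must be sorted in increasing order")
        if times.size and times[0] < 0:
            raise ValueError("spike times must be non-negative")

    def __len__(self) -> int:
        return self.times.size

    def merged_with(self, other: "SpikeTrain") -> "SpikeTrain":
        return SpikeTrain(np.sort(np.concatenate([self.times, other.times])))


def evolve_conductance(
    g0: float,
    train: SpikeTrain,
    params: SynapseParams,
    duration: float,
    dt: float,
) -> np.ndarray:
    """Conductance trace on the grid 0, dt, ..., duration (length n+1, nS).

    The no-spike decay uses the exact per-step factor exp(-dt/tau), so a
    purely decaying trajectory carries no integrator error.  Spikes are
    binned to the grid: a spike in (t_{k-1}, t_k] (and any spike at exactly
    t = 0) raises the value at grid point k by ``w``; multiple spikes in one
    bin add k*w.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if g0 < 0:
        raise ValueError("g0 must be non-negative")
    times = train.times
    if times.size and (times[-1] > duration):
        raise ValueError("spike train extends beyond duration")
    n = int(round(duration / dt))
    impulses = np.zeros(n + 1)
    impulses[0] = g0
    if times.size:
        idx = np.ceil(times / dt - 1e-12).astype(int)  # t = 0 lands on grid point 0
        np.add.at(impulses, np.clip(idx, 0, n), params.w)
    decay = np.exp(-dt / params.tau)
    # first-order recursion g[k] = decay*g[k-1] + impulses[k]
    g = lfilter([1.0], [1.0, -decay], impulses)
    return g


def poisson_spike_train(
    rate: float,
    duration: float,
    seed: int | np.random.Generator | None = None,
) -> SpikeTrain:
    """Homogeneous Poisson spike train on [0, duration) (rate in Hz, duration in ms)."""
    if rate < 0:
        raise ValueError("rate must be non-negative")
    if duration < 0:
        raise ValueError("duration must be non-negative")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    count = rng.poisson(rate * duration / 1000.0)
    times = np.sort(rng.uniform(0.0, duration, size=count))
    return SpikeTrain(times)
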