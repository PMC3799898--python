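"""Synaptic machinery: double-exponential receptors, NMDA Mg block,
delayed event delivery and Poisson background sources.

Receptor conductances follow the standard double-exponential kinetic

    g(t) = gmax * N * (exp(-t/tau2) - exp(-t/tau1)),   0 < tau1 < tau2,

with N chosen so the peak equals gmax. Because the kinetics are linear,
overlapping events superpose exactly; the engine keeps two decaying state
variables per receptor channel and increments both on each delivery. All
cell-to-cell events are delivered with a fixed 2 ms delay standing in for
axonal propagation and transmitter diffusion.
"""

from __future__ import annotations

import heapq
import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SynapseSpec",
    "PoissonSource",
    "EventQueue",
    "biexp_norm",
    "biexp_peak_time",
    "biexp_conductance",
    "nmda_block",
    "poisson_train",
]

DELAY_MS = 2.0  # uniform cell-to-cell synaptic delay


@dataclass(frozen=True)
class SynapseSpec:
    """One receptor: rise/decay times (ms), peak conductance (nS), reversal (mV)."""

    receptor: str
    tau1: float
    tau2: float
    gmax: float
    e_rev: float
    target: str = "soma"
    delay: float = DELAY_MS

    def __post_init__(self) -> None:
        if not 0 < self.tau1 < self.tau2:
            raise ValueError("need 0 < tau1 < tau2")
        if self.gmax < 0:
            raise ValueError("gmax must be >= 0")


@dataclass(frozen=True)
class PoissonSource:
    """A stationary Poisson event source driving one receptor channel."""

    rate: float          # Hz
    receptor: str
    gmax: float          # nS
    target: str = "soma"
    stream: tuple = (0, "background")

    def __post_init__(self) -> None:
        if self.rate <= 0:
            raise ValueError("rate must be > 0")


def biexp_peak_time(tau1: float, tau2: float) -> float:
    """Time of the conductance maximum: tau1*tau2/(tau2-tau1) * ln(tau2/tau1)."""
    return tau1 * tau2 / (tau2 - tau1) * math.log(tau2 / tau1)


def biexp_norm(tau1: float, tau2: float) -> float:
    """Normalization so that max_t (exp(-t/tau2) - exp(-t/tau1)) / N^-1 = 1."""
    tp = biexp_peak_time(tau1, tau2)
    return 1.0 / (math.exp(-tp / tau2) - math.exp(-tp / tau1))


def biexp_conductance(t_since_event, spec: SynapseSpec):
    """Conductance (nS) ``t_since_event`` ms after a single event; 0 for t < 0."""
    t = np.asarray(t_since_event, dtype=float)
    n = biexp_norm(spec.tau1, spec.tau2)
    out = spec.gmax * n * (np.exp(-t / spec.tau2) - np.exp(-t / spec.tau1))
    out = np.where(t >= 0.0, out, 0.0)
    return out if out.ndim else float(out)


def nmda_block(v, mg_mM: float = 1.0, eta: float = 0.28, gamma: float = 0.062):
    """Voltage-dependent Mg2+ relief factor of the NMDA receptor.

    The Jahr-Stevens form 1 / (1 + eta * [Mg] * exp(-gamma * v)); in (0, 1],
    increasing with depolarization, exactly 1 at zero magnesium.
    """
    if mg_mM < 0:
        raise ValueError("mg_mM must be >= 0")
    v = np.asarray(v, dtype=float)
    out = 1.0 / (1.0 + eta * mg_mM * np.exp(-gamma * v))
    return out if out.ndim else float(out)


def poisson_train(rate: float, duration: float, stream) -> np.ndarray:
    """Event times (ms) of a Poisson process on [0, duration) ms.

    ``rate`` is in Hz. ``stream`` seeds the generator: equal streams give
    identical trains (the engine uses (cell id, source kind) pairs so input
    randomizations switch independently of wiring).
    """
    if rate <= 0:
        raise ValueError("rate must be > 0")
    rng = np.random.default_rng(np.random.SeedSequence(_stream_entropy(stream)))
    mean_iei = 1000.0 / rate  # ms
    n_guess = max(16, int(duration / mean_iei * 1.5) + 32)
    times = []
    t = 0.0
    while True:
        chunk = np.cumsum(rng.exponential(mean_iei, size=n_guess)) + t
        inside = chunk[chunk < duration]
        times.append(inside)
        if len(inside) < n_guess:
            break
        t = chunk[-1]
    return np.concatenate(times)


def _stream_entropy(stream) -> list[int]:
    """Map an arbitrary hashable stream id to SeedSequence entropy."""
    if isinstance(stream, (int, np.integer)):
        return [int(stream) & 0x7FFFFFFF]
    if isinstance(stream, (tuple, list)):
        out = []
        for part in stream:
            if isinstance(part, (int, np.integer)):
                out.append(int(part) & 0x7FFFFFFF)
            else:
                out.append(hash(str(part)) & 0x7FFFFFFF)
        return out
    return [hash(str(stream)) & 0x7FFFFFFF]


@dataclass
class EventQueue:
    """Time-ordered delivery queue of (delivery time, synapse id) pairs.

    ``push`` schedules an emission: the event is stored at
    emission time + delay. ``pop_until`` removes and returns every event due
    by the given time, in order; no event is lost or duplicated.
    """

    _heap: list = field(default_factory=list)
    _counter: int = 0

    def push(self, emission_time: float, synapse_id, delay: float = DELAY_MS) -> None:
        heapq.heappush(self._heap, (emission_time + delay, self._counter, synapse_id))
        self._counter += 1

    def pop_until(self, now: float) -> list[tuple[float, object]]:
        out = []
        while self._heap and self._heap[0][0] <= now:
            t, _, sid = heapq.heappop(self._heap)
            out.append((t, sid))
        return out

    def __len__(self) -> int:
        return len(self._heap)
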