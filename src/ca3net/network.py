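"""Network assembly and simulation: fixed-convergence random wiring, the
full-network driver, the dipole LFP and population statistics.

Wiring follows fixed convergences (a constant number of presynaptic inputs
per postsynaptic cell for each projection, sampled without replacement, no
self-edges), so divergence varies randomly. The local field potential proxy
is the sum over pyramidal cells of the membrane-potential difference
between the most distal apical and the basal dendritic compartment.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .model import EngineSpec, PROJECTIONS, RawResult, run_engine
from .params import load_parameters, scaled_populations

__all__ = [
    "NetworkConfig",
    "Wiring",
    "SimResult",
    "wire_network",
    "run_network",
    "compute_lfp",
    "prepare_lfp",
    "population_rates",
]


@dataclass(frozen=True)
class NetworkConfig:
    """Declarative description of one network simulation.

    ``ih_scales`` maps each cell class to its neuromodulation factor s
    (baseline 1.0). ``population_scale`` shrinks all populations
    proportionally for desk-scale runs while keeping convergences — and so
    per-cell input statistics — fixed.
    """

    ih_scales: dict = field(default_factory=lambda: {"PYR": 1.0, "BAS": 1.0, "OLM": 1.0})
    wiring_seed: int = 0
    input_seed: int = 0
    duration_ms: float = 8000.0
    dt: float | None = None
    population_scale: float = 1.0
    background: bool = True
    synapses: bool = True
    param_file: str | None = None

    def load(self) -> dict:
        params = load_parameters(self.param_file)
        if self.population_scale != 1.0:
            params = scaled_populations(params, self.population_scale)
        return params

    def with_scales(self, **scales) -> "NetworkConfig":
        new = dict(self.ih_scales)
        new.update(scales)
        return replace(self, ih_scales=new)


@dataclass(frozen=True)
class Wiring:
    """Realized edge lists, as per-projection CSR keyed by presynaptic cell."""

    csr: dict          # (pre, post) -> (indptr, targets)
    convergence: dict  # (pre, post) -> inputs per postsynaptic cell
    populations: dict

    @property
    def n_synapses(self) -> int:
        """Total synapse count: AMPA/NMDA pairs at one contact count as two."""
        total = 0
        for (pre, post), (indptr, tgt) in self.csr.items():
            n_receptors = self._receptors_per_contact.get((pre, post), 1)
            total += len(tgt) * n_receptors
        return total

    _receptors_per_contact = {
        ("PYR", "PYR"): 2, ("PYR", "BAS"): 2, ("PYR", "OLM"): 2,
        ("BAS", "PYR"): 1, ("BAS", "BAS"): 1, ("OLM", "PYR"): 1,
    }

    def in_degrees(self, pre: str, post: str) -> np.ndarray:
        indptr, tgt = self.csr[(pre, post)]
        n_post = self.populations[post]
        return np.bincount(tgt, minlength=n_post)


def wire_network(config: NetworkConfig, params: dict | None = None) -> Wiring:
    """Sample the fixed-convergence random wiring for ``config``.

    Deterministic given the wiring seed; each postsynaptic cell draws its
    convergence-many presynaptic partners without replacement, excluding
    itself for recurrent projections.
    """
    if params is None:
        params = config.load()
    rng = np.random.default_rng(config.wiring_seed)
    pops = params["populations"]
    conv = {}
    for row in params["synapses"]:
        key = (row["pre"], row["post"])
        if key in conv and conv[key] != row["convergence"]:
            raise ValueError(f"inconsistent convergence for projection {key}")
        conv[key] = row["convergence"]
    csr = {}
    for (pre, post) in PROJECTIONS:
        n_pre, n_post = pops[pre], pops[post]
        c = conv[(pre, post)]
        pre_of_post = np.empty((n_post, c), dtype=np.int64)
        all_pre = np.arange(n_pre)
        for j in range(n_post):
            if pre == post:
                candidates = np.delete(all_pre, j)
            else:
                candidates = all_pre
            pre_of_post[j] = rng.choice(candidates, size=c, replace=False)
        # invert to CSR by presynaptic cell
        pre_ids = pre_of_post.ravel()
        post_ids = np.repeat(np.arange(n_post), c)
        order = np.argsort(pre_ids, kind="stable")
        targets = post_ids[order]
        counts = np.bincount(pre_ids, minlength=n_pre)
        indptr = np.zeros(n_pre + 1, dtype=np.int64)
        np.cumsum(counts, out=indptr[1:])
        csr[(pre, post)] = (indptr, targets)
    return Wiring(csr=csr, convergence=conv, populations=dict(pops))


@dataclass(frozen=True)
class SimResult:
    """Spikes, soma traces and the dipole LFP of one network run."""

    config: NetworkConfig
    raw: RawResult
    populations: dict

    @property
    def lfp(self) -> np.ndarray:
        return self.raw.lfp

    @property
    def t(self) -> np.ndarray:
        return self.raw.t_rec

    @property
    def fs(self) -> float:
        """LFP sampling rate, Hz."""
        return 1000.0 / self.raw.dt_rec

    def spike_trains(self, kind: str) -> tuple[np.ndarray, np.ndarray]:
        """(cell ids, spike times in ms) of one population."""
        return self.raw.spikes[kind]


def run_network(config: NetworkConfig, wiring: Wiring | None = None,
                record: list | None = None) -> SimResult:
    """Simulate the network described by ``config``.

    Reproducible given (wiring seed, input seed). Aborts with a diagnostic
    if the integration produces non-finite state.
    """
    params = config.load()
    if wiring is None and config.synapses:
        wiring = wire_network(config, params)
    dt = config.dt if config.dt is not None else params["simulation"]["dt"]
    rec_every = max(1, int(round(params["simulation"]["lfp_sample_ms"] / dt)))
    spec = EngineSpec(
        params=params,
        n=dict(params["populations"]),
        scales=dict(config.ih_scales),
        wiring=wiring.csr if wiring is not None else None,
        background=config.background,
    )
    raw = run_engine(spec, config.duration_ms, dt, config.input_seed,
                     rec_every=rec_every, record=record)
    if raw.failed:
        raise FloatingPointError(
            f"integration failure (non-finite state) at t = {raw.fail_time:.3f} ms")
    return SimResult(config=config, raw=raw, populations=dict(params["populations"]))


def compute_lfp(result: SimResult) -> np.ndarray:
    """Raw LFP: summed (distal apical - basal) PYR membrane-potential series."""
    return result.raw.lfp


def prepare_lfp(lfp: np.ndarray, fs: float, trim_ms: float = 200.0) -> np.ndarray:
    """Trim ``trim_ms`` from both ends and remove the DC component.

    This is the preprocessing applied before any spectral or coupling
    analysis; endpoint trimming avoids initialization and edge artifacts.
    """
    lfp = np.asarray(lfp, dtype=float)
    k = int(round(trim_ms * fs / 1000.0))
    if 2 * k >= len(lfp):
        raise ValueError("series shorter than twice the trim window")
    out = lfp[k: len(lfp) - k]
    return out - np.mean(out)


def population_rates(result: SimResult, kind: str | None = None,
                     trim_ms: float = 200.0):
    """Mean firing rate (Hz) per population over the trimmed window."""
    if kind is None:
        return {k: population_rates(result, k, trim_ms)
                for k in ("PYR", "BAS", "OLM")}
    ids, times = result.raw.spikes[kind]
    t_end = result.config.duration_ms
    mask = (times >= trim_ms) & (times < t_end - trim_ms)
    n_cells = result.populations[kind]
    window_s = (t_end - 2 * trim_ms) / 1000.0
    if n_cells == 0 or window_s <= 0:
        return 0.0
    return float(np.sum(mask) / (n_cells * window_s))
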