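"""Compartmental cell models and isolated-cell protocols.

The three cell classes:

* **PYR** — five compartments (soma, basal dendrite, three apical levels
  proximal to distal) with leak, transient Na and delayed-rectifier K in the
  soma, A-type K and a slow HCN2-like Ih in every compartment, and a +50 pA
  tonic somatic injection.
* **BAS** — one compartment with leak, Na, K-dr and a fast HCN1-like Ih.
* **OLM** — one compartment adding an L-type Ca current, a Ca-activated K
  current with a first-order intracellular Ca pool, a mixed-isoform Ih with
  depolarized reversal (-40 mV), and a -25 pA tonic injection.

Isolated-cell protocols run a single cell with network synapses and
background off (tonic injections retained, as in the network configuration)
for 7 s to steady state; postsynaptic potentials are probed with a single
0.5 nS conductance event at 5.5 s.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import EngineSpec, PYR_COMPARTMENTS, RawResult, run_engine
from .params import load_parameters

__all__ = [
    "CellModel",
    "build_cell",
    "run_isolated",
    "measure_rmp",
    "measure_psp",
    "detect_spikes",
    "freeze_ih",
    "RMPResult",
    "PSPResult",
]

STEADY_STATE_MS = 7000.0
PSP_STIM_MS = 5500.0
PSP_GMAX_NS = 0.5
PSP_WINDOW_MS = 300.0
PSP_BASELINE_MS = 100.0


@dataclass(frozen=True)
class CellModel:
    """A cell class instance: compartments, channel inventory, Ih scale."""

    kind: str
    compartments: tuple
    channels: dict            # compartment name -> tuple of channel names
    inj_pA: float
    ih_scale: float

    @property
    def n_compartments(self) -> int:
        return len(self.compartments)


def build_cell(kind: str, ih_scale: float = 1.0,
               params: dict | None = None) -> CellModel:
    """Construct the channel inventory of one cell class.

    All classes carry leak, transient Na and delayed-rectifier K; PYR adds
    A-type K and Ih in every compartment; BAS adds Ih; OLM adds the L-type
    Ca / KCa pair, the Ca pool and Ih.
    """
    if kind not in ("PYR", "BAS", "OLM"):
        raise ValueError(f"unknown cell kind {kind!r}")
    if ih_scale < 0:
        raise ValueError("ih_scale must be >= 0")
    if params is None:
        params = load_parameters()
    cell = params["cells"][kind]
    comps = tuple(c["name"] for c in cell["compartments"])
    channels = {}
    for c in cell["compartments"]:
        names = ["leak"]
        if c["gna"] > 0:
            names.append("Na_t")
        if c["gkdr"] > 0:
            names.append("K_dr")
        if c["gka"] > 0:
            names.append("K_A")
        if c.get("gcal", 0) > 0:
            names.append("Ca_L")
        if c.get("gkca", 0) > 0:
            names.append("K_Ca")
        if c.get("ih", 0) > 0:
            names.append("Ih")
        channels[c["name"]] = tuple(names)
    return CellModel(kind=kind, compartments=comps, channels=channels,
                     inj_pA=cell["inj_pA"], ih_scale=ih_scale)


def run_isolated(kind: str, ih_scale: float, duration_ms: float = STEADY_STATE_MS,
                 *, params: dict | None = None, dt: float | None = None,
                 events: list | None = None, na_block: bool = False,
                 ih_static: bool = False, gfix: np.ndarray | None = None,
                 rec_every: int = 4, input_seed: int = 0) -> RawResult:
    """Simulate one isolated cell (no synapses, no background).

    ``events`` is a list of (t_ms, receptor, gmax_nS) somatic conductance
    events. ``gfix`` (S/cm2 per compartment) replaces the dynamic Ih when
    ``ih_static`` is set.
    """
    if params is None:
        params = load_parameters()
    if dt is None:
        dt = params["simulation"]["dt"]
    spec = EngineSpec(
        params=params,
        n={kind: 1},
        scales={kind: ih_scale},
        na_block={kind: na_block},
        ih_static={kind: ih_static},
        background=False,
    )
    if gfix is not None:
        spec.gfix[kind] = np.atleast_2d(np.asarray(gfix, dtype=float))
    for (t, receptor, gmax) in events or []:
        spec.events.append((t, kind, 0, "soma", receptor, gmax))
    return run_engine(spec, duration_ms, dt, input_seed, rec_every=rec_every)


@dataclass(frozen=True)
class RMPResult:
    kind: str
    ih_scale: float
    rmp_mV: float
    transient_spikes: int
    rhythmic: bool
    firing_hz: float


def measure_rmp(kind: str, ih_scale: float, *, params: dict | None = None,
                duration_ms: float = STEADY_STATE_MS,
                dt: float | None = None) -> RMPResult:
    """Resting potential of the isolated cell after ``duration_ms``.

    If spiking persists through the final 5 s the cell is flagged rhythmic
    and the mean firing frequency over that window is reported instead of a
    settled RMP (the final voltage is still returned).
    """
    res = run_isolated(kind, ih_scale, duration_ms, params=params, dt=dt,
                       rec_every=40)
    _, times = res.spikes[kind]
    tail_start = duration_ms - 5000.0
    tail = times[times >= tail_start]
    rhythmic = len(tail) >= 5
    firing = len(tail) / 5.0 if rhythmic else 0.0
    return RMPResult(
        kind=kind,
        ih_scale=ih_scale,
        rmp_mV=float(res.vrec[-1, 0]),
        transient_spikes=int(len(times) - len(tail)),
        rhythmic=rhythmic,
        firing_hz=firing,
    )


@dataclass(frozen=True)
class PSPResult:
    kind: str
    ih_scale: float
    receptor: str
    static_ih: bool
    amplitude_mV: float
    time_to_peak_ms: float
    measurable: bool


def measure_psp(kind: str, ih_scale: float, receptor: str, *,
                static_ih: bool = False, na_block: bool = False,
                params: dict | None = None, dt: float | None = None) -> PSPResult:
    """Somatic PSP amplitude and delay for a single 0.5 nS input at 5.5 s.

    Amplitude is the extremum deviation from the 100 ms pre-stimulus
    baseline; time-to-peak is measured from the stimulus. A spike in the
    measurement window marks the result unmeasurable. With ``static_ih``
    the dynamic Ih is replaced by the fixed conductance it had reached at
    steady state at the same scale (measured from a dynamic run).
    """
    if receptor not in ("AMPA", "GABA_A"):
        raise ValueError("receptor must be AMPA or GABA_A")
    gfix = None
    if static_ih:
        gfix = freeze_ih(kind, ih_scale, params=params, dt=dt)
    res = run_isolated(
        kind, ih_scale, params=params, dt=dt,
        events=[(PSP_STIM_MS, receptor, PSP_GMAX_NS)],
        na_block=na_block, ih_static=static_ih, gfix=gfix,
    )
    t = res.t_rec
    v = res.vrec[:, 0]
    pre = (t >= PSP_STIM_MS - PSP_BASELINE_MS) & (t < PSP_STIM_MS)
    win = (t >= PSP_STIM_MS) & (t <= PSP_STIM_MS + PSP_WINDOW_MS)
    baseline = float(np.mean(v[pre]))
    dev = v[win] - baseline
    _, times = res.spikes[kind]
    spike_in_win = np.any(
        (times >= PSP_STIM_MS - PSP_BASELINE_MS)
        & (times <= PSP_STIM_MS + PSP_WINDOW_MS))
    if spike_in_win:
        return PSPResult(kind, ih_scale, receptor, static_ih,
                         float("nan"), float("nan"), False)
    # depolarizing for excitatory input, hyperpolarizing for inhibitory
    idx = int(np.argmax(dev)) if receptor == "AMPA" else int(np.argmin(dev))
    return PSPResult(
        kind=kind,
        ih_scale=ih_scale,
        receptor=receptor,
        static_ih=static_ih,
        amplitude_mV=float(abs(dev[idx])),
        time_to_peak_ms=float(t[win][idx] - PSP_STIM_MS),
        measurable=True,
    )


def freeze_ih(kind: str, ih_scale: float, *, params: dict | None = None,
              dt: float | None = None,
              duration_ms: float = STEADY_STATE_MS) -> np.ndarray:
    """Per-compartment static Ih conductance (S/cm2) at steady state.

    Runs the isolated cell for ``duration_ms`` with dynamic Ih and returns
    g_fix = ghbar * scale * h(end) per compartment, for use as the frozen
    substitution. At scale 0 the result is identically zero.
    """
    if params is None:
        params = load_parameters()
    res = run_isolated(kind, ih_scale, duration_ms, params=params, dt=dt,
                       rec_every=400)
    h_end = res.final_h[kind][0]
    ghbar = params["ih"][kind]["ghbar"]
    per_comp = np.array([
        ghbar * comp.get("ih", 0.0) * ih_scale * h
        for comp, h in zip(params["cells"][kind]["compartments"], h_end)
    ])
    return per_comp


def detect_spikes(voltage: np.ndarray, dt: float,
                  thresh: float = 0.0, refractory_ms: float = 1.0) -> np.ndarray:
    """Spike times (ms) as upward threshold crossings with a dead time."""
    v = np.asarray(voltage, dtype=float)
    if not np.all(np.isfinite(v)):
        raise ValueError("voltage trace contains non-finite values")
    up = np.flatnonzero((v[:-1] < thresh) & (v[1:] >= thresh)) + 1
    times = up * dt
    if len(times) == 0:
        return times
    kept = [times[0]]
    for t in times[1:]:
        if t - kept[-1] >= refractory_ms:
            kept.append(t)
    return np.asarray(kept)


def compartment_names(kind: str) -> tuple:
    return PYR_COMPARTMENTS if kind == "PYR" else ("soma",)
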