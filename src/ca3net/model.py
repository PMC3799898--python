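"""Assembly of engine arrays from the parameter file, and the shared
simulation driver used by both the isolated-cell protocols and the network.

Nothing here is part of the public API except :class:`RawResult`; use
:mod:`ca3net.cells` and :mod:`ca3net.network` instead.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import _engine as eng
from .synapses import biexp_norm

PYR_COMPARTMENTS = ("soma", "Bdend", "Adend1", "Adend2", "Adend3")
# parent of each compartment in the PYR cable (soma at index 0)
PYR_PARENT = (-1, 0, 0, 2, 3)
POP_INDEX = {"PYR": 0, "BAS": 1, "OLM": 2}

# receptor channel tables: (compartment index, receptor, tau1 key)
# taus/reversals are filled in from the parameter file at assembly time.
PYR_CHANNELS = (
    (0, "AMPA"), (0, "GABA_A"),
    (1, "AMPA"), (1, "GABA_A"),
    (2, "AMPA"), (2, "GABA_A"),
    (3, "AMPA"), (3, "GABA_A"),
    (4, "AMPA"), (4, "GABA_A"),
    (4, "GABA_A_slow"),
    (1, "NMDA"), (4, "NMDA"),
)
UNIT_CHANNELS = ((0, "AMPA"), (0, "GABA_A"), (0, "NMDA"))

# canonical receptor kinetics; GABA_A_slow is the OLM->PYR dendritic receptor
RECEPTOR_TAUS = {
    "AMPA": (0.05, 5.3),
    "NMDA": (15.0, 150.0),
    "GABA_A": (0.07, 9.1),
    "GABA_A_slow": (0.2, 20.0),
}

# projections in engine order; channel names resolve against the tables above
PROJECTIONS = (
    ("PYR", "PYR"), ("PYR", "BAS"), ("PYR", "OLM"),
    ("BAS", "PYR"), ("BAS", "BAS"), ("OLM", "PYR"),
)


def _compartment_geometry(comp: dict, ra: float):
    """Area (cm2) and half-cable axial resistance (ohm) of one cylinder."""
    L_cm = comp["L"] * 1e-4
    d_cm = comp["diam"] * 1e-4
    area = math.pi * d_cm * L_cm
    r_half = ra * (L_cm / 2.0) / (math.pi * (d_cm / 2.0) ** 2)
    return area, r_half


def _pack_pop(params: dict, kind: str, scale: float, *, na_block=False,
              ih_static=False) -> tuple[np.ndarray, np.ndarray]:
    cell = params["cells"][kind]
    ih = params["ih"][kind]
    kin = params["kinetics"]
    P = np.zeros(eng.NP)
    P[eng.P_CM] = cell["cm"]
    P[eng.P_EL] = cell["e_leak"]
    P[eng.P_ENA] = kin["na"]["e_rev"]
    P[eng.P_EK] = kin["kdr"]["e_rev"]
    P[eng.P_PHI] = kin["na"]["phi"]
    P[eng.P_EH] = ih["e_rev"]
    P[eng.P_VHALF] = ih["v_half"]
    P[eng.P_KSLOPE] = ih["k"]
    P[eng.P_TAMP] = ih["tau_amp"]
    P[eng.P_TVC] = ih["tau_vc"]
    P[eng.P_TSIG] = ih["tau_sigma"]
    P[eng.P_TMIN] = ih["tau_min"]
    P[eng.P_INJ] = cell["inj_pA"]  # pA; engine converts to mA via 1e-9
    P[eng.P_IHSCALE] = scale
    P[eng.P_NABLOCK] = 1.0 if na_block else 0.0
    P[eng.P_IHSTATIC] = 1.0 if ih_static else 0.0
    P[eng.P_KATAUA] = kin["ka"]["tau_a"]
    P[eng.P_KATAUB] = kin["ka"]["tau_b"]
    P[eng.P_ECA] = kin["cal"]["e_rev"]
    P[eng.P_CALTAUM] = kin["cal"]["tau_m"]
    P[eng.P_KD] = kin["kca"]["kd"]
    P[eng.P_CA0] = kin["ca_pool"]["ca0"]
    P[eng.P_TAUCA] = kin["ca_pool"]["tau"]
    P[eng.P_FIN] = kin["ca_pool"]["f_in"]
    P[eng.P_MG] = kin["nmda_mg"]["mg"]
    P[eng.P_ETA] = kin["nmda_mg"]["eta"]
    P[eng.P_GAMMA] = kin["nmda_mg"]["gamma"]
    P[eng.P_NASHIFT] = cell.get("na_shift", 0.0)
    P[eng.P_KSHIFT] = cell.get("kdr_shift", 0.0)
    P[eng.P_NAHSHIFT] = cell.get("na_h_shift", 0.0)

    comps = cell["compartments"]
    C = np.zeros((len(comps), eng.NC))
    for c, comp in enumerate(comps):
        area, _ = _compartment_geometry(comp, cell["ra"])
        C[c, eng.C_AREA] = area
        C[c, eng.C_GL] = comp["g_leak"]
        C[c, eng.C_GNA] = comp["gna"]
        C[c, eng.C_GKDR] = comp["gkdr"]
        C[c, eng.C_GKA] = comp["gka"]
        C[c, eng.C_GHBAR] = ih["ghbar"] * comp.get("ih", 0.0)
        C[c, eng.C_GCAL] = comp.get("gcal", 0.0)
        C[c, eng.C_GKCA] = comp.get("gkca", 0.0)
    return P, C


def _pyr_adjacency(params: dict):
    cell = params["cells"]["PYR"]
    comps = cell["compartments"]
    n = len(comps)
    halves = [_compartment_geometry(c, cell["ra"])[1] for c in comps]
    neighbors: list[list[tuple[int, float]]] = [[] for _ in range(n)]
    for c, par in enumerate(PYR_PARENT):
        if par < 0:
            continue
        g = 1.0 / (halves[c] + halves[par])  # S
        neighbors[c].append((par, g))
        neighbors[par].append((c, g))
    max_deg = max(len(nb) for nb in neighbors)
    adj_idx = np.zeros((n, max_deg), dtype=np.int64)
    adj_g = np.zeros((n, max_deg))
    deg = np.zeros(n, dtype=np.int64)
    for c, nb in enumerate(neighbors):
        deg[c] = len(nb)
        for a, (j, g) in enumerate(nb):
            adj_idx[c, a] = j
            adj_g[c, a] = g
    return adj_idx, adj_g, deg


def _channel_arrays(layout, reversal: dict, dt: float):
    K = len(layout)
    comp = np.zeros(K, dtype=np.int64)
    d1 = np.zeros(K)
    d2 = np.zeros(K)
    E = np.zeros(K)
    nmda = np.zeros(K, dtype=np.int64)
    norm = np.zeros(K)
    for k, (c, receptor) in enumerate(layout):
        tau1, tau2 = RECEPTOR_TAUS[receptor]
        comp[k] = c
        d1[k] = math.exp(-dt / tau1)
        d2[k] = math.exp(-dt / tau2)
        base = receptor.replace("_slow", "")
        E[k] = reversal[base]
        nmda[k] = 1 if base == "NMDA" else 0
        norm[k] = biexp_norm(tau1, tau2)
    return comp, d1, d2, E, nmda, norm


def channel_index(kind: str, target: str, receptor: str) -> int:
    """Engine channel index for a (cell kind, compartment, receptor) triple."""
    if kind == "PYR":
        layout = PYR_CHANNELS
        c = PYR_COMPARTMENTS.index(target)
        if receptor == "GABA_A" and target == "Adend3":
            receptor = "GABA_A_slow"
    else:
        layout = UNIT_CHANNELS
        c = 0
    for k, (cc, rr) in enumerate(layout):
        if cc == c and rr == receptor:
            return k
    raise KeyError(f"no channel for {kind}/{target}/{receptor}")


@dataclass
class RawResult:
    """Output of one engine run (times in ms)."""

    dt: float
    dt_rec: float
    t_rec: np.ndarray
    lfp: np.ndarray                      # summed PYR dipole (distal apical - basal), mV
    vrec: np.ndarray                     # (n_samples, n_recorded)
    rec_labels: list
    spikes: dict                         # kind -> (ids, times)
    n_cells: dict
    final_V: dict
    final_h: dict
    failed: bool = False
    fail_time: float = float("nan")


@dataclass
class EngineSpec:
    """Everything the kernel needs, pre-assembly. Built by cells/network."""

    params: dict
    n: dict                              # kind -> population size
    scales: dict = field(default_factory=lambda: {"PYR": 1.0, "BAS": 1.0, "OLM": 1.0})
    na_block: dict = field(default_factory=dict)       # kind -> bool
    ih_static: dict = field(default_factory=dict)      # kind -> bool
    gfix: dict = field(default_factory=dict)           # kind -> (n, ncomp) S/cm2
    wiring: dict | None = None           # projection -> (indptr, targets, wA, wB)
    background: bool = True
    events: list = field(default_factory=list)         # (t_ms, kind, cell, target, receptor, gmax)
    init_V: dict = field(default_factory=dict)         # kind -> scalar or array


def run_engine(spec: EngineSpec, duration_ms: float, dt: float,
               input_seed: int, rec_every: int = 40,
               record: list | None = None) -> RawResult:
    """Integrate the model and collect spikes, traces and the dipole LFP.

    ``record`` is a list of (kind, cell, compartment) voltage probes; by
    default the soma of cell 0 of each non-empty population is recorded.
    """
    params = spec.params
    n_steps = int(round(duration_ms / dt))
    delay_steps = int(round(params["synaptic_delay_ms"] / dt))
    reversal = params["reversal"]

    packs = {}
    for kind in ("PYR", "BAS", "OLM"):
        packs[kind] = _pack_pop(
            params, kind, spec.scales.get(kind, 1.0),
            na_block=spec.na_block.get(kind, False),
            ih_static=spec.ih_static.get(kind, False),
        )
    adj_idx, adj_g, deg = _pyr_adjacency(params)

    chans = {
        "PYR": _channel_arrays(PYR_CHANNELS, reversal, dt),
        "BAS": _channel_arrays(UNIT_CHANNELS, reversal, dt),
        "OLM": _channel_arrays(UNIT_CHANNELS, reversal, dt),
    }

    n = {k: int(spec.n.get(k, 0)) for k in ("PYR", "BAS", "OLM")}
    ncomp = {"PYR": 5, "BAS": 1, "OLM": 1}

    V, H, state = {}, {}, {}
    for kind in ("PYR", "BAS", "OLM"):
        P, C = packs[kind]
        v0 = spec.init_V.get(kind, P[eng.P_EL])
        V[kind] = np.full((n[kind], ncomp[kind]), float(v0))
        # gates at steady state for v0
        ih = params["ih"][kind]
        h0 = 1.0 / (1.0 + math.exp((float(v0) - ih["v_half"]) / ih["k"]))
        H[kind] = np.full((n[kind], ncomp[kind]), h0)

    from .channels import na_h_rates, kdr_n_rates, ka_inf, cal_m_inf

    def _init_scalar(kind, fn):
        P, _ = packs[kind]
        v0 = float(spec.init_V.get(kind, P[eng.P_EL]))
        return np.full(n[kind], fn(v0))

    def _shift(kind, idx):
        return packs[kind][0][idx]

    pyr_nah = _init_scalar("PYR", lambda v: na_h_rates(v - _shift("PYR", eng.P_NASHIFT) - _shift("PYR", eng.P_NAHSHIFT))[0])
    pyr_kn = _init_scalar("PYR", lambda v: kdr_n_rates(v - _shift("PYR", eng.P_KSHIFT))[0])
    bas_nah = _init_scalar("BAS", lambda v: na_h_rates(v - _shift("BAS", eng.P_NASHIFT) - _shift("BAS", eng.P_NAHSHIFT))[0])
    bas_kn = _init_scalar("BAS", lambda v: kdr_n_rates(v - _shift("BAS", eng.P_KSHIFT))[0])
    olm_nah = _init_scalar("OLM", lambda v: na_h_rates(v - _shift("OLM", eng.P_NASHIFT) - _shift("OLM", eng.P_NAHSHIFT))[0])
    olm_kn = _init_scalar("OLM", lambda v: kdr_n_rates(v - _shift("OLM", eng.P_KSHIFT))[0])
    v0p = float(spec.init_V.get("PYR", packs["PYR"][0][eng.P_EL]))
    pyr_kaa = np.full((n["PYR"], 5), ka_inf(v0p)[0])
    pyr_kab = np.full((n["PYR"], 5), ka_inf(v0p)[1])
    v0o = float(spec.init_V.get("OLM", packs["OLM"][0][eng.P_EL]))
    olm_calm = np.full(n["OLM"], cal_m_inf(v0o))
    olm_ca = np.full(n["OLM"], params["kinetics"]["ca_pool"]["ca0"])

    s1 = {k: np.zeros((len(chans[k][0]), n[k])) for k in n}
    s2 = {k: np.zeros((len(chans[k][0]), n[k])) for k in n}
    gfix = {}
    for kind in n:
        g = spec.gfix.get(kind)
        if g is None:
            g = np.zeros((n[kind], ncomp[kind]))
        gfix[kind] = np.asarray(g, dtype=float)

    # wiring CSR per projection
    def _empty_proj(npre):
        return np.zeros(npre + 1, dtype=np.int64), np.zeros(0, dtype=np.int64)

    proj_csr = []
    projA_chan = np.zeros(6, dtype=np.int64)
    projA_w = np.zeros(6)
    projB_chan = np.zeros(6, dtype=np.int64)
    projB_w = np.zeros(6)
    syn_rows = {}
    for row in params["synapses"]:
        syn_rows.setdefault((row["pre"], row["post"]), []).append(row)
    for pi, (pre, post) in enumerate(PROJECTIONS):
        if spec.wiring is not None and (pre, post) in spec.wiring:
            indptr, tgt = spec.wiring[(pre, post)]
        else:
            indptr, tgt = _empty_proj(n[pre])
        proj_csr.append((np.asarray(indptr, dtype=np.int64),
                         np.asarray(tgt, dtype=np.int64)))
        rows = syn_rows.get((pre, post), [])
        # AMPA/GABA_A row is channel A; NMDA (if present) channel B
        a = [r for r in rows if r["receptor"] != "NMDA"]
        bnm = [r for r in rows if r["receptor"] == "NMDA"]
        if a:
            projA_chan[pi] = channel_index(post, a[0]["target"], a[0]["receptor"])
            projA_w[pi] = a[0]["gmax"]
        if bnm:
            projB_chan[pi] = channel_index(post, bnm[0]["target"], "NMDA")
            projB_w[pi] = bnm[0]["gmax"]

    # background streams
    bg = {k: ([], [], []) for k in n}
    if spec.background:
        for row in params["background"]:
            kind = row["cell"]
            mean_ms = 1000.0 / row["rate"]
            if kind == "PYR" and row["section"] == "dend":
                targets = ("Bdend", "Adend1", "Adend2", "Adend3")
            else:
                targets = (row["section"],)
            for tgt_name in targets:
                ch = channel_index(kind, tgt_name, row["receptor"])
                bg[kind][0].append(ch)
                bg[kind][1].append(mean_ms)
                bg[kind][2].append(row["gmax"])

    def _bg_arrays(kind):
        ch, mean, w = bg[kind]
        return (np.asarray(ch, dtype=np.int64), np.asarray(mean, dtype=float),
                np.asarray(w, dtype=float),
                np.zeros((len(ch), n[kind])))

    pyr_bg = _bg_arrays("PYR")
    bas_bg = _bg_arrays("BAS")
    olm_bg = _bg_arrays("OLM")

    # scheduled events
    events = sorted(spec.events, key=lambda e: e[0])
    ev_step = np.array([int(round(e[0] / dt)) for e in events], dtype=np.int64)
    ev_pop = np.array([POP_INDEX[e[1]] for e in events], dtype=np.int64)
    ev_cell = np.array([e[2] for e in events], dtype=np.int64)
    ev_chan = np.array(
        [channel_index(e[1], e[3], e[4]) for e in events], dtype=np.int64)
    ev_w = np.array([e[5] for e in events], dtype=float)

    # recording probes
    if record is None:
        record = [(k, 0, 0) for k in ("PYR", "BAS", "OLM") if n[k] > 0]
    rec_pop = np.array([POP_INDEX[r[0]] for r in record], dtype=np.int64)
    rec_cell = np.array([r[1] for r in record], dtype=np.int64)
    rec_comp = np.array([r[2] for r in record], dtype=np.int64)

    n_rec = (n_steps + rec_every - 1) // rec_every
    lfp_out = np.zeros(n_rec)
    vrec_out = np.zeros((n_rec, len(record)))
    status = np.zeros(2)

    cap = {k: int(n[k] * duration_ms / 1000.0 * 150) + 1000 for k in n}
    sp_t = {k: np.zeros(cap[k]) for k in n}
    sp_id = {k: np.zeros(cap[k], dtype=np.int64) for k in n}

    nsp = eng._advance(
        dt, n_steps, rec_every, int(input_seed) & 0x7FFFFFFF,
        packs["PYR"][0], packs["PYR"][1], adj_idx, adj_g, deg,
        *chans["PYR"],
        V["PYR"], H["PYR"], pyr_nah, pyr_kn, pyr_kaa, pyr_kab,
        s1["PYR"], s2["PYR"], gfix["PYR"],
        packs["BAS"][0], packs["BAS"][1],
        *chans["BAS"],
        V["BAS"], H["BAS"], bas_nah, bas_kn, s1["BAS"], s2["BAS"], gfix["BAS"],
        packs["OLM"][0], packs["OLM"][1],
        *chans["OLM"],
        V["OLM"], H["OLM"], olm_nah, olm_kn, olm_calm, olm_ca,
        s1["OLM"], s2["OLM"], gfix["OLM"],
        proj_csr[0][0], proj_csr[0][1], proj_csr[1][0], proj_csr[1][1],
        proj_csr[2][0], proj_csr[2][1], proj_csr[3][0], proj_csr[3][1],
        proj_csr[4][0], proj_csr[4][1], proj_csr[5][0], proj_csr[5][1],
        projA_chan, projA_w, projB_chan, projB_w, delay_steps,
        *pyr_bg, *bas_bg, *olm_bg,
        ev_step, ev_pop, ev_cell, ev_chan, ev_w,
        rec_pop, rec_cell, rec_comp,
        lfp_out, vrec_out,
        sp_t["PYR"], sp_id["PYR"], sp_t["BAS"], sp_id["BAS"],
        sp_t["OLM"], sp_id["OLM"],
        status,
    )
    nsp_pyr, nsp_bas, nsp_olm = nsp
    counts = {"PYR": nsp_pyr, "BAS": nsp_bas, "OLM": nsp_olm}
    spikes = {
        k: (sp_id[k][: counts[k]].copy(), sp_t[k][: counts[k]].copy())
        for k in counts
    }
    dt_rec = dt * rec_every
    n_filled = n_rec if status[0] == 0.0 else max(0, int(status[1] / dt_rec))
    t_rec = np.arange(n_filled) * dt_rec
    return RawResult(
        dt=dt,
        dt_rec=dt_rec,
        t_rec=t_rec,
        lfp=lfp_out[:n_filled],
        vrec=vrec_out[:n_filled],
        rec_labels=list(record),
        spikes=spikes,
        n_cells=dict(n),
        final_V={k: V[k] for k in n},
        final_h={k: H[k] for k in n},
        failed=bool(status[0] != 0.0),
        fail_time=float(status[1]) if status[0] != 0.0 else float("nan"),
    )
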