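"""Numerical engine: fixed-step exponential-Euler integration of the whole
network (or of isolated cells, which are just single-population runs with
synapses and background disabled).

Layout
------
Three populations in fixed order: PYR (5 compartments: soma, basal, three
apical levels), BAS (1), OLM (1). Per-population parameters are packed into

* a scalar vector ``P`` (indices ``P_*`` below),
* a per-compartment matrix ``C`` of shape (ncomp, NC) (indices ``C_*``),
* receptor-channel tables (compartment, tau1, tau2, E_rev, NMDA flag),

and per-population state arrays. Synaptic receptors are double-exponential
kinetic pairs (s1, s2) per channel per cell; all events (recurrent spikes
after the 2 ms delay, Poisson background, scheduled test pulses) increment
both states by weight * norm and the conductance is s2 - s1 (nS).

Units: mV, ms, S/cm2 for densities, nS for point conductances, pA for
injections, mM for calcium. S/cm2 * mV = mA/cm2; dV/dt [mV/ms] =
1e3 * I[mA/cm2] / Cm[uF/cm2].
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

# scalar parameter pack indices
P_CM, P_EL, P_ENA, P_EK, P_PHI, P_EH, P_VHALF, P_KSLOPE, P_TAMP, P_TVC, \
    P_TSIG, P_TMIN, P_INJ, P_IHSCALE, P_NABLOCK, P_IHSTATIC, P_KATAUA, \
    P_KATAUB, P_ECA, P_CALTAUM, P_KD, P_CA0, P_TAUCA, P_FIN, P_MG, P_ETA, \
    P_GAMMA, P_NASHIFT, P_KSHIFT, P_NAHSHIFT = range(30)
NP = 30

# per-compartment parameter pack indices
C_AREA, C_GL, C_GNA, C_GKDR, C_GKA, C_GHBAR, C_GCAL, C_GKCA = range(8)
NC = 8

REFRAC_MS = 1.0
SPIKE_THRESH = 0.0


@njit(cache=True, inline="always")
def _hinf(v, vhalf, k):
    return 1.0 / (1.0 + math.exp((v - vhalf) / k))


@njit(cache=True, inline="always")
def _htau(v, amp, vc, sig, tmin):
    x = (v - vc) / sig
    return amp / (math.exp(x) + math.exp(-x)) + tmin


@njit(cache=True, inline="always")
def _na_minf(v):
    x = v + 35.0
    if abs(x) < 1e-6:
        am = 1.0
    else:
        am = -0.1 * x / (math.exp(-0.1 * x) - 1.0)
    bm = 4.0 * math.exp(-(v + 60.0) / 18.0)
    return am / (am + bm)


@njit(cache=True, inline="always")
def _na_h_rates(v, phi):
    ah = 0.07 * math.exp(-(v + 58.0) / 20.0)
    bh = 1.0 / (math.exp(-0.1 * (v + 28.0)) + 1.0)
    s = ah + bh
    return ah / s, 1.0 / (phi * s)


@njit(cache=True, inline="always")
def _kdr_n_rates(v, phi):
    x = v + 34.0
    if abs(x) < 1e-6:
        an = 0.1
    else:
        an = -0.01 * x / (math.exp(-0.1 * x) - 1.0)
    bn = 0.125 * math.exp(-(v + 44.0) / 80.0)
    s = an + bn
    return an / s, 1.0 / (phi * s)


@njit(cache=True, inline="always")
def _ka_ainf(v):
    return 1.0 / (1.0 + math.exp(-(v + 50.0) / 10.0))


@njit(cache=True, inline="always")
def _ka_binf(v):
    return 1.0 / (1.0 + math.exp((v + 80.0) / 6.0))


@njit(cache=True, inline="always")
def _cal_minf(v):
    return 1.0 / (1.0 + math.exp(-(v + 20.0) / 6.5))


@njit(cache=True, inline="always")
def _gate_step(x, xinf, tau, dt):
    return xinf + (x - xinf) * math.exp(-dt / tau)


@njit(cache=True)
def _advance(
    dt, n_steps, rec_every, seed,
    # PYR
    pyr_P, pyr_C, pyr_adj_idx, pyr_adj_g, pyr_deg,
    pyr_chan_comp, pyr_chan_d1, pyr_chan_d2, pyr_chan_E, pyr_chan_nmda,
    pyr_chan_norm,
    pyr_V, pyr_h, pyr_nah, pyr_kn, pyr_kaa, pyr_kab,
    pyr_s1, pyr_s2, pyr_gfix,
    # BAS
    bas_P, bas_C,
    bas_chan_comp, bas_chan_d1, bas_chan_d2, bas_chan_E, bas_chan_nmda,
    bas_chan_norm,
    bas_V, bas_h, bas_nah, bas_kn, bas_s1, bas_s2, bas_gfix,
    # OLM
    olm_P, olm_C,
    olm_chan_comp, olm_chan_d1, olm_chan_d2, olm_chan_E, olm_chan_nmda,
    olm_chan_norm,
    olm_V, olm_h, olm_nah, olm_kn, olm_calm, olm_ca, olm_s1, olm_s2, olm_gfix,
    # wiring: 6 projections (PYR>PYR, PYR>BAS, PYR>OLM, BAS>PYR, BAS>BAS, OLM>PYR)
    p0_indptr, p0_tgt, p1_indptr, p1_tgt, p2_indptr, p2_tgt,
    p3_indptr, p3_tgt, p4_indptr, p4_tgt, p5_indptr, p5_tgt,
    projA_chan, projA_w, projB_chan, projB_w, delay_steps,
    # background: per population stream tables + per-stream-per-cell next times
    pyr_bg_chan, pyr_bg_mean, pyr_bg_w, pyr_bg_next,
    bas_bg_chan, bas_bg_mean, bas_bg_w, bas_bg_next,
    olm_bg_chan, olm_bg_mean, olm_bg_w, olm_bg_next,
    # scheduled events (sorted by step)
    ev_step, ev_pop, ev_cell, ev_chan, ev_w,
    # recording selections
    rec_pop, rec_cell, rec_comp,
    # outputs
    lfp_out, vrec_out,
    sp_t_pyr, sp_id_pyr, sp_t_bas, sp_id_bas, sp_t_olm, sp_id_olm,
    status_out,
):
    np.random.seed(seed)

    n_pyr = pyr_V.shape[0]
    n_bas = bas_V.shape[0]
    n_olm = olm_V.shape[0]
    ncomp = pyr_V.shape[1]

    nring = delay_steps + 1
    # slow gates (Ih, A-type K; time constants >= 5 ms) advance on a coarser
    # 0.2 ms schedule with a matching step size
    slow_every = max(1, int(round(0.2 / dt)))
    dts = dt * slow_every
    pyr_kaa_inf_dk = math.exp(-dts / pyr_P[P_KATAUA])
    pyr_kab_inf_dk = math.exp(-dts / pyr_P[P_KATAUB])
    ring_pyr = np.zeros((nring, pyr_s1.shape[0], n_pyr))
    ring_bas = np.zeros((nring, bas_s1.shape[0], n_bas))
    ring_olm = np.zeros((nring, olm_s1.shape[0], n_olm))

    last_pyr = np.full(n_pyr, -1e9)
    last_bas = np.full(n_bas, -1e9)
    last_olm = np.full(n_olm, -1e9)
    prev_pyr = pyr_V[:, 0].copy()
    prev_bas = bas_V[:, 0].copy()
    prev_olm = olm_V[:, 0].copy()

    nsp_pyr = 0
    nsp_bas = 0
    nsp_olm = 0
    ev_i = 0
    n_ev = ev_step.shape[0]
    rec_i = 0
    n_rec_slots = lfp_out.shape[0]

    # initialize background next-event times
    for k in range(pyr_bg_chan.shape[0]):
        for i in range(n_pyr):
            pyr_bg_next[k, i] = -math.log(np.random.random()) * pyr_bg_mean[k]
    for k in range(bas_bg_chan.shape[0]):
        for i in range(n_bas):
            bas_bg_next[k, i] = -math.log(np.random.random()) * bas_bg_mean[k]
    for k in range(olm_bg_chan.shape[0]):
        for i in range(n_olm):
            olm_bg_next[k, i] = -math.log(np.random.random()) * olm_bg_mean[k]

    for step in range(n_steps):
        t = step * dt
        slot = step % nring
        slow_step = step % slow_every == 0

        # ---- scheduled events (delivered at their step, no extra delay)
        while ev_i < n_ev and ev_step[ev_i] == step:
            pop = ev_pop[ev_i]
            c = ev_cell[ev_i]
            ch = ev_chan[ev_i]
            if pop == 0:
                amt = ev_w[ev_i] * pyr_chan_norm[ch]
                pyr_s1[ch, c] += amt
                pyr_s2[ch, c] += amt
            elif pop == 1:
                amt = ev_w[ev_i] * bas_chan_norm[ch]
                bas_s1[ch, c] += amt
                bas_s2[ch, c] += amt
            else:
                amt = ev_w[ev_i] * olm_chan_norm[ch]
                olm_s1[ch, c] += amt
                olm_s2[ch, c] += amt
            ev_i += 1

        # ---- ring-buffer deliveries (spikes emitted delay_steps ago)
        for ch in range(pyr_s1.shape[0]):
            for i in range(n_pyr):
                w = ring_pyr[slot, ch, i]
                if w != 0.0:
                    amt = w * pyr_chan_norm[ch]
                    pyr_s1[ch, i] += amt
                    pyr_s2[ch, i] += amt
                    ring_pyr[slot, ch, i] = 0.0
        for ch in range(bas_s1.shape[0]):
            for i in range(n_bas):
                w = ring_bas[slot, ch, i]
                if w != 0.0:
                    amt = w * bas_chan_norm[ch]
                    bas_s1[ch, i] += amt
                    bas_s2[ch, i] += amt
                    ring_bas[slot, ch, i] = 0.0
        for ch in range(olm_s1.shape[0]):
            for i in range(n_olm):
                w = ring_olm[slot, ch, i]
                if w != 0.0:
                    amt = w * olm_chan_norm[ch]
                    olm_s1[ch, i] += amt
                    olm_s2[ch, i] += amt
                    ring_olm[slot, ch, i] = 0.0

        # ---- Poisson background events in (t, t+dt]
        tnext = t + dt
        for k in range(pyr_bg_chan.shape[0]):
            ch = pyr_bg_chan[k]
            amt0 = pyr_bg_w[k] * pyr_chan_norm[ch]
            for i in range(n_pyr):
                while pyr_bg_next[k, i] < tnext:
                    pyr_s1[ch, i] += amt0
                    pyr_s2[ch, i] += amt0
                    pyr_bg_next[k, i] += -math.log(np.random.random()) * pyr_bg_mean[k]
        for k in range(bas_bg_chan.shape[0]):
            ch = bas_bg_chan[k]
            amt0 = bas_bg_w[k] * bas_chan_norm[ch]
            for i in range(n_bas):
                while bas_bg_next[k, i] < tnext:
                    bas_s1[ch, i] += amt0
                    bas_s2[ch, i] += amt0
                    bas_bg_next[k, i] += -math.log(np.random.random()) * bas_bg_mean[k]
        for k in range(olm_bg_chan.shape[0]):
            ch = olm_bg_chan[k]
            amt0 = olm_bg_w[k] * olm_chan_norm[ch]
            for i in range(n_olm):
                while olm_bg_next[k, i] < tnext:
                    olm_s1[ch, i] += amt0
                    olm_s2[ch, i] += amt0
                    olm_bg_next[k, i] += -math.log(np.random.random()) * olm_bg_mean[k]

        # ---- decay receptor states
        for ch in range(pyr_s1.shape[0]):
            d1 = pyr_chan_d1[ch]
            d2 = pyr_chan_d2[ch]
            for i in range(n_pyr):
                pyr_s1[ch, i] *= d1
                pyr_s2[ch, i] *= d2
        for ch in range(bas_s1.shape[0]):
            d1 = bas_chan_d1[ch]
            d2 = bas_chan_d2[ch]
            for i in range(n_bas):
                bas_s1[ch, i] *= d1
                bas_s2[ch, i] *= d2
        for ch in range(olm_s1.shape[0]):
            d1 = olm_chan_d1[ch]
            d2 = olm_chan_d2[ch]
            for i in range(n_olm):
                olm_s1[ch, i] *= d1
                olm_s2[ch, i] *= d2

        # ================= PYR update =================
        if n_pyr > 0:
            phi = pyr_P[P_PHI]
            nablock = pyr_P[P_NABLOCK] > 0.5
            ihstatic = pyr_P[P_IHSTATIC] > 0.5
            sih = pyr_P[P_IHSCALE]
            for i in range(n_pyr):
                vs = pyr_V[i, 0]
                # gates from current voltages
                hinf, htau = _na_h_rates(vs - pyr_P[P_NASHIFT] - pyr_P[P_NAHSHIFT], phi)
                pyr_nah[i] = _gate_step(pyr_nah[i], hinf, htau, dt)
                ninf, ntau = _kdr_n_rates(vs - pyr_P[P_KSHIFT], phi)
                pyr_kn[i] = _gate_step(pyr_kn[i], ninf, ntau, dt)
                if slow_step:
                    for c in range(ncomp):
                        vc = pyr_V[i, c]
                        ainf = _ka_ainf(vc)
                        pyr_kaa[i, c] = ainf + (pyr_kaa[i, c] - ainf) * pyr_kaa_inf_dk
                        binf = _ka_binf(vc)
                        pyr_kab[i, c] = binf + (pyr_kab[i, c] - binf) * pyr_kab_inf_dk
                        if not ihstatic:
                            pyr_h[i, c] = _gate_step(
                                pyr_h[i, c],
                                _hinf(vc, pyr_P[P_VHALF], pyr_P[P_KSLOPE]),
                                _htau(vc, pyr_P[P_TAMP], pyr_P[P_TVC],
                                      pyr_P[P_TSIG], pyr_P[P_TMIN]),
                                dts)
                # membrane update
                for c in range(ncomp):
                    vc = pyr_V[i, c]
                    area = pyr_C[c, C_AREA]
                    gtot = pyr_C[c, C_GL]
                    b = pyr_C[c, C_GL] * pyr_P[P_EL]
                    if not nablock:
                        gna = pyr_C[c, C_GNA]
                        if gna > 0.0:
                            m = _na_minf(vc - pyr_P[P_NASHIFT])
                            g = gna * m * m * m * pyr_nah[i]
                            gtot += g
                            b += g * pyr_P[P_ENA]
                        gk = pyr_C[c, C_GKDR]
                        if gk > 0.0:
                            n4 = pyr_kn[i]
                            g = gk * n4 * n4 * n4 * n4
                            gtot += g
                            b += g * pyr_P[P_EK]
                        gka = pyr_C[c, C_GKA]
                        if gka > 0.0:
                            g = gka * pyr_kaa[i, c] * pyr_kab[i, c]
                            gtot += g
                            b += g * pyr_P[P_EK]
                    if ihstatic:
                        g = pyr_gfix[i, c]
                    else:
                        g = pyr_C[c, C_GHBAR] * sih * pyr_h[i, c]
                    gtot += g
                    b += g * pyr_P[P_EH]
                    # synaptic channels on this compartment
                    for ch in range(pyr_chan_comp.shape[0]):
                        if pyr_chan_comp[ch] == c:
                            gs = (pyr_s2[ch, i] - pyr_s1[ch, i]) * 1e-9 / area
                            if gs != 0.0:
                                if pyr_chan_nmda[ch] == 1:
                                    gs *= 1.0 / (1.0 + pyr_P[P_ETA] * pyr_P[P_MG]
                                                 * math.exp(-pyr_P[P_GAMMA] * vc))
                                gtot += gs
                                b += gs * pyr_chan_E[ch]
                    # axial coupling
                    for a in range(pyr_deg[c]):
                        gax = pyr_adj_g[c, a] / area
                        gtot += gax
                        b += gax * pyr_V[i, pyr_adj_idx[c, a]]
                    if c == 0:
                        b += pyr_P[P_INJ] * 1e-9 / area  # pA -> mA
                    if gtot > 0.0:
                        vinf = b / gtot
                        rate = 1e3 * gtot / pyr_P[P_CM]
                        pyr_V[i, c] = vinf + (vc - vinf) * math.exp(-dt * rate)
                    else:
                        pyr_V[i, c] = vc + dt * 1e3 * b / pyr_P[P_CM]
            # spikes
            for i in range(n_pyr):
                v0 = pyr_V[i, 0]
                if prev_pyr[i] < SPIKE_THRESH <= v0 and t - last_pyr[i] >= REFRAC_MS:
                    last_pyr[i] = t
                    if nsp_pyr < sp_t_pyr.shape[0]:
                        sp_t_pyr[nsp_pyr] = t
                        sp_id_pyr[nsp_pyr] = i
                        nsp_pyr += 1
                    dslot = (step + delay_steps) % nring
                    for e in range(p0_indptr[i], p0_indptr[i + 1]):
                        ring_pyr[dslot, projA_chan[0], p0_tgt[e]] += projA_w[0]
                        ring_pyr[dslot, projB_chan[0], p0_tgt[e]] += projB_w[0]
                    for e in range(p1_indptr[i], p1_indptr[i + 1]):
                        ring_bas[dslot, projA_chan[1], p1_tgt[e]] += projA_w[1]
                        ring_bas[dslot, projB_chan[1], p1_tgt[e]] += projB_w[1]
                    for e in range(p2_indptr[i], p2_indptr[i + 1]):
                        ring_olm[dslot, projA_chan[2], p2_tgt[e]] += projA_w[2]
                        ring_olm[dslot, projB_chan[2], p2_tgt[e]] += projB_w[2]
                prev_pyr[i] = v0

        # ================= BAS update =================
        if n_bas > 0:
            phi = bas_P[P_PHI]
            nablock = bas_P[P_NABLOCK] > 0.5
            ihstatic = bas_P[P_IHSTATIC] > 0.5
            sih = bas_P[P_IHSCALE]
            for i in range(n_bas):
                vc = bas_V[i, 0]
                hinf, htau = _na_h_rates(vc - bas_P[P_NASHIFT] - bas_P[P_NAHSHIFT], phi)
                bas_nah[i] = _gate_step(bas_nah[i], hinf, htau, dt)
                ninf, ntau = _kdr_n_rates(vc - bas_P[P_KSHIFT], phi)
                bas_kn[i] = _gate_step(bas_kn[i], ninf, ntau, dt)
                if slow_step and not ihstatic:
                    bas_h[i, 0] = _gate_step(
                        bas_h[i, 0],
                        _hinf(vc, bas_P[P_VHALF], bas_P[P_KSLOPE]),
                        _htau(vc, bas_P[P_TAMP], bas_P[P_TVC],
                              bas_P[P_TSIG], bas_P[P_TMIN]),
                        dts)
                area = bas_C[0, C_AREA]
                gtot = bas_C[0, C_GL]
                b = bas_C[0, C_GL] * bas_P[P_EL]
                if not nablock:
                    m = _na_minf(vc - bas_P[P_NASHIFT])
                    g = bas_C[0, C_GNA] * m * m * m * bas_nah[i]
                    gtot += g
                    b += g * bas_P[P_ENA]
                    n4 = bas_kn[i]
                    g = bas_C[0, C_GKDR] * n4 * n4 * n4 * n4
                    gtot += g
                    b += g * bas_P[P_EK]
                if ihstatic:
                    g = bas_gfix[i, 0]
                else:
                    g = bas_C[0, C_GHBAR] * sih * bas_h[i, 0]
                gtot += g
                b += g * bas_P[P_EH]
                for ch in range(bas_chan_comp.shape[0]):
                    gs = (bas_s2[ch, i] - bas_s1[ch, i]) * 1e-9 / area
                    if gs != 0.0:
                        if bas_chan_nmda[ch] == 1:
                            gs *= 1.0 / (1.0 + bas_P[P_ETA] * bas_P[P_MG]
                                         * math.exp(-bas_P[P_GAMMA] * vc))
                        gtot += gs
                        b += gs * bas_chan_E[ch]
                b += bas_P[P_INJ] * 1e-9 / area
                if gtot > 0.0:
                    vinf = b / gtot
                    rate = 1e3 * gtot / bas_P[P_CM]
                    bas_V[i, 0] = vinf + (vc - vinf) * math.exp(-dt * rate)
                else:
                    bas_V[i, 0] = vc + dt * 1e3 * b / bas_P[P_CM]
            for i in range(n_bas):
                v0 = bas_V[i, 0]
                if prev_bas[i] < SPIKE_THRESH <= v0 and t - last_bas[i] >= REFRAC_MS:
                    last_bas[i] = t
                    if nsp_bas < sp_t_bas.shape[0]:
                        sp_t_bas[nsp_bas] = t
                        sp_id_bas[nsp_bas] = i
                        nsp_bas += 1
                    dslot = (step + delay_steps) % nring
                    for e in range(p3_indptr[i], p3_indptr[i + 1]):
                        ring_pyr[dslot, projA_chan[3], p3_tgt[e]] += projA_w[3]
                    for e in range(p4_indptr[i], p4_indptr[i + 1]):
                        ring_bas[dslot, projA_chan[4], p4_tgt[e]] += projA_w[4]
                prev_bas[i] = v0

        # ================= OLM update =================
        if n_olm > 0:
            phi = olm_P[P_PHI]
            nablock = olm_P[P_NABLOCK] > 0.5
            ihstatic = olm_P[P_IHSTATIC] > 0.5
            sih = olm_P[P_IHSCALE]
            for i in range(n_olm):
                vc = olm_V[i, 0]
                hinf, htau = _na_h_rates(vc - olm_P[P_NASHIFT] - olm_P[P_NAHSHIFT], phi)
                olm_nah[i] = _gate_step(olm_nah[i], hinf, htau, dt)
                ninf, ntau = _kdr_n_rates(vc - olm_P[P_KSHIFT], phi)
                olm_kn[i] = _gate_step(olm_kn[i], ninf, ntau, dt)
                olm_calm[i] = _gate_step(
                    olm_calm[i], _cal_minf(vc), olm_P[P_CALTAUM], dt)
                if slow_step and not ihstatic:
                    olm_h[i, 0] = _gate_step(
                        olm_h[i, 0],
                        _hinf(vc, olm_P[P_VHALF], olm_P[P_KSLOPE]),
                        _htau(vc, olm_P[P_TAMP], olm_P[P_TVC],
                              olm_P[P_TSIG], olm_P[P_TMIN]),
                        dts)
                area = olm_C[0, C_AREA]
                gtot = olm_C[0, C_GL]
                b = olm_C[0, C_GL] * olm_P[P_EL]
                if not nablock:
                    m = _na_minf(vc - olm_P[P_NASHIFT])
                    g = olm_C[0, C_GNA] * m * m * m * olm_nah[i]
                    gtot += g
                    b += g * olm_P[P_ENA]
                    n4 = olm_kn[i]
                    g = olm_C[0, C_GKDR] * n4 * n4 * n4 * n4
                    gtot += g
                    b += g * olm_P[P_EK]
                # L-type Ca and Ca-activated K
                mca = olm_calm[i]
                gca = olm_C[0, C_GCAL] * mca * mca
                ica = gca * (vc - olm_P[P_ECA])
                gtot += gca
                b += gca * olm_P[P_ECA]
                gk = olm_C[0, C_GKCA] * olm_ca[i] / (olm_ca[i] + olm_P[P_KD])
                gtot += gk
                b += gk * olm_P[P_EK]
                # calcium pool
                olm_ca[i] += dt * (-olm_P[P_FIN] * ica
                                   - (olm_ca[i] - olm_P[P_CA0]) / olm_P[P_TAUCA])
                if olm_ca[i] < olm_P[P_CA0]:
                    olm_ca[i] = olm_P[P_CA0]
                if ihstatic:
                    g = olm_gfix[i, 0]
                else:
                    g = olm_C[0, C_GHBAR] * sih * olm_h[i, 0]
                gtot += g
                b += g * olm_P[P_EH]
                for ch in range(olm_chan_comp.shape[0]):
                    gs = (olm_s2[ch, i] - olm_s1[ch, i]) * 1e-9 / area
                    if gs != 0.0:
                        if olm_chan_nmda[ch] == 1:
                            gs *= 1.0 / (1.0 + olm_P[P_ETA] * olm_P[P_MG]
                                         * math.exp(-olm_P[P_GAMMA] * vc))
                        gtot += gs
                        b += gs * olm_chan_E[ch]
                b += olm_P[P_INJ] * 1e-9 / area
                if gtot > 0.0:
                    vinf = b / gtot
                    rate = 1e3 * gtot / olm_P[P_CM]
                    olm_V[i, 0] = vinf + (vc - vinf) * math.exp(-dt * rate)
                else:
                    olm_V[i, 0] = vc + dt * 1e3 * b / olm_P[P_CM]
            for i in range(n_olm):
                v0 = olm_V[i, 0]
                if prev_olm[i] < SPIKE_THRESH <= v0 and t - last_olm[i] >= REFRAC_MS:
                    last_olm[i] = t
                    if nsp_olm < sp_t_olm.shape[0]:
                        sp_t_olm[nsp_olm] = t
                        sp_id_olm[nsp_olm] = i
                        nsp_olm += 1
                    dslot = (step + delay_steps) % nring
                    for e in range(p5_indptr[i], p5_indptr[i + 1]):
                        ring_pyr[dslot, projA_chan[5], p5_tgt[e]] += projA_w[5]
                prev_olm[i] = v0

        # ---- recording
        if step % rec_every == 0 and rec_i < n_rec_slots:
            dip = 0.0
            for i in range(n_pyr):
                dip += pyr_V[i, 4] - pyr_V[i, 1]
            lfp_out[rec_i] = dip
            for s in range(rec_pop.shape[0]):
                pop = rec_pop[s]
                if pop == 0:
                    vrec_out[rec_i, s] = pyr_V[rec_cell[s], rec_comp[s]]
                elif pop == 1:
                    vrec_out[rec_i, s] = bas_V[rec_cell[s], rec_comp[s]]
                else:
                    vrec_out[rec_i, s] = olm_V[rec_cell[s], rec_comp[s]]
            if not math.isfinite(lfp_out[rec_i]):
                status_out[0] = 1.0
                status_out[1] = t
                return nsp_pyr, nsp_bas, nsp_olm
            rec_i += 1

    status_out[0] = 0.0
    return nsp_pyr, nsp_bas, nsp_olm
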