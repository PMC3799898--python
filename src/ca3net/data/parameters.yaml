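# Model parameter file: single source of truth for cell, channel, synapse and
# background-input constants.
#
# Units: voltage mV, time ms, conductance density S/cm2, point conductance nS,
# point current pA, length/diameter um, axial resistivity ohm*cm, specific
# capacitance uF/cm2, calcium mM.
#
# Printed, literature-anchored quantities (Ih densities, reversals, half-
# activation voltages, synaptic tables, convergences, injections) are marked
# "anchored". Remaining constants come from the prior-model lineage
# (Wang-Buzsaki interneuron spike currents; Rotstein/Tort-style OLM Ih, CaL
# and KCa; sigmoidal HCN activation) with free passive/density constants
# constrained by the isolated-cell measurements the model reproduces
# (resting potentials, PSP amplitudes and delays per Ih level).

ih:
  # h_inf(v) = 1 / (1 + exp((v - v_half) / k))          (k > 0: closes with depolarization)
  # tau_h(v) = tau_amp / (exp((v - tau_vc)/tau_sigma) + exp(-(v - tau_vc)/tau_sigma)) + tau_min
  BAS:   # HCN1-like: fast
    ghbar: 2.0e-4          # anchored
    e_rev: -30.0           # anchored
    v_half: -73.0          # anchored
    k: 2.5
    tau_amp: 36.0
    tau_vc: -70.0
    tau_sigma: 20.0
    tau_min: 10.0
  PYR:   # HCN2-like: slow
    ghbar: 1.0e-4          # anchored
    e_rev: -30.0           # anchored
    v_half: -82.0          # anchored
    k: 14.0
    tau_amp: 360.0
    tau_vc: -75.0
    tau_sigma: 20.0
    tau_min: 40.0
  OLM:   # mixed isoform, depolarized reversal
    ghbar: 1.5e-4          # anchored
    e_rev: -40.0           # anchored
    v_half: -77.98
    k: 11.11
    tau_amp: 200.0
    tau_vc: -70.0
    tau_sigma: 20.0
    tau_min: 5.0

kinetics:
  na:   {e_rev: 55.0, phi: 5.0}     # Wang-Buzsaki transient Na (instantaneous m)
  kdr:  {e_rev: -90.0, phi: 5.0}    # Wang-Buzsaki delayed rectifier
  ka:   {e_rev: -90.0, tau_a: 5.0, tau_b: 20.0}
  cal:  {e_rev: 120.0, tau_m: 1.5}
  kca:  {e_rev: -90.0, kd: 0.03}
  ca_pool: {ca0: 5.0e-5, tau: 44.0, f_in: 0.02}    # dCa/dt = -f_in*I_CaL - (Ca-ca0)/tau
  nmda_mg: {mg: 1.0, eta: 0.28, gamma: 0.062}      # Jahr-Stevens block factor

cells:
  PYR:
    inj_pA: 50.0           # anchored
    cm: 1.0
    ra: 150.0
    na_shift: 0.0
    kdr_shift: 0.0
    na_h_shift: 8.0        # depolarized Na inactivation: soma keeps firing in up-states
    e_leak: -72.89
    compartments:          # order: soma, basal, 3 apical levels proximal->distal
      - {name: soma,   L: 20.0,  diam: 10.13, g_leak: 1.287e-4, gna: 3.5e-2, gkdr: 9.0e-3, gka: 5.0e-4, ih: 1.0}
      - {name: Bdend,  L: 200.0, diam: 2.53,  g_leak: 1.287e-4, gna: 0.0,    gkdr: 1.15e-2, gka: 5.0e-4, ih: 1.0}
      - {name: Adend1, L: 150.0, diam: 2.03,  g_leak: 1.287e-4, gna: 0.0,    gkdr: 1.15e-2, gka: 5.0e-4, ih: 1.0}
      - {name: Adend2, L: 150.0, diam: 2.03,  g_leak: 1.287e-4, gna: 0.0,    gkdr: 1.15e-2, gka: 5.0e-4, ih: 1.0}
      - {name: Adend3, L: 150.0, diam: 2.03,  g_leak: 1.287e-4, gna: 0.0,    gkdr: 1.15e-2, gka: 5.0e-4, ih: 1.0}
  BAS:
    inj_pA: 0.0            # anchored (no tonic drive)
    cm: 1.0
    ra: 150.0
    na_shift: 3.27         # depolarizing shift of spike kinetics (threshold placement)
    kdr_shift: 3.27
    e_leak: -65.44
    compartments:
      - {name: soma, L: 59.6, diam: 59.6, g_leak: 5.44e-5, gna: 3.5e-2, gkdr: 9.0e-3, gka: 0.0, ih: 1.0}
  OLM:
    inj_pA: -25.0          # anchored
    cm: 1.3
    ra: 150.0
    na_shift: 0.0
    kdr_shift: 0.0
    e_leak: -62.39
    compartments:
      - {name: soma, L: 49.46, diam: 49.46, g_leak: 1.102e-4, gna: 3.5e-2, gkdr: 9.0e-3, gka: 0.0,
         ih: 1.0, gcal: 1.0e-3, gkca: 8.5e-3}

populations:               # anchored
  PYR: 800
  BAS: 200
  OLM: 200

synapses:                  # anchored: one row per projection
  # receptor taus in ms, conductance in nS, convergence = inputs per postsynaptic cell
  - {pre: PYR, post: PYR, receptor: AMPA,  tau1: 0.05, tau2: 5.3,  gmax: 0.02, convergence: 25, target: Bdend}
  - {pre: PYR, post: PYR, receptor: NMDA,  tau1: 15.0, tau2: 150.0, gmax: 0.004, convergence: 25, target: Bdend}
  - {pre: PYR, post: BAS, receptor: AMPA,  tau1: 0.05, tau2: 5.3,  gmax: 0.36, convergence: 100, target: soma}
  - {pre: PYR, post: BAS, receptor: NMDA,  tau1: 15.0, tau2: 150.0, gmax: 1.38, convergence: 100, target: soma}
  - {pre: PYR, post: OLM, receptor: AMPA,  tau1: 0.05, tau2: 5.3,  gmax: 0.36, convergence: 10, target: soma}
  - {pre: PYR, post: OLM, receptor: NMDA,  tau1: 15.0, tau2: 150.0, gmax: 0.7,  convergence: 10, target: soma}
  - {pre: BAS, post: PYR, receptor: GABA_A, tau1: 0.07, tau2: 9.1, gmax: 0.72, convergence: 50, target: soma}
  - {pre: BAS, post: BAS, receptor: GABA_A, tau1: 0.07, tau2: 9.1, gmax: 4.5,  convergence: 60, target: soma}
  - {pre: OLM, post: PYR, receptor: GABA_A, tau1: 0.2,  tau2: 20.0, gmax: 72.0, convergence: 20, target: Adend3}

synaptic_delay_ms: 2.0     # anchored: all cell-to-cell delays
reversal:                  # anchored
  AMPA: 0.0
  NMDA: 0.0
  GABA_A: -80.0

background:                # anchored: Poisson bombardment (rates: fast 1000 Hz, NMDA 10 Hz)
  - {cell: PYR, section: soma, receptor: AMPA,  tau1: 0.05, tau2: 5.3,  gmax: 0.05,  rate: 1000.0}
  - {cell: PYR, section: soma, receptor: GABA_A, tau1: 0.07, tau2: 9.1, gmax: 0.012, rate: 1000.0}
  - {cell: PYR, section: dend, receptor: AMPA,  tau1: 0.05, tau2: 5.3,  gmax: 0.05,  rate: 1000.0}
  # slow NMDA stream: entorhinal-like input onto the last distal apical compartment
  - {cell: PYR, section: Adend3, receptor: NMDA, tau1: 15.0, tau2: 150.0, gmax: 6.5, rate: 10.0}
  - {cell: PYR, section: dend, receptor: GABA_A, tau1: 0.07, tau2: 9.1, gmax: 0.012, rate: 1000.0}
  - {cell: BAS, section: soma, receptor: AMPA,  tau1: 0.05, tau2: 5.3,  gmax: 0.02,  rate: 1000.0}
  - {cell: BAS, section: soma, receptor: GABA_A, tau1: 0.07, tau2: 9.1, gmax: 0.2,   rate: 1000.0}
  - {cell: OLM, section: soma, receptor: AMPA,  tau1: 0.05, tau2: 5.3,  gmax: 0.0625, rate: 1000.0}
  - {cell: OLM, section: soma, receptor: GABA_A, tau1: 0.07, tau2: 9.1, gmax: 0.2,   rate: 1000.0}

simulation:
  dt: 0.025                # ms; exponential-Euler step
  lfp_sample_ms: 1.0       # LFP / trace sampling interval
  trim_ms: 200.0           # discard at both ends before spectral analysis
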