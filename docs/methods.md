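# Model and methods

`ca3net` is a conductance-based model of hippocampal area CA3 built to study
how the hyperpolarization-activated cation current Ih tunes theta (4–12 Hz)
and low-gamma (25–55 Hz) network rhythms and their cross-frequency coupling.
This note records the model equations, the reasoning behind every
parameter that had to be chosen, the numerical scheme, and what the
synthetic protocols do and do not establish.

## Network architecture

Three cell classes: 800 five-compartment pyramidal cells (PYR: soma, one
basal dendrite, three apical compartments proximal→distal), 200
single-compartment basket interneurons (BAS) and 200 single-compartment
oriens-lacunosum-moleculare interneurons (OLM). Wiring uses fixed
convergence — every postsynaptic cell draws a fixed number of presynaptic
partners per projection, sampled without replacement, no self-contacts —
so divergence varies randomly. The projections (receptor, rise/decay ms,
peak nS, convergence):

| projection | receptor | tau1/tau2 | gmax | convergence | target |
|---|---|---|---|---|---|
| PYR→PYR | AMPA + NMDA | 0.05/5.3, 15/150 | 0.02, 0.004 | 25 | basal dendrite |
| PYR→BAS | AMPA + NMDA | 0.05/5.3, 15/150 | 0.36, 1.38 | 100 | soma |
| PYR→OLM | AMPA + NMDA | 0.05/5.3, 15/150 | 0.36, 0.7 | 10 | soma |
| BAS→PYR | GABA_A | 0.07/9.1 | 0.72 | 50 | soma |
| BAS→BAS | GABA_A | 0.07/9.1 | 4.5 | 60 | soma |
| OLM→PYR | GABA_A | 0.2/20 | 72 | 20 | distal apical |

At full scale this yields exactly 152,000 synapses (AMPA and NMDA at one
contact count separately). All cell-to-cell delays are 2 ms. AMPA/NMDA
reverse at 0 mV, GABA_A at −80 mV. Receptors are double-exponential
conductances normalized so a unit event peaks at gmax; the kinetics are
linear, so the engine integrates two decaying state variables per receptor
channel and increments both on each delivery (exact superposition with no
per-event bookkeeping).

Background drive is Poisson: 1000 Hz AMPA and GABA_A bombardment on every
soma (and PYR dendritic compartments), representing unmodeled afferents and
producing a high-conductance state, plus a slow 6.5 nS NMDA stream at 10 Hz
onto the most distal apical PYR compartment, standing in for entorhinal
input. That stream drives regenerative NMDA depolarizations in the distal
dendrite and sparse pyramidal firing. We place it on the distal compartment
only: duplicated across dendritic compartments its summed conductance
(~13 nS sustained) locks the cell in permanent depolarization block.

Tonic injections set baseline excitability: +50 pA into every PYR soma,
−25 pA into every OLM cell. Isolated-cell protocols keep these injections
and switch off synapses and background.

## Membrane currents

All classes carry leak, transient Na and delayed-rectifier K (Wang–Buzsaki
kinetics with instantaneous m³, phi = 5, and small per-class voltage shifts
of the rate functions that place the spike threshold — see calibration).
PYR adds an A-type K current and Ih in every compartment; BAS adds a fast
Ih; OLM adds an L-type Ca current, a Ca-activated K current driven by a
first-order intracellular Ca pool (dCa/dt = −f·I_CaL − (Ca−Ca0)/tau), and a
mixed-isoform Ih.

The h-current is, per compartment,

    I_h = g_hbar · s · h · (V − E_h),
    h_inf(V) = 1 / (1 + exp((V − V_half)/k)),
    tau_h(V) = A / (exp((V−Vc)/σ) + exp(−(V−Vc)/σ)) + tau_min,
    dh/dt = (h_inf − h) / tau_h,

with the neuromodulation scale s ∈ [0, 2] (1 = baseline). Class-specific
constants: g_hbar = 2×10⁻⁴ (BAS), 1×10⁻⁴ (PYR), 1.5×10⁻⁴ (OLM) S/cm²;
E_h = −30 mV (BAS, PYR) and −40 mV (OLM); V_half = −73 mV (BAS, HCN1-like,
fast tau) and −82 mV (PYR, HCN2-like, slow tau). The "static" substitution
replaces the gated conductance by the fixed value g_hbar·s·h it reached at
the end of a 7 s relaxation, with the same reversal: it keeps the resting
potential but removes the gate's dynamic closing during synaptic events,
isolating Ih's dynamic contribution to synaptic integration.

## Calibration of unprinted constants

The Ih densities, reversals and half-activation voltages, the synaptic and
background tables, convergences and injections above are fixed from the
published description of this network. Cell geometry, passive properties,
spike-current placement and the remaining kinetic constants are not
published; they were reconstructed by constraining the model to reproduce
the published isolated-cell measurements, which pin them tightly:

* PSP time-to-peak fixes the resting membrane time constant (leak density),
* PSP amplitude then fixes the cell's area,
* the resting potential at s = 0 fixes the leak reversal,
* the RMP ladder across s = 0…2 fixes the h_inf slope k,
* quiescence at s = 1.5 versus 6 Hz rhythmic firing at s = 2 places the
  OLM spike threshold and the KCa/Ca-pool constants (the OLM oscillates by
  an Ih/KCa pacemaker mechanism with ~50 ms Ca clearance),
* the network baseline rates fix the PYR dendritic K-dr density.

The resulting battery: OLM rests at −67.9 / −64.1 / −61.6 mV at s = 0 /
0.5 / 1, fires one transient spike then rests at −59.4 mV at s = 1.5, and
fires rhythmically at 6.2 Hz at s = 2. BAS: 0.98 mV EPSP and 0.31 mV IPSP
at s = 0, IPSP growing to 0.41 mV at s = 2 with a time-to-peak of 12.3 ms
there (the published 12.5 ms anchor; unlike the published cell, ours
reaches it from above — 13.4 ms at s = 0 — rather than from below).
PYR: 1.80 mV EPSP at s = 0 dipping to
1.73 mV at s = 0.5 — the one condition where amplitude decreases — with
monotone RMP from −65.5 to −57.7 mV. With Na and K currents blocked the
EPSP shrinks monotonically with s (driving force and shunting only); with
the static substitution it exceeds the dynamic EPSP at s ≥ 1 (the dynamic
gate closes during the EPSP and trims it).

One slope was left deliberately steep: the BAS h_inf uses k = 2.5 mV.
Shallower slopes put so much Ih conductance at rest that no leak level can
reconcile the printed ±3 mV RMP span with the ~13 ms membrane time constant
the printed IPSP delays require.

## Numerical scheme

Fixed-step exponential-Euler integration at dt = 0.025 ms: every gate and
every compartment voltage relaxes toward its instantaneous steady state
with its instantaneous time constant, treating conductances and neighbor
voltages as frozen within the step. This is unconditionally stable, keeps
gates in [0, 1], and is exact for a clamped-voltage gate. Slow gates (Ih,
A-type K; time constants ≥ 5 ms) advance on a 0.2 ms subschedule. Synaptic
delays round to the nearest step. Halving dt moves a 7 s resting potential
by < 0.05 mV. Spikes are upward 0 mV crossings with a 1 ms dead time.

## LFP and rhythm analysis

The LFP proxy is the sum over pyramidal cells of (distal apical − basal)
membrane potential — a dipole sum. Before any spectral use the first and
last 200 ms are discarded and the DC component removed. Spectra use DPSS
multitapers (time-bandwidth 4, 7 tapers, adaptive weights; Parseval-exact
scaling), with peaks reported for theta (4–12 Hz) and low gamma (25–55 Hz).

Coupling analysis is event-based: theta phase comes from the analytic
signal of the 6–10 Hz zero-phase (forward-backward Butterworth) filtered
LFP, with 0 at the theta peak and positive phases on the descending limb.
Gamma events are time-domain transients of the 25–55 Hz-filtered LFP:
local maxima above mean + 1 SD, at most one per 40 ms, whose trough-to-
trough duty cycle falls in 18–40 ms (one period of a 25–55 Hz event); a
series whose gamma band holds < 0.1% of the variance yields no events
(noise gate against filter ringing). The theta phases at event peaks fill
100 equal bins; the modulation index is the Kullback–Leibler divergence of
the normalized histogram from uniform, divided by log 100 (0 = uniform,
1 = single-bin). Sampling gamma at event peaks rather than via a continuous
amplitude envelope reduces the artifacts sharp deflections introduce into
phase-amplitude coupling estimates. The phase of peak gamma is estimated by
the profile's first circular moment — identical to the argmax for a
unimodal symmetric profile and robust to bin noise.

## Protocols and desk scaling

The published design is 5 Ih levels × 6 wirings × 6 input streams of 8 s
per swept class, plus 25 long (900 s) runs on a PYR × BAS grid. The
package expresses that design declaratively (`SweepSpec`, `cfc_grid`,
`run_campaign`) and runs reduced versions for routine verification:
populations scale down proportionally with convergences held fixed (so
per-cell input statistics are preserved; where a shrunken pool cannot
supply the full convergence it is capped with gmax scaled up to conserve
total input conductance). Network statistics are moderately
scale-sensitive — smaller networks synchronize more strongly — so
quantitative rate checks use half scale (400/100/100), where the model
reproduces the published baseline best, and trend checks use quarter scale.

## Emergent behavior and known limitations

At baseline the network shows nested rhythms: OLM cells pace theta through
their slow, strong distal inhibition; the PYR–BAS loop (with BAS–BAS
inhibition) generates low gamma whose amplitude waxes within each theta
cycle. Removing OLM Ih (s = 0) silences OLM, roughly doubles PYR firing,
more than doubles BAS firing and multiplies gamma power several-fold;
raising OLM Ih (s = 2) suppresses the whole network. Raising BAS Ih
increases gamma power and lowers gamma frequency; raising PYR Ih increases
theta power and frequency; raising both raises both powers and lowers
gamma frequency.

Known quantitative limitations of the reconstruction:

* The BAS baseline rate runs ~20–30 % below the published 10.8 Hz, and at
  OLM-Ih-0 reaches ~19–22 Hz against a published 28.7 Hz: the BAS/PYR gain
  of the reconstructed basket cell is structurally lower, and OLM
  excitability cannot be raised to compensate without destroying the
  isolated OLM battery (its quiescence window at s = 1.5 spans ~1 mV).
* The dipole LFP's theta band carries substantial incoherent power from
  the distal NMDA bombardment (each cell's distal compartment undergoes
  large slow conductance fluctuations). Removing OLM therefore reduces
  theta-band power several-fold but does not push it below gamma-band
  power, and theta peak frequencies sit ~1–2 Hz below the published
  values. Thicker dendrites would damp this noise but are excluded by the
  printed somatic PSP amplitudes and delays.
* Isolated PYR EPSP growth at high s (2.21 mV at s = 1.5 in the published
  measurements) is
  not reproduced (ours stays near 1.7 mV): it requires a subthreshold Na
  amplification profile the Wang–Buzsaki-lineage kinetics do not provide.

The synthetic protocols establish internal consistency of the
implementation (oracle-checked kinetics, superposition, spectral scaling,
coupling recovery on constructed signals) and the qualitative circuit
mechanisms above; they do not validate the model against in vivo data.
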