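"""Membrane channels, with the cell-type-specific Ih (HCN) parameterizations.

The h-current is modeled per cell class with a sigmoidal steady-state
activation that *closes* with depolarization,

    h_inf(v) = 1 / (1 + exp((v - v_half) / k)),          k > 0,

a bell-shaped voltage-dependent time constant

    tau_h(v) = tau_amp / (exp((v - vc)/sigma) + exp(-(v - vc)/sigma)) + tau_min,

and first-order gate relaxation dh/dt = (h_inf(v) - h) / tau_h(v). The
instantaneous conductance is g_hbar * s * h where s is a dimensionless
neuromodulation scale in [0, 2] (1 = baseline density), so

    I_h = g_hbar * s * h * (v - E_h).

Basket cells use a fast HCN1-like tau and v_half = -73 mV; pyramidal cells
a slow HCN2-like tau and v_half = -82 mV; OLM cells a mixed-isoform variant
with a depolarized reversal (-40 mV). Constants live in the packaged
parameter file and are loaded through :func:`ih_spec_for`.

The "static" substitution replaces the dynamic gate with a fixed (leak-like)
conductance equal to the steady-state Ih conductance measured at the end of
a relaxation run, with the same reversal: I = g_fix * (v - E_h). It isolates
the dynamic (gating) contribution of Ih from its tonic depolarizing one.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .params import load_parameters

__all__ = [
    "IhSpec",
    "StaticIhSpec",
    "ih_spec_for",
    "ih_steady_state",
    "ih_time_constant",
    "ih_current",
    "step_gate",
    "static_ih_current",
    "freeze_gate",
]


@dataclass(frozen=True)
class IhSpec:
    """Parameters of one cell class's h-current.

    Conductance density ``ghbar`` in S/cm2, voltages in mV, times in ms,
    ``scale`` dimensionless (neuromodulation factor s).
    """

    ghbar: float
    e_rev: float
    v_half: float
    k: float
    tau_amp: float
    tau_vc: float
    tau_sigma: float
    tau_min: float
    scale: float = 1.0

    def __post_init__(self) -> None:
        if self.ghbar <= 0:
            raise ValueError("ghbar must be > 0")
        if self.scale < 0:
            raise ValueError("scale must be >= 0")
        if self.k <= 0 or self.tau_min <= 0 or self.tau_amp <= 0:
            raise ValueError("kinetic constants must be positive")

    def with_scale(self, scale: float) -> "IhSpec":
        return replace(self, scale=scale)


@dataclass(frozen=True)
class StaticIhSpec:
    """Frozen Ih: fixed conductance ``g_fix`` (S/cm2) with reversal ``e_rev``."""

    g_fix: float
    e_rev: float

    def __post_init__(self) -> None:
        if self.g_fix < 0:
            raise ValueError("g_fix must be >= 0")


def ih_spec_for(kind: str, scale: float = 1.0, params: dict | None = None) -> IhSpec:
    """Build the h-current spec of one cell class from the parameter file."""
    if params is None:
        params = load_parameters()
    try:
        raw = params["ih"][kind]
    except KeyError as err:
        raise KeyError(f"no Ih parameterization for cell kind {kind!r}") from err
    return IhSpec(
        ghbar=raw["ghbar"],
        e_rev=raw["e_rev"],
        v_half=raw["v_half"],
        k=raw["k"],
        tau_amp=raw["tau_amp"],
        tau_vc=raw["tau_vc"],
        tau_sigma=raw["tau_sigma"],
        tau_min=raw["tau_min"],
        scale=scale,
    )


def ih_steady_state(v, spec: IhSpec):
    """Steady-state activation h_inf(v); in [0, 1], decreasing in v."""
    v = np.asarray(v, dtype=float)
    out = 1.0 / (1.0 + np.exp((v - spec.v_half) / spec.k))
    return out if out.ndim else float(out)


def ih_time_constant(v, spec: IhSpec):
    """Voltage-dependent time constant tau_h(v) in ms; strictly positive."""
    v = np.asarray(v, dtype=float)
    x = (v - spec.tau_vc) / spec.tau_sigma
    out = spec.tau_amp / (np.exp(x) + np.exp(-x)) + spec.tau_min
    return out if out.ndim else float(out)


def ih_current(v, h, spec: IhSpec):
    """Current density I_h = ghbar * s * h * (v - E_h), in mA/cm2.

    Outward (positive) for v > E_h. Linear in both ``h`` and ``spec.scale``.
    """
    h = np.asarray(h, dtype=float)
    if np.any(h < 0) or np.any(h > 1):
        raise ValueError("gate state h must lie in [0, 1]")
    v = np.asarray(v, dtype=float)
    # S/cm2 * mV = mA/cm2
    out = spec.ghbar * spec.scale * h * (v - spec.e_rev)
    return out if out.ndim else float(out)


def static_ih_current(v, spec: StaticIhSpec):
    """Current density of the frozen-conductance substitution, mA/cm2."""
    v = np.asarray(v, dtype=float)
    out = spec.g_fix * (v - spec.e_rev)
    return out if out.ndim else float(out)


def step_gate(h, v, dt: float, spec: IhSpec):
    """Advance the gate one step of ``dt`` ms at (clamped) voltage ``v``.

    Uses the exponential-Euler update
    h <- h_inf + (h - h_inf) * exp(-dt / tau_h), which is exact at clamped
    voltage and keeps h in [0, 1] unconditionally.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    h = np.asarray(h, dtype=float)
    hinf = ih_steady_state(v, spec)
    tau = ih_time_constant(v, spec)
    out = hinf + (h - hinf) * np.exp(-dt / tau)
    return out if out.ndim else float(out)


def freeze_gate(v, spec: IhSpec) -> StaticIhSpec:
    """Static substitution at the fully relaxed gate for voltage ``v``.

    g_fix = ghbar * s * h_inf(v); see :class:`StaticIhSpec`. For frozen
    conductances measured at the end of an actual simulation (the protocol
    used by the experiments layer) use the engine's final gate state instead.
    """
    return StaticIhSpec(
        g_fix=spec.ghbar * spec.scale * ih_steady_state(v, spec),
        e_rev=spec.e_rev,
    )


# --- generic spike/adaptation currents (Wang-Buzsaki lineage) -----------------
#
# These vectorized forms mirror the engine's jitted kernels and exist for
# direct inspection and unit testing of the kinetics.

def na_m_inf(v):
    """Instantaneous activation of the transient Na current."""
    v = np.asarray(v, dtype=float)
    am = _vtrap(-0.1 * (v + 35.0), np.exp(-0.1 * (v + 35.0)) - 1.0)
    bm = 4.0 * np.exp(-(v + 60.0) / 18.0)
    return am / (am + bm)


def na_h_rates(v, phi: float = 5.0):
    """(h_inf, tau_h) of Na inactivation; tau in ms."""
    v = np.asarray(v, dtype=float)
    ah = 0.07 * np.exp(-(v + 58.0) / 20.0)
    bh = 1.0 / (np.exp(-0.1 * (v + 28.0)) + 1.0)
    return ah / (ah + bh), 1.0 / (phi * (ah + bh))


def kdr_n_rates(v, phi: float = 5.0):
    """(n_inf, tau_n) of the delayed-rectifier activation; tau in ms."""
    v = np.asarray(v, dtype=float)
    an = _vtrap(-0.01 * (v + 34.0), np.exp(-0.1 * (v + 34.0)) - 1.0)
    bn = 0.125 * np.exp(-(v + 44.0) / 80.0)
    return an / (an + bn), 1.0 / (phi * (an + bn))


def ka_inf(v):
    """(a_inf, b_inf) of the A-type K current (activation, inactivation)."""
    v = np.asarray(v, dtype=float)
    a = 1.0 / (1.0 + np.exp(-(v + 50.0) / 10.0))
    b = 1.0 / (1.0 + np.exp((v + 80.0) / 6.0))
    return a, b


def cal_m_inf(v):
    """Activation of the high-threshold (L-type) Ca current."""
    v = np.asarray(v, dtype=float)
    return 1.0 / (1.0 + np.exp(-(v + 20.0) / 6.5))


def kca_open(ca, kd: float = 0.03):
    """Open fraction of the Ca-activated K current: ca / (ca + kd)."""
    ca = np.asarray(ca, dtype=float)
    return ca / (ca + kd)


def _vtrap(x_over, denom):
    """x/ (exp-form denominator) with the removable singularity filled in."""
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(np.abs(denom) > 1e-9, x_over / denom, 1.0 - denom / 2.0)
    return out
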