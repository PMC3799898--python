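"""Experiment protocols: the isolated-cell battery, Ih-conductance scaling
sweeps with independent wiring/input randomizations, the long-duration
PYR x BAS coupling grid, and campaign bookkeeping.

The full published design is 5 scale levels x 6 wirings x 6 input streams
(180 simulations per swept cell class) of 8 s each, plus a 25-cell grid of
900 s runs for coupling; ``SweepSpec`` expresses any subset of that design,
and the desk-scale defaults used by the test-suite shrink populations,
seeds and durations while preserving every qualitative trend.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .cells import measure_psp, measure_rmp
from .network import NetworkConfig, population_rates, prepare_lfp, run_network
from .rhythms import (GAMMA_BAND, THETA_BAND, band_peak, cfc_analysis,
                      psd_multitaper)

__all__ = [
    "SweepSpec",
    "single_cell_battery",
    "scaling_sweep",
    "sweep_trends",
    "cfc_grid",
    "run_campaign",
    "analyze_run",
]

SCALE_LEVELS = (0.0, 0.5, 1.0, 1.5, 2.0)


@dataclass(frozen=True)
class SweepSpec:
    """One scaling sweep: which class(es) to scale, levels, randomizations."""

    target: str                       # PYR | BAS | OLM | all | PYR+BAS
    levels: tuple = SCALE_LEVELS
    wiring_seeds: tuple = (0, 1, 2, 3, 4, 5)
    input_seeds: tuple = (10, 11, 12, 13, 14, 15)
    duration_ms: float = 8000.0
    population_scale: float = 1.0

    def __post_init__(self):
        if self.target not in ("PYR", "BAS", "OLM", "all", "PYR+BAS"):
            raise ValueError(f"unknown sweep target {self.target!r}")
        if not self.levels or not all(0 <= lv <= 2 for lv in self.levels):
            raise ValueError("levels must lie in [0, 2]")
        if not self.wiring_seeds or not self.input_seeds:
            raise ValueError("seed lists must be non-empty")

    def scales_for(self, level: float) -> dict:
        if self.target == "all":
            kinds = ("PYR", "BAS", "OLM")
        elif self.target == "PYR+BAS":
            kinds = ("PYR", "BAS")
        else:
            kinds = (self.target,)
        scales = {"PYR": 1.0, "BAS": 1.0, "OLM": 1.0}
        scales.update({k: level for k in kinds})
        return scales

    @property
    def n_simulations(self) -> int:
        return len(self.levels) * len(self.wiring_seeds) * len(self.input_seeds)


def single_cell_battery(kinds=("PYR", "BAS", "OLM"), levels=SCALE_LEVELS,
                        receptors=("AMPA", "GABA_A"), static_modes=(False, True),
                        params: dict | None = None) -> pd.DataFrame:
    """Isolated-cell measurements per (kind, Ih level, receptor, Ih mode).

    One row per combination with the resting potential (or rhythmic firing
    frequency), transient spike count, and PSP amplitude / time-to-peak.
    PSPs contaminated by a spike carry NaN and ``measurable`` False — e.g.
    the OLM cell firing rhythmically at twice-baseline Ih precludes an IPSP
    measurement there.
    """
    rows = []
    for kind in kinds:
        for level in levels:
            rmp = measure_rmp(kind, level, params=params)
            for receptor in receptors:
                for static in static_modes:
                    psp = measure_psp(kind, level, receptor,
                                      static_ih=static, params=params)
                    rows.append({
                        "kind": kind,
                        "ih_scale": level,
                        "receptor": receptor,
                        "static_ih": static,
                        "rmp_mV": rmp.rmp_mV,
                        "rhythmic": rmp.rhythmic,
                        "firing_hz": rmp.firing_hz,
                        "transient_spikes": rmp.transient_spikes,
                        "psp_amplitude_mV": psp.amplitude_mV,
                        "psp_time_to_peak_ms": psp.time_to_peak_ms,
                        "psp_measurable": psp.measurable,
                    })
    return pd.DataFrame(rows)


def analyze_run(result, trim_ms: float = 200.0) -> dict:
    """Rates, band peaks and CFC summary of one network simulation."""
    rates = population_rates(result, trim_ms=trim_ms)
    lfp = prepare_lfp(result.lfp, result.fs, trim_ms)
    spectrum = psd_multitaper(lfp, result.fs)
    theta = band_peak(spectrum, THETA_BAND)
    gamma = band_peak(spectrum, GAMMA_BAND)
    cfc = cfc_analysis(lfp, result.fs)
    return {
        "rate_PYR": rates["PYR"],
        "rate_BAS": rates["BAS"],
        "rate_OLM": rates["OLM"],
        "theta_freq": theta.freq,
        "theta_power": theta.power,
        "gamma_freq": gamma.freq,
        "gamma_power": gamma.power,
        "mi": cfc.mi,
        "gamma_phase": cfc.peak_phase,
        "n_gamma_events": cfc.n_events,
    }


def scaling_sweep(spec: SweepSpec, base: NetworkConfig | None = None,
                  progress=None) -> pd.DataFrame:
    """Run the sweep: one row per (level, wiring seed, input seed)."""
    if base is None:
        base = NetworkConfig()
    rows = []
    for level in spec.levels:
        for ws in spec.wiring_seeds:
            for iseed in spec.input_seeds:
                cfg = replace(
                    base,
                    ih_scales=spec.scales_for(level),
                    wiring_seed=int(ws),
                    input_seed=int(iseed),
                    duration_ms=spec.duration_ms,
                    population_scale=spec.population_scale,
                )
                result = run_network(cfg)
                row = {"target": spec.target, "level": level,
                       "wiring_seed": ws, "input_seed": iseed}
                row.update(analyze_run(result))
                rows.append(row)
                if progress is not None:
                    progress(row)
    return pd.DataFrame(rows)


def sweep_trends(summary: pd.DataFrame,
                 metrics=("theta_power", "theta_freq", "gamma_power",
                          "gamma_freq")) -> dict:
    """Pearson correlation of each band metric against the swept level.

    Returns metric -> (r, sign). Trend direction claims are made on the
    sign of the product-moment coefficient across all sweep rows.
    """
    out = {}
    for metric in metrics:
        x = summary["level"].to_numpy(dtype=float)
        y = summary[metric].to_numpy(dtype=float)
        ok = np.isfinite(x) & np.isfinite(y)
        if ok.sum() < 3 or np.std(x[ok]) == 0 or np.std(y[ok]) == 0:
            out[metric] = (float("nan"), 0)
            continue
        r = float(np.corrcoef(x[ok], y[ok])[0, 1])
        out[metric] = (r, int(np.sign(r)))
    return out


def cfc_grid(pyr_levels=SCALE_LEVELS, bas_levels=SCALE_LEVELS,
             duration_ms: float = 900_000.0, wiring_seed: int = 0,
             input_seed: int = 10, base: NetworkConfig | None = None,
             progress=None) -> pd.DataFrame:
    """Theta-gamma coupling over a PYR x BAS Ih-scale grid.

    All cells of the grid share one wiring and one input stream, as in the
    long-duration design. Returns one row per grid cell with MI, the theta
    phase of peak gamma, and band peaks.
    """
    if base is None:
        base = NetworkConfig()
    rows = []
    for sp in pyr_levels:
        for sb in bas_levels:
            cfg = replace(
                base,
                ih_scales={"PYR": sp, "BAS": sb, "OLM": 1.0},
                wiring_seed=wiring_seed,
                input_seed=input_seed,
                duration_ms=duration_ms,
            )
            result = run_network(cfg)
            row = {"pyr_level": sp, "bas_level": sb}
            row.update(analyze_run(result))
            rows.append(row)
            if progress is not None:
                progress(row)
    return pd.DataFrame(rows)


# --------------------------- campaign bookkeeping ---------------------------

def _run_key(entry: dict) -> str:
    """Content hash of a manifest entry (stable across dict ordering)."""
    blob = json.dumps(entry, sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def run_campaign(manifest: list[dict], out_dir: str | Path,
                 base: NetworkConfig | None = None) -> pd.DataFrame:
    """Run every simulation listed in ``manifest``; resumable and idempotent.

    Each manifest entry is a mapping with optional keys ``ih_scales``,
    ``wiring_seed``, ``input_seed``, ``duration_ms``, ``population_scale``.
    Per-run summaries are stored content-addressed under ``out_dir``; a
    completed entry is never re-simulated, and re-running a finished
    manifest regenerates the identical summary table.
    """
    if base is None:
        base = NetworkConfig()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for entry in manifest:
        key = _run_key(entry)
        cache = out_dir / f"{key}.json"
        if cache.exists():
            row = json.loads(cache.read_text())
        else:
            cfg = replace(
                base,
                ih_scales={**{"PYR": 1.0, "BAS": 1.0, "OLM": 1.0},
                           **entry.get("ih_scales", {})},
                wiring_seed=int(entry.get("wiring_seed", 0)),
                input_seed=int(entry.get("input_seed", 0)),
                duration_ms=float(entry.get("duration_ms", 8000.0)),
                population_scale=float(entry.get("population_scale", 1.0)),
            )
            result = run_network(cfg)
            row = {"key": key, **entry}
            row.update(analyze_run(result))
            cache.write_text(json.dumps(row, sort_keys=True))
        rows.append(row)
    df = pd.DataFrame(rows)
    if len(df):
        df.to_csv(out_dir / "summary.csv", index=False)
    return df
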