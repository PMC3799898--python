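"""Cell construction, membrane integration, spike detection and the
isolated-cell protocols."""

import copy

import numpy as np
import pytest

from ca3net.cells import (build_cell, detect_spikes, freeze_ih, measure_psp,
                          measure_rmp, run_isolated)


class TestBuildCell:
    def test_pyr_has_five_compartments_with_ih_everywhere(self, params):
        cell = build_cell("PYR", 1.0, params)
        assert cell.n_compartments == 5
        assert all("Ih" in chans for chans in cell.channels.values())
        assert all("K_A" in chans for chans in cell.channels.values())

    def test_bas_single_compartment_with_inert_ih_at_zero_scale(self, params):
        cell = build_cell("BAS", 0.0, params)
        assert cell.n_compartments == 1
        assert "Ih" in cell.channels["soma"]
        assert cell.ih_scale == 0.0

    def test_olm_carries_calcium_machinery(self, params):
        cell = build_cell("OLM", 1.0, params)
        chans = cell.channels["soma"]
        assert {"K_Ca", "Ca_L", "Ih", "leak", "Na_t", "K_dr"} <= set(chans)

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError):
            build_cell("GRC", 1.0)
        with pytest.raises(ValueError):
            build_cell("PYR", -0.5)


class TestMembraneIntegration:
    def test_leak_only_relaxes_with_rc_time_constant(self, params):
        """With every active conductance silenced the soma follows the
        closed-form RC relaxation toward the leak reversal."""
        p = copy.deepcopy(params)
        cell = p["cells"]["BAS"]
        comp = cell["compartments"][0]
        comp["gna"] = 0.0
        comp["gkdr"] = 0.0
        cell["inj_pA"] = 0.0
        p["ih"]["BAS"]["ghbar"] = 1e-300  # validation requires > 0; inert
        res = run_isolated("BAS", 0.0, 120.0, params=p, rec_every=4)
        v = res.vrec[:, 0]
        t = res.t_rec
        el, gl, cm = cell["e_leak"], comp["g_leak"], cell["cm"]
        tau = cm / gl * 1e-3  # ms
        exact = el + (v[0] - el) * np.exp(-(t - t[0]) / tau)
        np.testing.assert_allclose(v, exact, atol=1e-5)

    def test_suprathreshold_injection_spikes(self, params):
        p = copy.deepcopy(params)
        p["cells"]["PYR"]["inj_pA"] = 500.0
        res = run_isolated("PYR", 1.0, 500.0, params=p)
        assert len(res.spikes["PYR"][1]) > 0

    def test_halving_dt_changes_rmp_little(self, params):
        a = measure_rmp("BAS", 1.0, params=params, duration_ms=3000.0, dt=0.025)
        b = measure_rmp("BAS", 1.0, params=params, duration_ms=3000.0, dt=0.0125)
        assert abs(a.rmp_mV - b.rmp_mV) < 0.05


class TestDetectSpikes:
    def test_flat_trace_empty(self):
        assert len(detect_spikes(np.full(1000, -65.0), 0.1)) == 0

    def test_three_injected_waveforms_found_at_peaks(self):
        dt = 0.1
        t = np.arange(0, 300, dt)
        v = np.full_like(t, -65.0)
        centers = [50.0, 150.0, 250.0]
        for c in centers:
            v += 90.0 * np.exp(-0.5 * ((t - c) / 0.8) ** 2)
        times = detect_spikes(v, dt)
        assert len(times) == 3
        assert np.allclose(times, centers, atol=1.0)

    def test_subthreshold_sinusoid_empty(self):
        t = np.arange(0, 1000, 0.1)
        v = -35.0 + 25.0 * np.sin(2 * np.pi * 8 * t / 1000)  # peaks at -10 mV
        assert len(detect_spikes(v, 0.1)) == 0

    def test_refractory_separation(self, rng):
        v = rng.normal(0, 30, size=5000)  # pathological noise trace
        times = detect_spikes(v, 0.1)
        if len(times) > 1:
            assert np.all(np.diff(times) >= 1.0)

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            detect_spikes(np.array([0.0, np.nan]), 0.1)


class TestIsolatedProtocols:
    def test_rmp_monotone_in_ih_scale_for_pyr_and_bas(self, params):
        for kind in ("PYR", "BAS"):
            rmps = [measure_rmp(kind, s, params=params).rmp_mV
                    for s in (0.0, 1.0, 2.0)]
            assert rmps[0] < rmps[1] < rmps[2]

    def test_ipsp_amplitude_grows_with_ih_scale(self, params):
        amps = [measure_psp("BAS", s, "GABA_A", params=params).amplitude_mV
                for s in (0.0, 1.0, 2.0)]
        assert amps[0] < amps[1] < amps[2]

    def test_epsp_shrinks_with_ih_under_na_k_block(self, params):
        """With spike currents blocked only driving force and shunting act,
        so depolarizing Ih must reduce the EPSP."""
        amps = [measure_psp("BAS", s, "AMPA", na_block=True,
                            params=params).amplitude_mV
                for s in (0.0, 1.0, 2.0)]
        assert amps[0] > amps[1] > amps[2]

    def test_zero_scale_static_and_dynamic_identical(self, params):
        dyn = measure_psp("BAS", 0.0, "AMPA", params=params)
        stat = measure_psp("BAS", 0.0, "AMPA", static_ih=True, params=params)
        assert stat.amplitude_mV == pytest.approx(dyn.amplitude_mV, abs=1e-9)
        assert stat.time_to_peak_ms == dyn.time_to_peak_ms

    def test_static_ih_epsp_larger_than_dynamic(self, params):
        """The dynamic gate closes during the EPSP and trims its peak, so
        the frozen-conductance variant overshoots the dynamic one."""
        dyn = measure_psp("BAS", 1.0, "AMPA", params=params)
        stat = measure_psp("BAS", 1.0, "AMPA", static_ih=True, params=params)
        assert stat.amplitude_mV > dyn.amplitude_mV

    def test_freeze_ih_zero_scale_is_zero(self, params):
        gfix = freeze_ih("BAS", 0.0, params=params, duration_ms=1000.0)
        assert np.all(gfix == 0.0)

    def test_static_substitution_preserves_resting_potential(self, params):
        """Replacing the relaxed gate by its frozen conductance leaves the
        resting potential in place (< 0.1 mV drift over the final second)."""
        gfix = freeze_ih("BAS", 1.0, params=params)
        res = run_isolated("BAS", 1.0, 2000.0, params=params,
                           ih_static=True, gfix=gfix, rec_every=40)
        v = res.vrec[:, 0]
        ref = measure_rmp("BAS", 1.0, params=params).rmp_mV
        assert abs(v[-1] - ref) < 0.1
        assert abs(v[-1] - v[len(v) // 2]) < 0.1
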