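"""Wiring, LFP bookkeeping, population statistics and engine-level event
delivery semantics."""

import copy

import numpy as np
import pytest

from ca3net.model import EngineSpec, run_engine
from ca3net.network import (NetworkConfig, population_rates, prepare_lfp,
                            run_network, wire_network)


@pytest.fixture(scope="module")
def full_wiring(params):
    return wire_network(NetworkConfig(), params)


class TestWiring:
    def test_total_synapse_count_152000(self, full_wiring):
        """Table convergences x population sizes: the network holds exactly
        152,000 synapses at full scale."""
        assert full_wiring.n_synapses == 152_000

    def test_bas_bas_projection(self, full_wiring):
        indptr, targets = full_wiring.csr[("BAS", "BAS")]
        assert len(targets) == 60 * 200
        # no self-edges: a presynaptic cell never targets itself
        for pre in range(200):
            assert pre not in targets[indptr[pre]: indptr[pre + 1]]

    def test_in_degrees_exact(self, full_wiring):
        for (pre, post), conv in full_wiring.convergence.items():
            assert np.all(full_wiring.in_degrees(pre, post) == conv)

    def test_same_seed_reproduces_different_seed_differs(self, params):
        a = wire_network(NetworkConfig(wiring_seed=5), params)
        b = wire_network(NetworkConfig(wiring_seed=5), params)
        c = wire_network(NetworkConfig(wiring_seed=6), params)
        for key in a.csr:
            np.testing.assert_array_equal(a.csr[key][1], b.csr[key][1])
        assert any(not np.array_equal(a.csr[k][1], c.csr[k][1]) for k in a.csr)
        # in-degree invariant holds for every seed
        for (pre, post), conv in c.convergence.items():
            assert np.all(c.in_degrees(pre, post) == conv)

    def test_infeasible_convergence_rejected(self, params):
        p = copy.deepcopy(params)
        p["populations"]["BAS"] = 30  # fewer candidates than convergence 60
        with pytest.raises(Exception):
            wire_network(NetworkConfig(), p)


class TestLfp:
    def test_prepare_trims_and_removes_dc(self):
        fs = 1000.0
        lfp = np.full(3000, 7.5)
        out = prepare_lfp(lfp, fs, trim_ms=200.0)
        assert len(out) == 3000 - 400
        assert np.allclose(out, 0.0)

    def test_sinusoid_preserved(self):
        fs = 1000.0
        t = np.arange(3000) / fs
        x = np.sin(2 * np.pi * 8 * t)
        out = prepare_lfp(x, fs, trim_ms=200.0)
        assert np.std(out) == pytest.approx(np.std(x), rel=0.05)

    def test_too_short_series_rejected(self):
        with pytest.raises(ValueError):
            prepare_lfp(np.ones(300), 1000.0, trim_ms=200.0)


class TestPopulationRates:
    def _result_with_spikes(self, params, n_cells, spikes):
        from ca3net.model import RawResult
        from ca3net.network import SimResult
        cfg = NetworkConfig(duration_ms=8000.0)
        raw = RawResult(
            dt=0.025, dt_rec=1.0, t_rec=np.arange(8000.0),
            lfp=np.zeros(8000), vrec=np.zeros((8000, 1)), rec_labels=[],
            spikes=spikes, n_cells={"PYR": 0, "BAS": n_cells, "OLM": 0},
            final_V={}, final_h={},
        )
        pops = {"PYR": 0, "BAS": n_cells, "OLM": 0}
        return SimResult(config=cfg, raw=raw, populations=pops)

    def test_zero_spikes_zero_rate(self, params):
        res = self._result_with_spikes(
            params, 200, {"PYR": (np.array([]), np.array([])),
                          "BAS": (np.array([]), np.array([])),
                          "OLM": (np.array([]), np.array([]))})
        assert population_rates(res, "BAS", trim_ms=0.0) == 0.0

    def test_fixture_arithmetic(self, params):
        # 200 cells x 8 spikes over 8 s -> 1.0 Hz
        ids = np.repeat(np.arange(200), 8)
        times = np.tile(np.linspace(500, 7500, 8), 200)
        res = self._result_with_spikes(
            params, 200, {"PYR": (np.array([]), np.array([])),
                          "BAS": (ids, times),
                          "OLM": (np.array([]), np.array([]))})
        assert population_rates(res, "BAS", trim_ms=0.0) == pytest.approx(1.0)

    def test_invariant_to_relabeling(self, params, rng):
        ids = rng.integers(0, 200, size=1000)
        times = np.sort(rng.uniform(300, 7700, size=1000))
        spikes = {"PYR": (np.array([]), np.array([])),
                  "BAS": (ids, times), "OLM": (np.array([]), np.array([]))}
        res = self._result_with_spikes(params, 200, spikes)
        shuffled = {"PYR": (np.array([]), np.array([])),
                    "BAS": ((ids + 37) % 200, times),
                    "OLM": (np.array([]), np.array([]))}
        res2 = self._result_with_spikes(params, 200, shuffled)
        assert population_rates(res, "BAS") == population_rates(res2, "BAS")


class TestEngineDelivery:
    def test_synaptic_delay_two_ms(self, params):
        """A presynaptic spike reaches its target 2 ms after emission: the
        postsynaptic membrane stays put until then."""
        p = copy.deepcopy(params)
        p["cells"]["PYR"]["inj_pA"] = 0.0
        indptr = np.array([0, 1, 1], dtype=np.int64)   # cell0 -> cell1
        targets = np.array([1], dtype=np.int64)
        spec = EngineSpec(
            params=p, n={"PYR": 2}, background=False,
            wiring={("PYR", "PYR"): (indptr, targets)},
            events=[(100.0, "PYR", 0, "soma", "AMPA", 30.0)],  # force a spike
        )
        res = run_engine(spec, 160.0, 0.025, 0, rec_every=1,
                         record=[("PYR", 0, 0), ("PYR", 1, 1)])
        _, spike_times = res.spikes["PYR"]
        assert len(spike_times) == 1
        t_spike = spike_times[0]
        # control without the event isolates the synaptic deflection from
        # the cells' intrinsic settling drift
        ctrl_spec = EngineSpec(params=p, n={"PYR": 2}, background=False,
                               wiring={("PYR", "PYR"): (indptr, targets)})
        ctrl = run_engine(ctrl_spec, 160.0, 0.025, 0, rec_every=1,
                          record=[("PYR", 0, 0), ("PYR", 1, 1)])
        dv = np.abs(res.vrec[:, 1] - ctrl.vrec[:, 1])
        t = res.t_rec
        onset = t[dv > 1e-6][0]
        assert onset == pytest.approx(t_spike + 2.0, abs=0.1)

    def test_two_simultaneous_events_superpose(self, params):
        """Receptor kinetics are linear: two co-timed events produce exactly
        twice the conductance, i.e. the sum of two single-event runs."""
        p = copy.deepcopy(params)
        p["cells"]["BAS"]["inj_pA"] = 0.0

        def deflection(weight_events):
            spec = EngineSpec(params=p, n={"BAS": 1}, background=False,
                              events=weight_events, na_block={"BAS": True})
            res = run_engine(spec, 300.0, 0.025, 0, rec_every=1)
            return res.vrec[:, 0]

        ctrl = deflection([])
        one = deflection([(150.0, "BAS", 0, "soma", "AMPA", 0.2)]) - ctrl
        two = deflection([(150.0, "BAS", 0, "soma", "AMPA", 0.2),
                          (150.0, "BAS", 0, "soma", "AMPA", 0.2)]) - ctrl
        # receptor states superpose exactly; the voltage response adds a
        # small driving-force nonlinearity, so compare at the few-percent
        # level of the deflection itself
        peak = np.abs(one).max()
        assert peak > 0.05
        np.testing.assert_allclose(two, 2 * one, atol=0.03 * peak)

    def test_run_network_reproducible(self, params):
        cfg = NetworkConfig(duration_ms=600.0, population_scale=0.05,
                            wiring_seed=3, input_seed=4)
        a = run_network(cfg)
        b = run_network(cfg)
        np.testing.assert_array_equal(a.lfp, b.lfp)
        np.testing.assert_array_equal(a.spike_trains("PYR")[1],
                                      b.spike_trains("PYR")[1])

    def test_decoupled_network_matches_isolated_cells(self, params):
        """With synapses and background off every cell behaves exactly like
        its isolated-cell protocol."""
        from ca3net.cells import run_isolated
        cfg = NetworkConfig(duration_ms=500.0, population_scale=0.02,
                            background=False, synapses=False)
        net = run_network(cfg)
        iso = run_isolated("BAS", 1.0, 500.0, params=cfg.load(), rec_every=40)
        bas_col = [i for i, lab in enumerate(net.raw.rec_labels)
                   if lab[0] == "BAS"][0]
        np.testing.assert_allclose(net.raw.vrec[:, bas_col], iso.vrec[:, 0],
                                   atol=1e-9)
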