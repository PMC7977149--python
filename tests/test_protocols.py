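"""Stimulus currents, recall subsets, snapshots, fast-forward, experiments."""

import math

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from stcnet.fixtures import generate_fixture
from stcnet.network import network_from_edges, spawn_streams
from stcnet.params import (NeuronParams, ParameterError, PlasticityParams,
                           ScheduleParams, SimulationConfig, StimulusParams,
                           TopologyParams, H0_DEFAULT)
from stcnet.protocols import (fast_forward, run_memory_experiment,
                              run_single_synapse_protocol,
                              select_recall_subset, step_stimulus_current)


class TestStimulusCurrent:
    def test_mean_drive_from_defaults(self):
        # w_stim * N_stim * f_stim = 0.420075 * 25 * 100
        assert StimulusParams().mean_drive == pytest.approx(1050.1875)

    def test_zero_weight_stays_zero(self):
        stim = StimulusParams(w_stim=0.0)
        I = 0.0
        for _ in range(100):
            I = step_stimulus_current(I, stim, NeuronParams(), True, 1.0)
        assert I == 0.0

    def test_relaxes_to_mean_drive(self):
        stim, nrn = StimulusParams(), NeuronParams()
        I = 0.0
        I = step_stimulus_current(I, stim, nrn, True, 0.0,
                                  elapsed=50 * nrn.tau_syn)
        assert I == pytest.approx(1050.1875, rel=1e-9)

    def test_inactive_decays_to_zero(self):
        stim, nrn = StimulusParams(), NeuronParams()
        out = step_stimulus_current(100.0, stim, nrn, False, 1e9,
                                    elapsed=nrn.tau_syn)
        assert out == pytest.approx(100.0 * math.exp(-1.0), rel=1e-12)


class TestRecallSubset:
    def test_half_of_default_assembly(self, rng):
        sub = select_recall_subset(np.arange(150), 0.5, rng)
        assert sub.size == 75
        assert np.all(np.isin(sub, np.arange(150)))
        assert np.unique(sub).size == 75

    def test_full_assembly(self, rng):
        assert np.array_equal(select_recall_subset(np.arange(10), 1.0, rng),
                              np.arange(10))

    def test_reproducible_from_stream(self):
        a = select_recall_subset(np.arange(150), 0.5,
                                 np.random.default_rng(4))
        b = select_recall_subset(np.arange(150), 0.5,
                                 np.random.default_rng(4))
        assert np.array_equal(a, b)

    def test_errors(self, rng):
        with pytest.raises(ValueError):
            select_recall_subset(np.empty(0), 0.5, rng)
        with pytest.raises(ValueError):
            select_recall_subset(np.arange(5), 0.0, rng)


class TestSnapshot:
    def test_save_load_continue_bit_identical(self):
        fx = generate_fixture("small_assembly", seed=9)
        net = fx.network
        net.advance(1.5)
        snap = net.state_dict()
        net.advance(1.0)
        log_a = net.spike_log
        V_a, h_a = net.V.copy(), (net.materialize() or net.h.copy())
        net.load_state(snap)
        net.advance(1.0)
        log_b = net.spike_log
        net.materialize()
        assert np.array_equal(log_a[0], log_b[0])
        assert np.array_equal(log_a[1], log_b[1])
        assert np.array_equal(V_a, net.V)
        assert np.array_equal(h_a, net.h)


class TestFastForward:
    def test_rejects_active_stimulus(self):
        fx = generate_fixture("small_assembly", seed=2)
        net = fx.network
        mask = np.zeros(net.N, bool)
        mask[:5] = True
        net.advance(0.05, stim_mask=mask, stim_active=True, stim_mean=100.0,
                    stim_sigma=1.0)
        with pytest.raises(ParameterError):
            fast_forward(net, 10.0)

    def test_early_phase_closed_form_decay(self):
        # elevation shrinks by e^-1 over 10 tau_h = 6884 s
        net = network_from_edges([(0, 1)], 2, 0,
                                 neuron=NeuronParams(sigma_wn=0.0),
                                 rngs=spawn_streams(0))
        net.h[0] = H0_DEFAULT + 0.42
        fast_forward(net, 6884.0)
        assert net.h[0] == pytest.approx(H0_DEFAULT + 0.42 * math.exp(-1),
                                         abs=1e-9)

    def test_reduced_system_matches_ode_oracle(self):
        """Fast-forward vs scipy integration of the stimulus-free reduced
        dynamics (h decay, protein with threshold drive, tagged late phase),
        on a two-synapse toy state with no threshold crossing inside the
        horizon."""
        pl = PlasticityParams(calcium_mode="network")
        net = network_from_edges([(0, 1), (2, 1)], 3, 0,
                                 neuron=NeuronParams(sigma_wn=0.0),
                                 plasticity=pl, rngs=spawn_streams(0))
        net.h[:] = [pl.h_0 + 0.35, pl.h_0 - 0.30]   # LTP- and LTD-tagged
        net.z[:] = [0.1, 0.0]
        net.p[:] = 0.0
        horizon = 1800.0

        def rhs(t, y):
            h1, h2, p, z1, z2 = y
            dev = abs(h1 - pl.h_0) + abs(h2 - pl.h_0)
            drive = pl.alpha if dev >= pl.theta_pro else 0.0
            dh1 = 0.1 * (pl.h_0 - h1) / pl.tau_h
            dh2 = 0.1 * (pl.h_0 - h2) / pl.tau_h
            dp = (-p + drive) / pl.tau_p
            tag1 = (h1 - pl.h_0) > pl.theta_tag
            tag2 = (pl.h_0 - h2) > pl.theta_tag
            dz1 = p * (1 - z1) / pl.tau_z if tag1 else 0.0
            dz2 = -p * (z2 + 0.5) / pl.tau_z if tag2 else 0.0
            return [dh1, dh2, dp, dz1, dz2]

        sol = solve_ivp(rhs, (0, horizon),
                        [net.h[0], net.h[1], 0.0, net.z[0], net.z[1]],
                        rtol=1e-10, atol=1e-12)
        fast_forward(net, horizon)
        h1, h2, p, z1, z2 = sol.y[:, -1]
        assert net.h[0] == pytest.approx(h1, abs=1e-6)
        assert net.h[1] == pytest.approx(h2, abs=1e-6)
        assert net.p[1] == pytest.approx(p, abs=1e-6)
        assert net.z[0] == pytest.approx(z1, abs=1e-6)
        assert net.z[1] == pytest.approx(z2, abs=1e-6)


class TestMemoryExperiment:
    def test_no_stimulus_leaves_weights_at_baseline(self):
        fx = generate_fixture("small_assembly", seed=21)
        cfg = fx.config.replace(stimulus=StimulusParams(w_stim=0.0, n_CA=8))
        res = run_memory_experiment(cfg, arms=("10s",), net=fx.network)
        # no drive: calcium almost never crosses theta_d, no tags, no protein
        assert np.abs(res.arms["10s"].h - H0_DEFAULT).max() < 0.02
        assert np.abs(res.arms["10s"].z).max() == 0.0

    def test_learning_strengthens_assembly_small_scale(self):
        fx = generate_fixture("small_assembly", seed=3)
        res = run_memory_experiment(fx.config, arms=("10s",),
                                    net=fx.network)
        a = res.assembly_synapses()
        others = np.setdiff1d(np.arange(res.syn_pre.size), a)
        assert res.h_post_learning[a].mean() > H0_DEFAULT
        assert res.h_post_learning[a].mean() > \
            res.h_post_learning[others].mean()

    def test_identical_seed_identical_outputs(self):
        outs = []
        for _ in range(2):
            fx = generate_fixture("small_assembly", seed=8)
            res = run_memory_experiment(fx.config, arms=("10s",),
                                        net=fx.network)
            outs.append(res)
        a, b = outs
        assert np.array_equal(a.arms["10s"].spike_times,
                              b.arms["10s"].spike_times)
        assert np.array_equal(a.arms["10s"].h, b.arms["10s"].h)
        assert np.array_equal(a.arms["10s"].recall_subset,
                              b.arms["10s"].recall_subset)


class TestSingleSynapseProtocol:
    def test_zero_rate_gives_flat_traces(self):
        cfg = SimulationConfig()
        cfg.single_synapse.f_tet = 1e-9
        r = run_single_synapse_protocol("WTET", trials=1, config=cfg, seed=0)
        assert np.allclose(r.h_mean, H0_DEFAULT)
        assert np.allclose(r.z_mean, 0.0)

    def test_unknown_protocol_rejected(self):
        with pytest.raises(ValueError):
            run_single_synapse_protocol("XTET", trials=1)

    def test_trials_must_be_positive(self):
        with pytest.raises(ValueError):
            run_single_synapse_protocol("STET", trials=0)
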