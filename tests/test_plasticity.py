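"""Calcium trace, early phase, tagging, protein synthesis and late phase."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from stcnet.network import network_from_edges, spawn_streams
from stcnet.params import NeuronParams, PlasticityParams, H0_DEFAULT
from stcnet.plasticity import (TagState, simulate_synapse_dense,
                               step_early_phase, step_late_phase,
                               step_protein, tag_state, update_calcium)


class TestCalcium:
    def test_pure_decay(self, plast_network):
        c = update_calcium(1.0, plast_network.tau_c, params=plast_network)
        assert c == pytest.approx(math.exp(-1.0), rel=1e-12)

    def test_presynaptic_jump_network_mode(self, plast_network):
        # one presynaptic spike: jump by the network-adjusted c_pre = 0.6
        assert update_calcium(0.0, 0.0, presyn_arrivals=1,
                              params=plast_network) == pytest.approx(0.6)

    def test_simultaneous_pre_and_post(self, plast_network):
        c = update_calcium(0.0, 0.0, presyn_arrivals=1, postsyn_spikes=1,
                           params=plast_network)
        assert c == pytest.approx(0.6 + 0.1655)

    def test_invitro_contributions(self, plast_invitro):
        c = update_calcium(0.0, 0.0, presyn_arrivals=1, postsyn_spikes=1,
                           params=plast_invitro)
        assert c == pytest.approx(1.0 + 0.2758)

    def test_negative_elapsed_rejected(self, plast_network):
        with pytest.raises(ValueError):
            update_calcium(1.0, -0.1, params=plast_network)


class TestEarlyPhase:
    def test_baseline_fixed_point(self, plast_network):
        h = step_early_phase(H0_DEFAULT, 0.0, 1.0, 0.0, plast_network)
        assert h == pytest.approx(H0_DEFAULT, rel=1e-12)

    def _stationary(self, c, params, n):
        h = H0_DEFAULT
        for _ in range(n):
            h = step_early_phase(h, c, 2e-4, 0.0, params)
        return h

    def test_potentiation_stationary_point(self, plast_network):
        # (0.1 h_0 + gamma_p * 1 nC) / (0.1 + gamma_p + gamma_d)
        p = plast_network
        expected = (0.1 * p.h_0 + p.gamma_p * p.h_max) \
            / (0.1 + p.gamma_p + p.gamma_d)
        assert expected == pytest.approx(0.8401, abs=2e-4)
        assert self._stationary(p.theta_p, p, 30000) == pytest.approx(
            expected, rel=1e-6)

    def test_depression_stationary_point(self, plast_network):
        p = plast_network
        expected = 0.1 * p.h_0 / (0.1 + p.gamma_d)
        assert expected == pytest.approx(1.341e-4, abs=1e-6)
        assert self._stationary(2.0, p, 150000) == pytest.approx(
            expected, abs=1e-5)

    def test_noise_gated_off_below_theta_d(self, plast_network):
        # with c < theta_d the noise amplitude is exactly zero
        a = step_early_phase(0.5, 1.0, 2e-4, +100.0, plast_network)
        b = step_early_phase(0.5, 1.0, 2e-4, -100.0, plast_network)
        assert a == b

    def test_noise_active_above_theta_d(self, plast_network):
        a = step_early_phase(0.5, 2.0, 2e-4, +1.0, plast_network)
        b = step_early_phase(0.5, 2.0, 2e-4, -1.0, plast_network)
        assert a != b

    def test_clipped_to_bounds(self, plast_network):
        assert step_early_phase(0.9, 5.0, 2e-4, +1e6, plast_network) == 1.0
        assert step_early_phase(0.1, 2.0, 2e-4, -1e6, plast_network) == 0.0


class TestTagState:
    @pytest.mark.parametrize("h,expected", [
        (H0_DEFAULT + 0.09, TagState.LTP_TAGGED),   # 0.09 > 0.0840149
        (H0_DEFAULT, TagState.UNTAGGED),
        (H0_DEFAULT - 0.09, TagState.LTD_TAGGED),
        (H0_DEFAULT + 0.08, TagState.UNTAGGED),     # below threshold
    ])
    def test_threshold_logic(self, h, expected, plast_network):
        assert tag_state(h, plast_network) is expected


class TestProtein:
    def test_sustained_drive_saturates(self, plast_network):
        p = 0.0
        for _ in range(100):
            # summed deviation 0.3 nC > theta_pro = 0.210037 nC
            p = step_protein(p, [H0_DEFAULT + 0.3], 600.0, plast_network)
        assert p == pytest.approx(plast_network.alpha, rel=1e-6)

    def test_decay_without_drive(self, plast_network):
        p = step_protein(0.5, [H0_DEFAULT], plast_network.tau_p,
                         plast_network)
        assert p == pytest.approx(0.5 * math.exp(-1.0), rel=1e-12)

    def test_zero_stays_zero(self, plast_network):
        assert step_protein(0.0, [H0_DEFAULT], 100.0, plast_network) == 0.0


class TestLatePhase:
    def test_no_protein_no_change(self, plast_network):
        for tag in TagState:
            assert step_late_phase(0.3, 0.0, tag, 1.0, plast_network) == 0.3

    def test_untagged_no_change(self, plast_network):
        assert step_late_phase(0.3, 1.0, TagState.UNTAGGED, 1.0,
                               plast_network) == 0.3

    def test_saturation_points(self, plast_network):
        assert step_late_phase(1.0, 1.0, TagState.LTP_TAGGED, 1.0,
                               plast_network) == 1.0
        assert step_late_phase(-0.5, 1.0, TagState.LTD_TAGGED, 1.0,
                               plast_network) == -0.5

    def test_direction(self, plast_network):
        assert step_late_phase(0.0, 1.0, TagState.LTP_TAGGED, 1.0,
                               plast_network) > 0
        assert step_late_phase(0.0, 1.0, TagState.LTD_TAGGED, 1.0,
                               plast_network) < 0

    def test_matches_closed_form_under_constant_drive(self, plast_network):
        # persistent LTP tag, constant p = alpha: z(t) = 1 - exp(-alpha t / tau_z)
        pl = plast_network
        dt = 0.1
        z = 0.0
        n = int(8 * 3600 / dt)
        for k in range(n):
            z = step_late_phase(z, pl.alpha, TagState.LTP_TAGGED, dt, pl)
        expected = 1.0 - math.exp(-pl.alpha * n * dt / pl.tau_z)
        assert z == pytest.approx(expected, abs=1e-3)


@settings(max_examples=30, deadline=None, derandomize=True)
@given(st.lists(st.tuples(st.floats(0, 6), st.integers(0, 3),
                          st.integers(0, 3), st.floats(-3, 3)),
                min_size=1, max_size=50))
def test_bounds_preserved_by_any_step_sequence(events):
    """h in [0, 1], z in [-0.5, 1], c >= 0, p in [0, alpha] after any steps."""
    pl = PlasticityParams(calcium_mode="invitro")
    h, z, c, p = pl.h_0, 0.0, 0.0, 0.0
    for c_extra, n_pre, n_post, noise in events:
        c = float(update_calcium(c + c_extra, 0.01, n_pre, n_post, pl))
        h = float(step_early_phase(h, c, 2e-4, noise, pl))
        p = step_protein(p, [h], 1.0, pl)
        z = step_late_phase(z, p, tag_state(h, pl), 1.0, pl)
        assert 0.0 <= h <= 1.0
        assert -0.5 <= z <= 1.0
        assert c >= 0.0
        assert 0.0 <= p <= pl.alpha


class TestKernelAgainstDenseOracle:
    """The event-driven network kernel must reproduce dense fixed-step
    integration of the same spike trains (noise switched off)."""

    def test_event_driven_equals_dense(self):
        rng = np.random.default_rng(3)
        pre_script = np.sort(rng.random(120) * 1.2)
        plast = PlasticityParams(calcium_mode="invitro", sigma_pl=0.0)
        nrn = NeuronParams(sigma_wn=0.0)
        dt = nrn.dt
        net = network_from_edges([(0, 1)], 2, 0, neuron=nrn,
                                 plasticity=plast, rngs=spawn_streams(0))
        steps = np.round(pre_script / dt).astype(np.int64)
        mon = net.advance(3.0, forced=(steps,
                                       np.zeros(len(steps), np.int32)),
                          mon_every=1, mon_syn=np.array([0]))
        times, ids = net.spike_log
        oracle = simulate_synapse_dense(times[ids == 0], times[ids == 1],
                                        3.0, plast, dt)
        k = np.round(mon[:, 0] / dt).astype(int)
        assert np.abs(mon[:, 3] - oracle.c[k]).max() < 1e-6   # calcium
        assert np.abs(mon[:, 1] - oracle.h[k]).max() < 1e-6   # early phase
        assert np.abs(mon[:, 4] - oracle.p[k]).max() < 1e-6   # protein
        assert np.abs(mon[:, 2] - oracle.z[k]).max() < 1e-6   # late phase
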