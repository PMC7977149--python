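"""Deterministic test fixtures.

Fixtures are generated programmatically — never stored as opaque binaries —
and are small enough for fast unit and end-to-end tests:

* ``two_neuron``: one plastic synapse driven by a scripted presynaptic
  Poisson train, together with the dense-integration reference trace of the
  noise-free dynamics (the brute-force oracle for the event-driven kernel).
* ``small_assembly``: a 40E/10I network with an 8-neuron assembly and a
  compressed schedule for end-to-end experiment tests.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .network import Network, build_network, network_from_edges, spawn_streams
from .params import (NeuronParams, PlasticityParams, ScheduleParams,
                     SimulationConfig, StimulusParams, TopologyParams)
from .plasticity import SynapseTrace, simulate_synapse_dense

__all__ = ["Fixture", "generate_fixture"]


@dataclass
class Fixture:
    kind: str
    seed: int
    network: Network
    config: SimulationConfig
    pre_spikes: np.ndarray | None = None       # scripted drive (two_neuron)
    oracle_trace: SynapseTrace | None = None   # dense noise-free reference
    assembly: np.ndarray | None = None         # small_assembly


def generate_fixture(kind: str, seed: int = 0) -> Fixture:
    """Build one of the deterministic fixtures (identical per seed)."""
    if kind == "two_neuron":
        cfg = SimulationConfig(
            neuron=NeuronParams(sigma_wn=0.0),
            plasticity=PlasticityParams(calcium_mode="invitro"),
            seed=seed)
        rngs = spawn_streams(seed)
        net = network_from_edges([(0, 1)], N_e=2, N_i=0, neuron=cfg.neuron,
                                 plasticity=cfg.plasticity, rngs=rngs)
        # scripted 100 Hz Poisson second of presynaptic drive
        script_rng = np.random.default_rng(np.random.SeedSequence((seed, 1)))
        n = script_rng.poisson(100.0)
        pre = np.sort(script_rng.random(n))
        oracle = simulate_synapse_dense(pre, [], duration=2.0,
                                        params=cfg.plasticity,
                                        dt=cfg.neuron.dt)
        return Fixture(kind=kind, seed=seed, network=net, config=cfg,
                       pre_spikes=pre, oracle_trace=oracle)
    if kind == "small_assembly":
        cfg = SimulationConfig(
            topology=TopologyParams(N_e=40, N_i=10, p_c=0.1),
            stimulus=StimulusParams(n_CA=8),
            schedule=ScheduleParams(settle=1.0, snapshot_time=4.0,
                                    recall_8h_time=104.0, t_learn=2.0),
            seed=seed)
        net = build_network(cfg.topology, cfg.coupling, neuron=cfg.neuron,
                            plasticity=cfg.plasticity, seed=seed)
        return Fixture(kind=kind, seed=seed, network=net, config=cfg,
                       assembly=np.arange(cfg.stimulus.n_CA))
    raise ValueError(f"unknown fixture kind {kind!r}")
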