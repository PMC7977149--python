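"""Recurrent two-population network: construction, state, and stepping.

The network holds ``N_e`` excitatory and ``N_i`` inhibitory leaky
integrate-and-fire neurons, connected independently with probability ``p_c``
(no self-connections, at most one synapse per ordered pair).  Only E->E
synapses are plastic; they carry the early-phase weight ``h``, the late-phase
weight ``z`` and a calcium trace.  Connections involving inhibitory neurons
have fixed magnitudes and inhibitory synapses act with negative sign.

Randomness is organised in five named streams spawned from one master seed
(``structure``, ``background``, ``stimulus``, ``plasticity``, ``protocol``);
identical seed and configuration give bit-identical spike logs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from . import _kernel
from .params import (CouplingParams, NeuronParams, ParameterError,
                     PlasticityParams, TopologyParams)

__all__ = [
    "RNG_STREAMS",
    "spawn_streams",
    "build_network",
    "network_from_edges",
    "Network",
    "total_weight",
    "mean_firing_rate",
    "step_background_current",
]

RNG_STREAMS = ("structure", "background", "stimulus", "plasticity", "protocol")

#: segment length (s) above which `Network.advance` splits kernel calls, to
#: bound spike-log buffer allocations
_CHUNK_S = 1.0


def spawn_streams(master_seed) -> dict[str, np.random.Generator]:
    """Five independent named generators spawned from one master seed
    (an integer or a ``numpy.random.SeedSequence``)."""
    if not isinstance(master_seed, np.random.SeedSequence):
        master_seed = np.random.SeedSequence(master_seed)
    children = master_seed.spawn(len(RNG_STREAMS))
    return {name: np.random.default_rng(seq)
            for name, seq in zip(RNG_STREAMS, children)}


def total_weight(h: float, z: float, kind: str,
                 coupling: CouplingParams) -> float:
    """Total synaptic weight (nC) by connection class.

    E->E combines the two plastic components as ``h + h_0 * z``; the other
    classes return the fixed coupling magnitude.
    """
    if kind == "EE":
        return h + coupling.h_0 * z
    if kind == "EI":
        return coupling.w_ei
    if kind == "IE":
        return coupling.w_ie
    if kind == "II":
        return coupling.w_ii
    raise ValueError(f"unknown connection class {kind!r}")


def mean_firing_rate(spike_log: tuple[np.ndarray, np.ndarray],
                     neurons: Sequence[int],
                     window: tuple[float, float]) -> float:
    """Mean rate (Hz) of a neuron set over ``[t0, t1)``.

    ``spike_log`` is a ``(times_s, neuron_ids)`` pair with nondecreasing
    times.
    """
    t0, t1 = window
    if not t1 > t0:
        raise ValueError("window must satisfy t1 > t0")
    neurons = np.asarray(list(neurons))
    if neurons.size == 0:
        raise ValueError("neuron set must be nonempty")
    times, ids = spike_log
    lo, hi = np.searchsorted(times, (t0, t1))
    n = np.isin(ids[lo:hi], neurons).sum()
    return float(n) / (neurons.size * (t1 - t0))


def step_background_current(I_bg, params: NeuronParams, noise,
                            elapsed: float | None = None):
    """Exact OU update of the background current over one interval.

    The mean relaxes to ``I_0`` with time constant ``tau_syn``; with a
    unit-normal ``noise`` draw the update reproduces the process' transition
    density exactly, giving the stationary standard deviation
    ``sigma_wn / sqrt(2 tau_syn)``.
    """
    dt = params.dt if elapsed is None else elapsed
    if dt <= 0:
        raise ValueError("elapsed must be > 0")
    decay = math.exp(-dt / params.tau_syn)
    sig = params.sigma_wn * math.sqrt((1.0 - decay * decay)
                                      / (2.0 * params.tau_syn))
    return params.I_0 + (I_bg - params.I_0) * decay + sig * np.asarray(noise)


@dataclass
class Network:
    """One network instance: parameters, topology, and full dynamic state."""

    neuron: NeuronParams
    topology: TopologyParams
    coupling: CouplingParams
    plasticity: PlasticityParams
    rngs: dict[str, np.random.Generator]

    # topology (CSR by presynaptic neuron over all connection classes, plus
    # E->E synapse indexing)
    out_indptr: np.ndarray = field(repr=False, default=None)
    out_targets: np.ndarray = field(repr=False, default=None)
    out_esyn: np.ndarray = field(repr=False, default=None)
    syn_pre: np.ndarray = field(repr=False, default=None)
    syn_post: np.ndarray = field(repr=False, default=None)
    in_indptr: np.ndarray = field(repr=False, default=None)
    in_syn: np.ndarray = field(repr=False, default=None)

    def __post_init__(self):
        self.N_e = self.topology.N_e
        self.N = self.topology.N_e + self.topology.N_i
        self._dt0 = self.neuron.dt
        self.d_ax = int(round(self.neuron.t_ax_delay / self.neuron.dt))
        self.d_ca = int(round(self.plasticity.t_c_delay / self.neuron.dt))
        if self.d_ax < 1 or self.d_ca < 1:
            raise ParameterError("delays must be at least one time step")
        self.M = int(self.syn_pre.size)
        self._init_state()

    # ------------------------------------------------------------------ state
    def _init_state(self):
        N, NE, M = self.N, self.N_e, self.M
        self.step = 0
        self.V = np.full(N, self.neuron.V_rev)
        self.ref = np.zeros(N, np.int32)
        self.I_bg = np.full(N, self.neuron.I_0)
        self.I_stim = np.zeros(N)
        self.I_syn = np.zeros(N)
        self.p = np.zeros(NE)
        self.h = np.full(M, self.coupling.h_0)
        self.z = np.zeros(M)
        self.c = np.zeros(M)
        self.last_step = np.zeros(M, np.int64)
        ring_len = max(self.d_ax, self.d_ca) + 1
        self.ring_cnt = np.zeros(ring_len, np.int32)
        self.ring_ids = np.zeros((ring_len, N), np.int32)
        self._spike_steps: list[np.ndarray] = []
        self._spike_ids: list[np.ndarray] = []
        self._rebuild_derived()

    # kernel coefficient shorthands
    @property
    def _a_c(self):
        return self.neuron.dt / self.plasticity.tau_c

    @property
    def _a_h(self):
        return 0.1 * self.neuron.dt / self.plasticity.tau_h

    def materialize(self) -> None:
        """Bring all lazily stored synapse variables up to the current step."""
        d = self.step - self.last_step
        live = d > 0
        if np.any(live):
            self.c[live] *= np.exp(-self._a_c * d[live])
            h0 = self.coupling.h_0
            self.h[live] = h0 + (self.h[live] - h0) * np.exp(
                -self._a_h * d[live])
            self.last_step[live] = self.step

    def _rebuild_derived(self) -> None:
        """Recompute active/tag lists and devsum from (h, c); tags and the
        calcium-active set are pure functions of the instantaneous state."""
        self.materialize()
        pl = self.plasticity
        M = self.M
        dev = self.h - self.coupling.h_0
        adev = np.abs(dev)
        self.devsum = np.bincount(self.syn_post, weights=adev,
                                  minlength=self.N_e).astype(float)
        self.is_active = (self.c >= pl.theta_d).astype(np.uint8)
        act = np.flatnonzero(self.is_active).astype(np.int32)
        self.act_list = np.empty(M, np.int32)
        self.act_list[:act.size] = act
        self.act_n = np.array([act.size], np.int64)
        self.tag_sign = np.zeros(M, np.int8)
        self.tag_sign[dev > pl.theta_tag] = 1
        self.tag_sign[dev < -pl.theta_tag] = -1
        tagged = np.flatnonzero(self.tag_sign != 0).astype(np.int32)
        self.in_tag_list = (self.tag_sign != 0).astype(np.uint8)
        self.tag_list = np.empty(M, np.int32)
        self.tag_list[:tagged.size] = tagged
        self.tag_n = np.array([tagged.size], np.int64)
        self.tag_expiry = np.zeros(M, np.int64)
        if tagged.size:
            expire = np.ceil(
                np.log(adev[tagged] / pl.theta_tag) / self._a_h)
            self.tag_expiry[tagged] = self.step + expire.astype(np.int64)

    # ------------------------------------------------------------- simulation
    def advance(self, duration: float, *,
                stim_mask: np.ndarray | None = None,
                stim_active: bool = False,
                stim_mean: float = 0.0,
                stim_sigma: float = 0.0,
                forced: tuple[np.ndarray, np.ndarray] | None = None,
                plasticity_on: bool = True,
                early_frozen: bool = False,
                mon_every: int = 0,
                mon_syn: np.ndarray | None = None) -> np.ndarray | None:
        """Advance the network by ``duration`` seconds of spiking simulation.

        The stimulation configuration is constant over the call.  ``forced``
        is an optional ``(steps, neuron_ids)`` pair of injected spikes with
        absolute step indices.  Returns the monitor samples (one row per
        sampling instant) when monitoring is enabled, else ``None``.
        """
        nrn = self.neuron
        if nrn.dt != self._dt0:
            raise ParameterError("dt must not change mid-simulation")
        n_steps = int(round(duration / nrn.dt))
        if n_steps <= 0:
            return None
        self._rebuild_derived()

        dt = nrn.dt
        dec_syn = math.exp(-dt / nrn.tau_syn)
        sig_bg = nrn.sigma_wn * math.sqrt(
            (1.0 - dec_syn ** 2) / (2.0 * nrn.tau_syn))
        sig_stim_step = stim_sigma * math.sqrt(
            (1.0 - dec_syn ** 2) / (2.0 * nrn.tau_syn))
        pl = self.plasticity
        ref_steps = int(round(nrn.t_ref / dt))
        mask = (np.zeros(self.N, np.uint8) if stim_mask is None
                else stim_mask.astype(np.uint8))
        if forced is None:
            fsteps = np.empty(0, np.int64)
            fids = np.empty(0, np.int32)
        else:
            fsteps = np.asarray(forced[0], np.int64)
            fids = np.asarray(forced[1], np.int32)
            order = np.argsort(fsteps, kind="stable")
            fsteps, fids = fsteps[order], fids[order]
        fptr = np.zeros(1, np.int64)

        if mon_every > 0 and mon_syn is not None and mon_syn.size:
            mon_syn = np.asarray(mon_syn, np.int32)
            mon_rows = []
        else:
            mon_every, mon_syn, mon_rows = 0, np.empty(0, np.int32), None

        chunk_steps = int(round(_CHUNK_S / dt))
        done = 0
        while done < n_steps:
            n = min(chunk_steps, n_steps - done)
            cap = self.N * (n // (ref_steps + 1) + 2)
            log_step = np.empty(cap, np.int64)
            log_id = np.empty(cap, np.int32)
            log_n = np.zeros(1, np.int64)
            if mon_every > 0:
                mbuf = np.empty((n // mon_every + 2, 1 + 4 * mon_syn.size))
            else:
                mbuf = np.empty((1, 1))
            mon_n = np.zeros(1, np.int64)
            status = _kernel.run_steps(
                self.step, n,
                self.N_e, self.N, dt, nrn.tau_mem, nrn.R, nrn.V_rev,
                nrn.V_reset, nrn.V_th, ref_steps,
                nrn.I_0, dec_syn, sig_bg, self.d_ax, self.d_ca,
                bool(stim_active), stim_mean, sig_stim_step, mask,
                bool(plasticity_on), bool(early_frozen),
                pl.c_pre, pl.c_post, self._a_c, self._a_h, self.coupling.h_0,
                pl.theta_p, pl.theta_d, pl.gamma_p, pl.gamma_d,
                dt / pl.tau_h, pl.sigma_pl * math.sqrt(dt / pl.tau_h),
                pl.h_min, pl.h_max,
                pl.theta_pro, pl.theta_tag, pl.alpha,
                math.exp(-dt / pl.tau_p), dt / pl.tau_z,
                self.coupling.w_ei, self.coupling.w_ie, self.coupling.w_ii,
                self.out_indptr, self.out_targets, self.out_esyn,
                self.in_indptr, self.in_syn, self.syn_post,
                self.V, self.ref, self.I_bg, self.I_stim, self.I_syn,
                self.p, self.devsum,
                self.h, self.z, self.c, self.last_step,
                self.is_active, self.act_list, self.act_n,
                self.tag_sign, self.tag_expiry, self.in_tag_list,
                self.tag_list, self.tag_n,
                self.ring_cnt, self.ring_ids,
                fsteps, fids, fptr,
                log_step, log_id, log_n,
                mon_every, mon_syn, mbuf, mon_n,
                self.rngs["background"], self.rngs["stimulus"],
                self.rngs["plasticity"])
            if status == _kernel.OVERFLOW:
                raise RuntimeError("spike log capacity exceeded")
            ns = int(log_n[0])
            if ns:
                self._spike_steps.append(log_step[:ns].copy())
                self._spike_ids.append(log_id[:ns].copy())
            if mon_rows is not None and int(mon_n[0]):
                mon_rows.append(mbuf[:int(mon_n[0])].copy())
            self.step += n
            done += n
        if early_frozen or not plasticity_on:
            # no plastic dynamics took place: stamp the lazy timestamps so
            # later segments do not back-apply passive decay over this span
            self.last_step[:] = self.step
        if mon_rows is not None:
            return (np.concatenate(mon_rows) if mon_rows
                    else np.empty((0, 1 + 4 * mon_syn.size)))
        return None

    # ------------------------------------------------------------- inspection
    @property
    def time(self) -> float:
        """Current simulation time (s)."""
        return self.step * self.neuron.dt

    @property
    def spike_log(self) -> tuple[np.ndarray, np.ndarray]:
        """All logged spikes so far as ``(times_s, neuron_ids)``."""
        if not self._spike_steps:
            return np.empty(0), np.empty(0, np.int32)
        steps = np.concatenate(self._spike_steps)
        ids = np.concatenate(self._spike_ids)
        return steps * self.neuron.dt, ids

    def ee_weights(self) -> np.ndarray:
        """Total weight ``h + h_0 z`` (nC) of every E->E synapse."""
        self.materialize()
        return self.h + self.coupling.h_0 * self.z

    def weight_matrix(self) -> np.ndarray:
        """Dense E->E total-weight matrix (rows presynaptic); NaN where no
        synapse exists."""
        W = np.full((self.N_e, self.N_e), np.nan)
        W[self.syn_pre, self.syn_post] = self.ee_weights()
        return W

    def realized_density(self) -> float:
        """Fraction of ordered non-self pairs that are connected."""
        return self.out_targets.size / (self.N * (self.N - 1))

    # ------------------------------------------------------------- snapshots
    def state_dict(self) -> dict:
        """Complete serialisable state; loading it continues bit-identically."""
        self.materialize()
        d = {
            "step": np.int64(self.step),
            "V": self.V.copy(), "ref": self.ref.copy(),
            "I_bg": self.I_bg.copy(), "I_stim": self.I_stim.copy(),
            "I_syn": self.I_syn.copy(), "p": self.p.copy(),
            "h": self.h.copy(), "z": self.z.copy(), "c": self.c.copy(),
            "ring_cnt": self.ring_cnt.copy(),
            "ring_ids": self.ring_ids.copy(),
            "spike_steps": (np.concatenate(self._spike_steps)
                            if self._spike_steps else np.empty(0, np.int64)),
            "spike_ids": (np.concatenate(self._spike_ids)
                          if self._spike_ids else np.empty(0, np.int32)),
        }
        for name in ("background", "stimulus", "plasticity", "protocol"):
            st = self.rngs[name].bit_generator.state
            d[f"rng_{name}_state"] = np.uint64(st["state"]["state"] & (2**64 - 1))
            d[f"rng_{name}_state_hi"] = np.uint64(st["state"]["state"] >> 64)
            d[f"rng_{name}_inc"] = np.uint64(st["state"]["inc"] & (2**64 - 1))
            d[f"rng_{name}_inc_hi"] = np.uint64(st["state"]["inc"] >> 64)
            d[f"rng_{name}_uint"] = np.uint64(st["uinteger"])
            d[f"rng_{name}_hasu"] = np.uint64(st["has_uint32"])
        return d

    def load_state(self, d: dict) -> None:
        self.step = int(d["step"])
        for name in ("V", "ref", "I_bg", "I_stim", "I_syn", "p", "h", "z",
                     "c", "ring_cnt", "ring_ids"):
            getattr(self, name)[...] = d[name]
        self.last_step[...] = self.step
        self._spike_steps = [np.asarray(d["spike_steps"], np.int64)]
        self._spike_ids = [np.asarray(d["spike_ids"], np.int32)]
        for name in ("background", "stimulus", "plasticity", "protocol"):
            gen = np.random.default_rng()
            gen.bit_generator.state = {
                "bit_generator": "PCG64",
                "state": {
                    "state": (int(d[f"rng_{name}_state_hi"]) << 64)
                    | int(d[f"rng_{name}_state"]),
                    "inc": (int(d[f"rng_{name}_inc_hi"]) << 64)
                    | int(d[f"rng_{name}_inc"]),
                },
                "has_uint32": int(d[f"rng_{name}_hasu"]),
                "uinteger": int(d[f"rng_{name}_uint"]),
            }
            self.rngs[name] = gen
        self._rebuild_derived()


def build_network(topology: TopologyParams, coupling: CouplingParams, *,
                  neuron: NeuronParams | None = None,
                  plasticity: PlasticityParams | None = None,
                  rngs: dict[str, np.random.Generator] | None = None,
                  seed: int = 0) -> Network:
    """Construct a network with independent random connectivity.

    Every ordered pair ``(j, i)`` with ``j != i`` is connected independently
    with probability ``p_c``; E->E synapses start at ``h = h_0``, ``z = 0``,
    ``c = 0``.  The realised structure is a deterministic function of the
    ``structure`` RNG stream (or of ``topology.structure_seed`` when set).
    """
    topology.validate()
    if topology.N_e == 0 or topology.N_i == 0:
        raise ParameterError("both populations must be nonempty")
    coupling.validate()
    neuron = neuron or NeuronParams()
    plasticity = plasticity or PlasticityParams()
    neuron.validate()
    plasticity.validate()
    rngs = rngs or spawn_streams(seed)
    if topology.structure_seed is not None:
        struct_rng = np.random.default_rng(topology.structure_seed)
    else:
        struct_rng = rngs["structure"]

    N = topology.N_e + topology.N_i
    NE = topology.N_e
    adj = struct_rng.random((N, N)) < topology.p_c
    np.fill_diagonal(adj, False)
    pre, post = np.nonzero(adj)         # sorted by pre, then post
    out_indptr = np.zeros(N + 1, np.int64)
    np.cumsum(np.bincount(pre, minlength=N), out=out_indptr[1:])
    out_targets = post.astype(np.int32)
    ee = (pre < NE) & (post < NE)
    out_esyn = np.full(pre.size, -1, np.int32)
    out_esyn[ee] = np.arange(int(ee.sum()), dtype=np.int32)
    syn_pre = pre[ee].astype(np.int32)
    syn_post = post[ee].astype(np.int32)
    order = np.argsort(syn_post, kind="stable").astype(np.int32)
    in_indptr = np.zeros(NE + 1, np.int64)
    np.cumsum(np.bincount(syn_post, minlength=NE), out=in_indptr[1:])
    return Network(neuron=neuron, topology=topology, coupling=coupling,
                   plasticity=plasticity, rngs=rngs,
                   out_indptr=out_indptr, out_targets=out_targets,
                   out_esyn=out_esyn, syn_pre=syn_pre, syn_post=syn_post,
                   in_indptr=in_indptr, in_syn=order)


def network_from_edges(edges: Sequence[tuple[int, int]], N_e: int, N_i: int,
                       *, neuron: NeuronParams | None = None,
                       coupling: CouplingParams | None = None,
                       plasticity: PlasticityParams | None = None,
                       rngs: dict[str, np.random.Generator] | None = None,
                       seed: int = 0) -> Network:
    """Network with an explicitly scripted connection list.

    Used for isolated-synapse experiments and tiny test fixtures.  ``edges``
    are ordered ``(presynaptic, postsynaptic)`` pairs; self-connections and
    duplicates are rejected.
    """
    N = N_e + N_i
    seen = set()
    for j, i in edges:
        if j == i:
            raise ParameterError("self-connections are not allowed")
        if not (0 <= j < N and 0 <= i < N):
            raise ParameterError("edge endpoint out of range")
        if (j, i) in seen:
            raise ParameterError("duplicate synapse between an ordered pair")
        seen.add((j, i))
    edges = sorted(edges)
    pre = np.array([e[0] for e in edges], np.int64)
    post = np.array([e[1] for e in edges], np.int64)
    out_indptr = np.zeros(N + 1, np.int64)
    np.cumsum(np.bincount(pre, minlength=N), out=out_indptr[1:])
    ee = (pre < N_e) & (post < N_e)
    out_esyn = np.full(pre.size, -1, np.int32)
    out_esyn[ee] = np.arange(int(ee.sum()), dtype=np.int32)
    syn_pre = pre[ee].astype(np.int32)
    syn_post = post[ee].astype(np.int32)
    order = np.argsort(syn_post, kind="stable").astype(np.int32)
    in_indptr = np.zeros(N_e + 1, np.int64)
    np.cumsum(np.bincount(syn_post, minlength=N_e), out=in_indptr[1:])
    return Network(neuron=neuron or NeuronParams(),
                   topology=TopologyParams(N_e=N_e, N_i=N_i, p_c=0.0),
                   coupling=coupling or CouplingParams(),
                   plasticity=plasticity or PlasticityParams(),
                   rngs=rngs or spawn_streams(seed),
                   out_indptr=out_indptr,
                   out_targets=post.astype(np.int32),
                   out_esyn=out_esyn, syn_pre=syn_pre, syn_post=syn_post,
                   in_indptr=in_indptr, in_syn=order)
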