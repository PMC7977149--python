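"""Stimulation protocols and experiment orchestration.

This module generates the learning/recall stimulus currents, runs the
settle -> learn -> snapshot -> early-recall / late-recall experiment (with an
optional intermediate recall), provides the fast-forward integrator that
skips spiking dynamics during stimulus-free hours, and implements the four
classical single-synapse induction protocols (STET, WTET, SLFS, WLFS).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np

from .network import Network, build_network, network_from_edges, spawn_streams
from .params import (NeuronParams, ParameterError, PlasticityParams,
                     SimulationConfig, SingleSynapseProtocols, StimulusParams)

log = logging.getLogger(__name__)

__all__ = [
    "step_stimulus_current",
    "select_recall_subset",
    "fast_forward",
    "MemoryExperimentResult",
    "run_memory_experiment",
    "run_standby",
    "run_single_synapse_protocol",
    "SingleSynapseResult",
]


def step_stimulus_current(I_stim, stimulus: StimulusParams,
                          neuron: NeuronParams, active: bool, noise,
                          elapsed: float | None = None):
    """Exact one-interval update of the stimulus OU current (nA).

    While ``active`` the current relaxes toward the mean drive
    ``w_stim * N_stim * f_stim`` with white-noise amplitude
    ``w_stim * sqrt(N_stim * f_stim)``; while inactive it decays to zero with
    ``tau_syn`` (no noise).
    """
    dt = neuron.dt if elapsed is None else elapsed
    decay = math.exp(-dt / neuron.tau_syn)
    if not active:
        return I_stim * decay
    mean = stimulus.mean_drive
    sig = stimulus.noise_amplitude * math.sqrt(
        (1.0 - decay * decay) / (2.0 * neuron.tau_syn))
    return mean + (I_stim - mean) * decay + sig * np.asarray(noise)


def select_recall_subset(assembly, r: float,
                         rng: np.random.Generator) -> np.ndarray:
    """Draw ``floor(r * len(assembly))`` distinct assembly members.

    The recall stimulus targets this subset; with the default ``r = 0.5`` and
    a 150-neuron assembly this is the 75 randomly drawn neurons of the
    protocol.  Reproducible from the ``protocol`` RNG stream.
    """
    assembly = np.asarray(assembly)
    if assembly.size == 0:
        raise ValueError("assembly must be nonempty")
    if not (0.0 < r <= 1.0):
        raise ValueError("r must lie in (0, 1]")
    k = int(r * assembly.size)
    return np.sort(rng.choice(assembly, size=k, replace=False))


# --------------------------------------------------------------------------
# fast-forward integration of the stimulus-free reduced system
# --------------------------------------------------------------------------

def fast_forward(net: Network, horizon: float,
                 checkpoint_interval: float = 1.0,
                 mon_syn: np.ndarray | None = None,
                 mon_stride: int = 10) -> np.ndarray | None:
    """Advance ``horizon`` seconds without spiking dynamics.

    In stimulus-free periods spikes are sparse and calcium essentially never
    reaches the depression threshold, so the full dynamics reduce to:
    closed-form relaxation of every early-phase weight toward ``h_0`` (time
    constant ``10 tau_h``), protein amounts following their exponential
    dynamics with the synthesis drive re-evaluated from the decaying weight
    deviations, and late-phase growth/decay of tagged synapses driven by the
    analytic protein integral.  States advance on a coarse grid of
    ``checkpoint_interval`` (s); threshold events (protein drive switching
    off, tags vanishing) are located in closed form inside each cell, so the
    integration is exact up to the piecewise-constant gating assumption.
    Calcium is zeroed at entry (it decays within tens of ms, negligible at
    this scale), as are the synaptic and stimulus current traces.

    Raises if a stimulus is still active.  Optionally samples monitored
    synapses every ``mon_stride`` coarse steps, returning rows
    ``[t, h, z, c, p] ...`` like the spiking kernel's monitor.
    """
    if np.max(np.abs(net.I_stim), initial=0.0) > 1e-9:
        raise ParameterError("fast_forward called while a stimulus is active")
    n_steps = int(round(horizon / net.neuron.dt))
    if n_steps <= 0:
        return None
    net.materialize()
    pl = net.plasticity
    h0 = net.coupling.h_0
    rate = 0.1 / pl.tau_h          # passive early-phase decay rate (1/s)

    net.c[:] = 0.0
    net.I_syn[:] = 0.0
    net.I_stim[:] = 0.0
    net.ring_cnt[:] = 0
    net.ref[:] = 0

    dev = net.h - h0
    adev = np.abs(dev)
    devsum = np.bincount(net.syn_post, weights=adev,
                         minlength=net.N_e).astype(float)
    tagged = np.flatnonzero(adev > pl.theta_tag)
    tag_adev = adev[tagged]
    tag_post = net.syn_post[tagged]
    tag_ltp = dev[tagged] > 0
    z_t = net.z[tagged]

    if mon_syn is not None and len(mon_syn):
        mon_syn = np.asarray(mon_syn, np.int64)
        mon_rows = []
    else:
        mon_rows = None

    p = net.p
    t = 0.0
    k = 0
    while t < horizon - 1e-12:
        d = min(checkpoint_interval, horizon - t)
        # protein: synthesis on while devsum >= theta_pro; crossing located
        # in closed form, then exact exponential in each phase
        on = devsum >= pl.theta_pro
        d_on = np.zeros(net.N_e)
        with np.errstate(divide="ignore"):
            d_on[on] = np.minimum(
                d, np.log(devsum[on] / pl.theta_pro) / rate)
        p0 = p.copy()
        pA = pl.alpha + (p0 - pl.alpha) * np.exp(-d_on / pl.tau_p)
        p[:] = pA * np.exp(-(d - d_on) / pl.tau_p)

        if tagged.size:
            # per-synapse time until the tag vanishes, capped by the cell
            d_tag = np.minimum(d, np.log(tag_adev / pl.theta_tag) / rate)
            # integral of p over [0, d_tag] with the two-phase structure
            x1 = np.minimum(d_tag, d_on[tag_post])
            P = pl.alpha * x1 + (p0[tag_post] - pl.alpha) * pl.tau_p \
                * (1.0 - np.exp(-x1 / pl.tau_p))
            x2 = np.maximum(d_tag - d_on[tag_post], 0.0)
            P += pA[tag_post] * pl.tau_p * (1.0 - np.exp(-x2 / pl.tau_p))
            g = np.exp(-P / pl.tau_z)
            z_t = np.where(tag_ltp, 1.0 - (1.0 - z_t) * g,
                           -0.5 + (z_t + 0.5) * g)
            keep = d_tag >= d - 1e-12
            if not np.all(keep):
                net.z[tagged] = z_t
                tagged = tagged[keep]
                tag_adev = tag_adev[keep]
                tag_post = tag_post[keep]
                tag_ltp = tag_ltp[keep]
                z_t = z_t[keep]
        fac = math.exp(-rate * d)
        devsum *= fac
        tag_adev *= fac
        t += d
        k += 1
        if mon_rows is not None and (k % mon_stride == 0
                                     or t >= horizon - 1e-12):
            net.z[tagged] = z_t
            row = np.empty(1 + 4 * mon_syn.size)
            row[0] = net.time + t
            hh = h0 + (net.h[mon_syn] - h0) * math.exp(-rate * t)
            row[1::4] = hh
            row[2::4] = net.z[mon_syn]
            row[3::4] = 0.0
            row[4::4] = p[net.syn_post[mon_syn]]
            mon_rows.append(row)

    net.z[tagged] = z_t
    net.h[:] = h0 + (net.h - h0) * math.exp(-rate * horizon)
    net.step += n_steps
    net.last_step[:] = net.step
    net._rebuild_derived()
    return np.array(mon_rows) if mon_rows is not None else None


# --------------------------------------------------------------------------
# learning / recall experiment
# --------------------------------------------------------------------------

@dataclass
class ArmResult:
    """Outputs of one recall arm."""

    name: str
    spike_times: np.ndarray
    spike_ids: np.ndarray
    recall_subset: np.ndarray
    t_recall: float          # measurement instant (end of recall pulse)
    h: np.ndarray            # early-phase weights just after recall
    z: np.ndarray


@dataclass
class MemoryExperimentResult:
    """Everything produced by one learning/recall experiment trial."""

    config: SimulationConfig
    assembly: np.ndarray
    syn_pre: np.ndarray
    syn_post: np.ndarray
    h_before: np.ndarray
    z_before: np.ndarray
    h_post_learning: np.ndarray     # at the snapshot time
    z_post_learning: np.ndarray
    learn_spike_times: np.ndarray   # spikes up to the snapshot time
    learn_spike_ids: np.ndarray
    arms: dict[str, ArmResult] = field(default_factory=dict)

    def assembly_synapses(self) -> np.ndarray:
        """Indices of E->E synapses with both endpoints in the assembly."""
        n = self.assembly.size
        return np.flatnonzero((self.syn_pre < n) & (self.syn_post < n))

    def mean_assembly_h(self, when: str = "post_learning") -> float:
        """Mean early-phase weight (nC) among within-assembly synapses."""
        h = {"before": self.h_before, "post_learning": self.h_post_learning,
             }.get(when)
        if h is None:
            h = self.arms[when].h
        return float(np.mean(h[self.assembly_synapses()]))

    def mean_assembly_z(self, when: str) -> float:
        z = {"before": self.z_before, "post_learning": self.z_post_learning,
             }.get(when)
        if z is None:
            z = self.arms[when].z
        return float(np.mean(z[self.assembly_synapses()]))


def _advance_with_pulse(net, cfg, t_end, mask):
    """Stimulate ``mask`` until ``t_end`` with the learning/recall OU drive."""
    stim = cfg.stimulus
    net.advance(t_end - net.time, stim_mask=mask, stim_active=True,
                stim_mean=stim.mean_drive, stim_sigma=stim.noise_amplitude)


def run_memory_experiment(config: SimulationConfig, *,
                          arms=("10s", "8h"),
                          block_early_phase_recall: bool = False,
                          net: Network | None = None
                          ) -> MemoryExperimentResult:
    """Run one full learning/consolidation/recall trial.

    Timeline: activity settles for ``schedule.settle`` seconds; the learning
    stimulus (``n_pulses`` pulses of ``pulse_len``, separated by
    ``pulse_gap``) drives the first ``n_CA`` excitatory neurons; at
    ``snapshot_time`` the complete state is saved.  The early arm ("10s")
    applies a recall pulse to a random half of the assembly immediately.  The
    late arm ("8h") reloads the snapshot, fast-forwards to
    ``resume_before`` seconds ahead of ``recall_8h_time`` (spiking is
    re-simulated from there so the measurement window is covered), and
    applies the recall pulse.  An optional intermediate recall is applied in
    the late arm without reloading afterwards, so it affects the late recall.

    With ``block_early_phase_recall`` the early-phase weights are frozen in
    the late arm after the reload (protein and late-phase dynamics continue),
    isolating the passive component of any recall improvement.
    """
    cfg = config.validate()
    sched = cfg.schedule
    if net is None:
        net = build_network(cfg.topology, cfg.coupling, neuron=cfg.neuron,
                            plasticity=cfg.plasticity, seed=cfg.seed)
    assembly = np.arange(cfg.stimulus.n_CA)
    mask = np.zeros(net.N, bool)
    mask[assembly] = True

    log.info("settle: %.1f s", sched.settle)
    net.advance(sched.settle)
    net.materialize()
    h_before, z_before = net.h.copy(), net.z.copy()

    log.info("learning: %d pulses of %.2f s to %d neurons",
             sched.n_pulses, sched.pulse_len, assembly.size)
    for t0, t1 in sched.pulse_times():
        if t0 > net.time:
            net.advance(t0 - net.time)
        _advance_with_pulse(net, cfg, t1, mask)
    net.advance(sched.snapshot_time - net.time)

    log.info("snapshot at %.1f s (%d spikes so far)", net.time,
             sum(a.size for a in net._spike_steps))
    snap = net.state_dict()
    result = MemoryExperimentResult(
        config=cfg, assembly=assembly,
        syn_pre=net.syn_pre, syn_post=net.syn_post,
        h_before=h_before, z_before=z_before,
        h_post_learning=snap["h"].copy(), z_post_learning=snap["z"].copy(),
        learn_spike_times=snap["spike_steps"] * cfg.neuron.dt,
        learn_spike_ids=snap["spike_ids"].copy())

    def finish_arm(name, subset):
        net.materialize()
        times, ids = net.spike_log
        result.arms[name] = ArmResult(
            name=name, spike_times=times, spike_ids=ids,
            recall_subset=subset, t_recall=net.time,
            h=net.h.copy(), z=net.z.copy())

    if "10s" in arms:
        subset = select_recall_subset(assembly, cfg.stimulus.r,
                                      net.rngs["protocol"])
        rmask = np.zeros(net.N, bool)
        rmask[subset] = True
        _advance_with_pulse(net, cfg, net.time + sched.recall_len, rmask)
        finish_arm("10s", subset)

    def late_arm(arm_name, frozen):
        log.info("late arm %s: reload, consolidate to %.0f s%s", arm_name,
                 sched.recall_8h_time,
                 " (early phase frozen)" if frozen else "")
        net.load_state(snap)
        events = []
        if sched.intermediate_recall is not None:
            events.append(sched.intermediate_recall)
        events.append(sched.recall_8h_time)
        subset = None
        for t_ev in events:
            lead = t_ev - sched.resume_before
            if lead > net.time:
                # allow the stimulus tail of a previous pulse to die out
                # inside full simulation before switching representations
                settle_gap = min(1.0, lead - net.time)
                net.advance(settle_gap, early_frozen=frozen)
                if lead > net.time:
                    fast_forward(net, lead - net.time)
            if net.time < t_ev:
                net.advance(t_ev - net.time, early_frozen=frozen)
            subset = select_recall_subset(assembly, cfg.stimulus.r,
                                          net.rngs["protocol"])
            rmask = np.zeros(net.N, bool)
            rmask[subset] = True
            stim = cfg.stimulus
            net.advance(sched.recall_len, stim_mask=rmask, stim_active=True,
                        stim_mean=stim.mean_drive,
                        stim_sigma=stim.noise_amplitude,
                        early_frozen=frozen)
        finish_arm(arm_name, subset)

    if "8h" in arms:
        late_arm("8h", bool(block_early_phase_recall))
    if "8h_noearly" in arms:
        late_arm("8h_noearly", True)
    return result


def run_standby(config: SimulationConfig, duration: float = 10.0) -> Network:
    """Simulate the unstimulated network (plasticity on) for ``duration``."""
    cfg = config.validate()
    net = build_network(cfg.topology, cfg.coupling, neuron=cfg.neuron,
                        plasticity=cfg.plasticity, seed=cfg.seed)
    net.advance(duration)
    return net


# --------------------------------------------------------------------------
# single-synapse induction protocols
# --------------------------------------------------------------------------

PROTOCOL_NAMES = ("STET", "WTET", "SLFS", "WLFS")


@dataclass
class SingleSynapseResult:
    """Trial-averaged traces and outcome statistics of one protocol."""

    protocol: str
    t: np.ndarray
    h_mean: np.ndarray
    h_std: np.ndarray
    z_mean: np.ndarray
    z_std: np.ndarray
    z_final: np.ndarray      # per trial, at the measurement time
    max_dev: np.ndarray      # per trial, max |h - h_0| over the trace
    max_p: np.ndarray        # per trial, max protein amount

    @property
    def w_mean(self) -> np.ndarray:
        """Trial-mean total weight h + h_0 z (h_0 from the first sample)."""
        return self.h_mean + self.h_mean[0] * self.z_mean


def _protocol_schedule(name: str, prot: SingleSynapseProtocols,
                       rng: np.random.Generator):
    """Presynaptic spike times (s) and the spans of full spiking simulation
    ``(t0, t1)`` required around them."""
    name = name.upper()
    if name == "STET":
        blocks = [(k * (prot.stet_block_len + prot.stet_block_gap),) * 1
                  for k in range(prot.stet_n_blocks)]
        starts = [b[0] for b in blocks]
        spikes = []
        for s in starts:
            n = rng.poisson(prot.f_tet * prot.stet_block_len)
            spikes.append(np.sort(s + rng.random(n) * prot.stet_block_len))
        spikes = np.concatenate(spikes)
        spans = [(s, s + prot.stet_block_len + 1.0) for s in starts]
    elif name == "WTET":
        n = rng.poisson(prot.f_tet * prot.wtet_block_len)
        spikes = np.sort(rng.random(n) * prot.wtet_block_len)
        spans = [(0.0, prot.wtet_block_len + 1.0)]
    elif name in ("SLFS", "WLFS"):
        n_burst = int(round(prot.lfs_duration * prot.lfs_burst_rate))
        if name == "SLFS":
            k, gap = prot.slfs_spikes_per_burst, prot.slfs_intra_gap
        else:
            k, gap = prot.wlfs_spikes_per_burst, prot.wlfs_intra_gap
        base = np.arange(n_burst) / prot.lfs_burst_rate
        spikes = (base[:, None] + gap * np.arange(k)[None, :]).ravel()
        spans = [(0.0, prot.lfs_duration + 1.0)]
    else:
        raise ValueError(f"unknown protocol {name!r}; "
                         f"choose from {PROTOCOL_NAMES}")
    return np.sort(spikes), spans


def run_single_synapse_protocol(name: str, trials: int = 20, *,
                                config: SimulationConfig | None = None,
                                seed: int = 0,
                                mon_dt: float = 0.05) -> SingleSynapseResult:
    """Simulate one plastic synapse between two neurons under an induction
    protocol and average over trials.

    The presynaptic neuron fires an injected spike train (Poisson tetanus or
    scripted 1 Hz bursts, see :class:`SingleSynapseProtocols`); calcium uses
    the in-vitro contributions and, by default, the background noise is
    switched off (quiet in-vitro conditions).  After the final stimulation
    span the run is fast-forwarded to the measurement time (8 h).
    """
    if trials < 1:
        raise ValueError("trials must be >= 1")
    cfg = config or SimulationConfig()
    prot = cfg.single_synapse
    neuron = replace(cfg.neuron,
                     sigma_wn=0.0 if prot.quiet_background
                     else cfg.neuron.sigma_wn)
    plast = replace(cfg.plasticity, calcium_mode="invitro")
    dt = neuron.dt

    traces_h, traces_z, t_grid = [], [], None
    z_final = np.empty(trials)
    max_dev = np.empty(trials)
    max_p = np.empty(trials)
    children = np.random.SeedSequence(seed).spawn(trials)
    mon = np.array([0])
    for trial in range(trials):
        rngs = spawn_streams(children[trial])
        net = network_from_edges([(0, 1)], N_e=2, N_i=0, neuron=neuron,
                                 coupling=cfg.coupling, plasticity=plast,
                                 rngs=rngs)
        spikes, spans = _protocol_schedule(name, prot, rngs["protocol"])
        rows = []
        for t0, t1 in spans:
            if t0 > net.time + 1e-12:
                r = fast_forward(net, t0 - net.time, mon_syn=mon,
                                 mon_stride=10)
                if r is not None and len(r):
                    rows.append(r)
            steps = np.round(spikes / dt).astype(np.int64)
            in_span = (spikes >= t0 - 1e-12) & (spikes < t1)
            r = net.advance(t1 - net.time,
                            forced=(steps[in_span],
                                    np.zeros(int(in_span.sum()), np.int32)),
                            mon_every=int(round(mon_dt / dt)), mon_syn=mon)
            rows.append(r)
        if prot.measure_at > net.time:
            r = fast_forward(net, prot.measure_at - net.time, mon_syn=mon,
                             mon_stride=10)
            if r is not None and len(r):
                rows.append(r)
        trace = np.concatenate(rows)
        if t_grid is None:
            t_grid = trace[:, 0]
        traces_h.append(trace[:, 1])
        traces_z.append(trace[:, 2])
        net.materialize()
        z_final[trial] = net.z[0]
        max_dev[trial] = np.max(np.abs(trace[:, 1] - cfg.coupling.h_0))
        max_p[trial] = np.max(trace[:, 4])
    H = np.vstack(traces_h)
    Z = np.vstack(traces_z)
    return SingleSynapseResult(
        protocol=name.upper(), t=t_grid,
        h_mean=H.mean(0), h_std=H.std(0, ddof=1) if trials > 1 else 0 * H[0],
        z_mean=Z.mean(0), z_std=Z.std(0, ddof=1) if trials > 1 else 0 * Z[0],
        z_final=z_final, max_dev=max_dev, max_p=max_p)
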