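"""Calcium-driven two-phase synaptic plasticity: pure per-synapse operations.

These functions are the reference formulation of the plasticity rule.  The
network kernel (:mod:`stcnet._kernel`) implements the same dynamics in an
event-driven, lazily evaluated form for speed; the test suite checks the two
against each other.

Model summary.  Each E->E synapse carries an early-phase weight ``h`` (nC), a
late-phase weight ``z`` (dimensionless, expressed in units of ``h_0`` in the
total weight), and a calcium trace ``c``.  Calcium decays with ``tau_c`` and
jumps by ``c_pre`` per presynaptic spike (delayed by ``t_c_delay``) and
``c_post`` per postsynaptic spike.  The early phase follows

    tau_h dh/dt = 0.1 (h_0 - h) + gamma_p (1 nC - h) Theta[c - theta_p]
                  - gamma_d h Theta[c - theta_d] + xi(t),

with calcium-gated noise ``xi``.  A deviation ``|h - h_0| > theta_tag`` marks
the synapse as tagged; if the summed incoming deviation of the postsynaptic
neuron exceeds ``theta_pro`` that neuron synthesises proteins

    tau_p dp/dt = -p + alpha Theta[sum_j |h_ji - h_0| - theta_pro],

and tag plus protein drive the late phase

    tau_z dz/dt = p (1 - z) Theta[(h - h_0) - theta_tag]
                  - p (z + 0.5) Theta[(h_0 - h) - theta_tag].

Discretisation conventions (shared with the kernel): per time step, spike
increments are added to ``c`` first, Heaviside gates are evaluated on the
post-increment calcium, the early phase takes a forward-Euler step, and
calcium then decays by ``exp(-dt/tau_c)``.  Heaviside terms use ``>=`` for
the calcium thresholds.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass

import numpy as np

from .params import PlasticityParams

__all__ = [
    "TagState",
    "update_calcium",
    "step_early_phase",
    "tag_state",
    "step_protein",
    "step_late_phase",
    "SynapseTrace",
    "simulate_synapse_dense",
]


class TagState(enum.IntEnum):
    """Tag status of a synapse, re-evaluated from ``h`` at any instant."""

    UNTAGGED = 0
    LTP_TAGGED = 1
    LTD_TAGGED = -1


def update_calcium(c, elapsed, presyn_arrivals=0, postsyn_spikes=0,
                   params: PlasticityParams | None = None):
    """Advance the calcium trace over ``elapsed`` seconds.

    Spike increments (``presyn_arrivals`` presynaptic arrivals, i.e. spikes
    whose ``t_c_delay`` has elapsed, and ``postsyn_spikes`` postsynaptic
    spikes) are applied instantaneously at the start of the interval, then
    the trace decays exponentially with ``tau_c``.
    """
    params = params or PlasticityParams()
    if np.any(np.asarray(elapsed) < 0):
        raise ValueError("elapsed must be >= 0")
    c = c + presyn_arrivals * params.c_pre + postsyn_spikes * params.c_post
    return c * np.exp(-np.asarray(elapsed) / params.tau_c)


def step_early_phase(h, c, dt, noise, params: PlasticityParams | None = None):
    """One forward-Euler step of the early-phase weight (nC).

    ``noise`` is a unit-normal draw (scalar or array); its effective
    amplitude ``sigma_pl * sqrt((Theta_p + Theta_d) dt / tau_h)`` is exactly
    zero while ``c < theta_d``.  The result is clipped to
    ``[h_min, h_max]`` (the drift confines ``h`` to this interval, the
    additive noise does not).
    """
    params = params or PlasticityParams()
    if dt <= 0:
        raise ValueError("dt must be > 0")
    h = np.asarray(h, dtype=float)
    c = np.asarray(c, dtype=float)
    on_p = (c >= params.theta_p).astype(float)
    on_d = (c >= params.theta_d).astype(float)
    drift = (0.1 * (params.h_0 - h)
             + params.gamma_p * (params.h_max - h) * on_p
             - params.gamma_d * h * on_d)
    sigma = params.sigma_pl * np.sqrt((on_p + on_d) * dt / params.tau_h)
    out = h + (dt / params.tau_h) * drift + sigma * np.asarray(noise)
    return np.clip(out, params.h_min, params.h_max)[()]


def tag_state(h, params: PlasticityParams | None = None):
    """Tag status implied by the instantaneous early-phase weight."""
    params = params or PlasticityParams()
    dev = h - params.h_0
    if dev > params.theta_tag:
        return TagState.LTP_TAGGED
    if -dev > params.theta_tag:
        return TagState.LTD_TAGGED
    return TagState.UNTAGGED


def step_protein(p, incoming_h, dt, params: PlasticityParams | None = None):
    """Advance the protein amount of one neuron over ``dt`` seconds.

    ``incoming_h`` enumerates the early-phase weights of all E->E synapses
    onto the neuron.  The synthesis drive ``alpha`` is active iff
    ``sum |h - h_0| >= theta_pro`` (held fixed over the step); the update
    toward the drive is the exact exponential with ``tau_p``.
    """
    params = params or PlasticityParams()
    dev_sum = float(np.sum(np.abs(np.asarray(incoming_h) - params.h_0)))
    target = params.alpha if dev_sum >= params.theta_pro else 0.0
    return target + (p - target) * math.exp(-dt / params.tau_p)


def step_late_phase(z, p, tag, dt, params: PlasticityParams | None = None):
    """One Euler step of the late-phase weight.

    ``z`` grows toward 1 when LTP-tagged and decays toward -0.5 when
    LTD-tagged, both at rate ``p / tau_z``; it is unchanged when untagged or
    when no proteins are available.
    """
    params = params or PlasticityParams()
    tag = TagState(tag)
    if p == 0.0 or tag is TagState.UNTAGGED:
        return z
    if tag is TagState.LTP_TAGGED:
        return z + (dt / params.tau_z) * p * (1.0 - z)
    return z - (dt / params.tau_z) * p * (z + 0.5)


@dataclass
class SynapseTrace:
    """Dense time series of one simulated synapse."""

    t: np.ndarray       # s
    h: np.ndarray       # nC
    z: np.ndarray
    c: np.ndarray
    p: np.ndarray       # protein amount of the postsynaptic neuron

    @property
    def total_weight(self) -> np.ndarray:
        """h + h_0 * z, using the baseline implied by the first h sample."""
        return self.h + self.h[0] * self.z


def simulate_synapse_dense(pre_spikes, post_spikes, duration,
                           params: PlasticityParams | None = None,
                           dt: float = 2e-4,
                           rng: np.random.Generator | None = None,
                           h0_state: float | None = None) -> SynapseTrace:
    """Dense fixed-step integration of one synapse given scripted spike trains.

    This is the brute-force oracle used to validate the event-driven network
    kernel and the fast-forward integrator: every quantity is advanced at
    every step with no lazy evaluation.  Presynaptic calcium arrivals occur
    ``t_c_delay`` after each presynaptic spike time.  With ``rng=None`` the
    plasticity noise is switched off and the trajectory is deterministic.
    """
    params = params or PlasticityParams()
    n = int(round(duration / dt))
    pre_arrival_steps = np.floor(
        (np.asarray(pre_spikes, dtype=float) + params.t_c_delay) / dt + 0.5
    ).astype(np.int64)
    post_steps = np.floor(np.asarray(post_spikes, dtype=float) / dt
                          + 0.5).astype(np.int64)
    pre_counts = np.bincount(pre_arrival_steps[pre_arrival_steps < n],
                             minlength=n)
    post_counts = np.bincount(post_steps[post_steps < n], minlength=n)

    h = params.h_0 if h0_state is None else h0_state
    z, c, p = 0.0, 0.0, 0.0
    dec_c = math.exp(-dt / params.tau_c)
    out = np.empty((n + 1, 5))
    out[0] = (0.0, h, z, c, p)
    for k in range(n):
        c += pre_counts[k] * params.c_pre + post_counts[k] * params.c_post
        noise = rng.normal() if rng is not None else 0.0
        h = float(step_early_phase(h, c, dt, noise, params))
        p = step_protein(p, (h,), dt, params)
        z = step_late_phase(z, p, tag_state(h, params), dt, params)
        c *= dec_c
        out[k + 1] = ((k + 1) * dt, h, z, c, p)
    return SynapseTrace(t=out[:, 0], h=out[:, 1], z=out[:, 2], c=out[:, 3],
                        p=out[:, 4])
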