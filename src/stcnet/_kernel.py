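"""Fixed-step simulation kernel (numba).

One call advances the network by ``n_steps`` steps of ``dt`` under a constant
stimulation configuration (the Python wrapper splits an experiment into such
segments).  Design notes:

* Membrane potentials take forward-Euler steps; the background and stimulus
  OU currents, the synaptic current traces and all exponential decays use the
  exact one-step exponential update.
* Synaptic transmission is event driven: a spike of neuron ``j`` is entered
  into a ring buffer and, ``t_ax_delay`` later, adds the synaptic weight at
  arrival time (in nC, acting as nA) to the postsynaptic current trace, which
  decays with ``tau_syn``.  Inhibitory weights enter with negative sign.
* Plastic E->E synapses are evaluated lazily.  Below the depression threshold
  ``theta_d`` the early phase has zero noise and both ``c`` and ``h`` decay as
  pure exponentials, so per-synapse state is stored together with the step at
  which it was last current and advanced in closed form only when an event
  touches the synapse.  Synapses with ``c >= theta_d`` live in an active list
  and take dense per-step stochastic Euler updates.  The two representations
  follow the same discretisation convention as
  :func:`stcnet.plasticity.simulate_synapse_dense`: spike increments first,
  Heaviside gates on the post-increment calcium, then the early-phase step,
  then calcium decay.
* ``devsum[i]`` tracks ``sum_j |h_ji - h_0|`` for every excitatory neuron
  incrementally: inactive contributions shrink by a uniform per-step factor
  (applied as one multiply), active synapses correct their own term.
* Tagged synapses (``|h - h_0| > theta_tag``) live in a second list for the
  late-phase update; tags of passively decaying synapses carry a precomputed
  closed-form expiry step.

Random numbers come from three dedicated ``numpy.random.Generator`` streams
(background, stimulus, plasticity) whose consumption order is a fixed
function of the simulation state, which makes snapshot/resume bit-exact.
"""

import math

import numpy as np
from numba import njit

__all__ = ["run_steps", "OVERFLOW"]

OVERFLOW = 1


@njit(inline="always")
def _materialize(s, step, h, c, last_step, h_0, a_c, a_h):
    """Advance lazily stored (c, h) of synapse ``s`` to ``step`` in closed form."""
    d = step - last_step[s]
    if d > 0:
        c[s] *= math.exp(-a_c * d)
        h[s] = h_0 + (h[s] - h_0) * math.exp(-a_h * d)
        last_step[s] = step


@njit(cache=True)
def run_steps(step0, n_steps,
              NE, N, dt, tau_mem, R, V_rev, V_reset, V_th, ref_steps,
              I_0, dec_syn, sig_bg, d_ax, d_ca,
              stim_active, stim_mean, sig_stim, stim_mask,
              plast_on, early_frozen,
              c_pre, c_post, a_c, a_h, h_0,
              theta_p, theta_d, gamma_p, gamma_d,
              k_h, sig_h, h_min, h_max,
              theta_pro, theta_tag, alpha, dec_p, dt_over_tau_z,
              w_ei, w_ie, w_ii,
              out_indptr, out_targets, out_esyn,
              in_indptr, in_syn, syn_post,
              V, ref, I_bg, I_stim, I_syn, p, devsum,
              h, z, c, last_step,
              is_active, act_list, act_n_arr,
              tag_sign, tag_expiry, in_tag_list, tag_list, tag_n_arr,
              ring_cnt, ring_ids,
              forced_steps, forced_ids, fptr_arr,
              log_step, log_id, log_n_arr,
              mon_every, mon_syn, mon_buf, mon_n_arr,
              rng_bg, rng_stim, rng_pl):
    ring_len = ring_cnt.shape[0]
    log_cap = log_step.shape[0]
    dec_c_step = math.exp(-a_c)
    lam_h_step = math.exp(-a_h)
    k_mem = dt / tau_mem
    plastic = plast_on and not early_frozen
    spk_buf = np.empty(N, np.int32)

    for step in range(step0, step0 + n_steps):
        ring_cnt[step % ring_len] = 0

        # -- background current: exact OU step, one draw per neuron per step
        if sig_bg > 0.0:
            for i in range(N):
                I_bg[i] = I_0 + (I_bg[i] - I_0) * dec_syn \
                    + sig_bg * rng_bg.normal(0.0, 1.0)
        else:
            for i in range(N):
                I_bg[i] = I_0 + (I_bg[i] - I_0) * dec_syn

        # -- stimulus current: OU toward the pulse mean for stimulated
        #    neurons while a pulse is active, pure decay otherwise
        if stim_active:
            for i in range(N):
                if stim_mask[i]:
                    I_stim[i] = stim_mean + (I_stim[i] - stim_mean) * dec_syn \
                        + sig_stim * rng_stim.normal(0.0, 1.0)
                else:
                    I_stim[i] *= dec_syn
        else:
            for i in range(N):
                I_stim[i] *= dec_syn

        # -- synaptic current traces: decay, then delayed spike arrivals
        for i in range(N):
            I_syn[i] *= dec_syn
        if step >= d_ax:
            slot = (step - d_ax) % ring_len
            for k in range(ring_cnt[slot]):
                j = ring_ids[slot, k]
                pre_is_e = j < NE
                for e in range(out_indptr[j], out_indptr[j + 1]):
                    tgt = out_targets[e]
                    s = out_esyn[e]
                    if s >= 0:                       # E -> E, plastic
                        if plastic:
                            _materialize(s, step, h, c, last_step,
                                         h_0, a_c, a_h)
                        I_syn[tgt] += h[s] + h_0 * z[s]
                    elif pre_is_e:                   # E -> I
                        I_syn[tgt] += w_ei
                    elif tgt < NE:                   # I -> E
                        I_syn[tgt] -= w_ie
                    else:                            # I -> I
                        I_syn[tgt] -= w_ii

        # -- presynaptically triggered calcium influx (delayed by t_c_delay)
        if plastic and step >= d_ca:
            slot = (step - d_ca) % ring_len
            for k in range(ring_cnt[slot]):
                j = ring_ids[slot, k]
                if j < NE:
                    for e in range(out_indptr[j], out_indptr[j + 1]):
                        s = out_esyn[e]
                        if s >= 0:
                            _materialize(s, step, h, c, last_step,
                                         h_0, a_c, a_h)
                            c[s] += c_pre
                            if c[s] >= theta_d and is_active[s] == 0:
                                is_active[s] = 1
                                act_list[act_n_arr[0]] = s
                                act_n_arr[0] += 1

        nspk = 0

        # -- injected (forced) spikes scheduled for this step
        nf = forced_steps.shape[0]
        while fptr_arr[0] < nf and forced_steps[fptr_arr[0]] <= step:
            if forced_steps[fptr_arr[0]] == step:
                nid = forced_ids[fptr_arr[0]]
                if ref[nid] == 0:
                    V[nid] = V_reset
                    ref[nid] = ref_steps + 1  # +1: decremented this step
                    spk_buf[nspk] = nid
                    nspk += 1
            fptr_arr[0] += 1

        # -- membrane integration and threshold crossings
        for i in range(N):
            if ref[i] > 0:
                ref[i] -= 1
                V[i] = V_reset
            else:
                V[i] += k_mem * ((V_rev - V[i])
                                 + R * (I_syn[i] + I_bg[i] + I_stim[i]))
                if V[i] > V_th:
                    V[i] = V_reset
                    ref[i] = ref_steps
                    spk_buf[nspk] = i
                    nspk += 1

        # -- spike bookkeeping: log, ring buffer, postsynaptic calcium
        for k in range(nspk):
            i = spk_buf[k]
            if log_n_arr[0] >= log_cap:
                return OVERFLOW
            log_step[log_n_arr[0]] = step
            log_id[log_n_arr[0]] = i
            log_n_arr[0] += 1
            slot = step % ring_len
            ring_ids[slot, ring_cnt[slot]] = i
            ring_cnt[slot] += 1
            if plastic and i < NE:
                for e in range(in_indptr[i], in_indptr[i + 1]):
                    s = in_syn[e]
                    _materialize(s, step, h, c, last_step, h_0, a_c, a_h)
                    c[s] += c_post
                    if c[s] >= theta_d and is_active[s] == 0:
                        is_active[s] = 1
                        act_list[act_n_arr[0]] = s
                        act_n_arr[0] += 1

        if plast_on:
            # -- early phase.  Uniform decay of all inactive |h - h_0|
            #    contributions; dense stochastic Euler for the active set.
            if not early_frozen:
                for i in range(NE):
                    devsum[i] *= lam_h_step
                idx = 0
                while idx < act_n_arr[0]:
                    s = act_list[idx]
                    cc = c[s]
                    hold = h[s]
                    drift = 0.1 * (h_0 - hold)
                    nterms = 0.0
                    if cc >= theta_p:
                        drift += gamma_p * (h_max - hold)
                        nterms += 1.0
                    if cc >= theta_d:
                        drift -= gamma_d * hold
                        nterms += 1.0
                    hn = hold + k_h * drift
                    if nterms > 0.0:
                        hn += sig_h * math.sqrt(nterms) \
                            * rng_pl.normal(0.0, 1.0)
                    if hn < h_min:
                        hn = h_min
                    elif hn > h_max:
                        hn = h_max
                    h[s] = hn
                    devsum[syn_post[s]] += abs(hn - h_0) \
                        - abs(hold - h_0) * lam_h_step
                    # tag status from the instantaneous early-phase weight
                    dev = hn - h_0
                    sign = 0
                    if dev > theta_tag:
                        sign = 1
                    elif -dev > theta_tag:
                        sign = -1
                    tag_sign[s] = sign
                    if sign != 0 and in_tag_list[s] == 0:
                        in_tag_list[s] = 1
                        tag_list[tag_n_arr[0]] = s
                        tag_n_arr[0] += 1
                    cn = cc * dec_c_step
                    c[s] = cn
                    last_step[s] = step + 1
                    if cn < theta_d:
                        is_active[s] = 0
                        act_n_arr[0] -= 1
                        act_list[idx] = act_list[act_n_arr[0]]
                        if tag_sign[s] != 0:
                            # closed-form step at which passive decay pulls
                            # |h - h_0| back below theta_tag
                            tag_expiry[s] = step + 1 + int(math.ceil(
                                math.log(abs(hn - h_0) / theta_tag) / a_h))
                        continue
                    idx += 1

            # -- protein synthesis per excitatory neuron (exact exponential)
            for i in range(NE):
                target = alpha if devsum[i] >= theta_pro else 0.0
                p[i] = target + (p[i] - target) * dec_p

            # -- late phase for tagged synapses
            idx = 0
            while idx < tag_n_arr[0]:
                s = tag_list[idx]
                drop = tag_sign[s] == 0
                if (not drop and not early_frozen and is_active[s] == 0
                        and step >= tag_expiry[s]):
                    tag_sign[s] = 0
                    drop = True
                if drop:
                    in_tag_list[s] = 0
                    tag_n_arr[0] -= 1
                    tag_list[idx] = tag_list[tag_n_arr[0]]
                    continue
                pp = p[syn_post[s]]
                if pp > 0.0:
                    if tag_sign[s] > 0:
                        z[s] += dt_over_tau_z * pp * (1.0 - z[s])
                    else:
                        z[s] -= dt_over_tau_z * pp * (z[s] + 0.5)
                idx += 1

        # -- monitored synapses: sample end-of-step values
        if mon_every > 0 and (step + 1 - step0) % mon_every == 0:
            row = mon_n_arr[0]
            mon_buf[row, 0] = (step + 1) * dt
            for m in range(mon_syn.shape[0]):
                s = mon_syn[m]
                d = (step + 1) - last_step[s]
                if d > 0 and plastic:
                    ch = c[s] * math.exp(-a_c * d)
                    hh = h_0 + (h[s] - h_0) * math.exp(-a_h * d)
                else:
                    ch = c[s]
                    hh = h[s]
                mon_buf[row, 1 + 4 * m] = hh
                mon_buf[row, 2 + 4 * m] = z[s]
                mon_buf[row, 3 + 4 * m] = ch
                mon_buf[row, 4 + 4 * m] = p[syn_post[s]]
            mon_n_arr[0] += 1

    return 0
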