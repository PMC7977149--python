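# Methods

This note documents the model, the numerical design, the default
parameters, and the limits of what the simulations show.  Internal units
are seconds, nA, nC, mV and MΩ throughout; with these, `R·I` is directly in
mV and a weight in nC acts as a current amplitude in nA.

## Neuron and network model

Neurons are leaky integrate-and-fire units: membrane time constant
`tau_mem = 10 ms`, resistance `R = 10 MΩ`, resting/reversal potential
`V_rev = −65 mV`, threshold `V_th = −55 mV`, reset `V_reset = −70 mV`
(held for the absolute refractory period `t_ref = 2 ms`).  A spike of
neuron *j* reaches its targets after the axonal delay `t_ax,delay = 3 ms`
and adds the synaptic weight `w_ji` (in nC, acting as an instantaneous
current amplitude `w_ji / 1 s` in nA) to the postsynaptic current trace,
which decays with `tau_syn = 5 ms`.  With the default `h_0 = 0.420075 nC`
this yields unitary EPSPs of ≈1 mV, a physiological scale.

The network holds `N_e = 1600` excitatory and `N_i = 400` inhibitory
neurons, every ordered pair connected independently with `p_c = 0.1` (no
self-connections, no multi-synapses).  Only E→E synapses are plastic with
total weight `h + h_0·z`; the fixed magnitudes are `w_ei = 2 h_0` and, as
the reference inhibition setting used in all default experiments,
`w_ie = w_ii = 4 h_0`.  Inhibitory synapses enter the postsynaptic current
with negative sign.  The total weight used for a spike's postsynaptic
current is the weight at arrival time, held fixed for that spike's decay
tail — weights change on time scales far slower than `tau_syn`.

Background input is an Ornstein–Uhlenbeck current per neuron (mean
`I_0 = 0.15 nA`, relaxation `tau_syn`, white-noise amplitude
`sigma_wn = 0.05 nA·s^1/2`, stationary standard deviation
`sigma_wn/sqrt(2 tau_syn) = 0.5 nA`).  Stimulation is a second OU current
with mean `w_stim·N_stim·f_stim` and noise amplitude
`w_stim·sqrt(N_stim·f_stim)` — the moment-matched diffusion description of
`N_stim = 25` input neurons firing at `f_stim = 100 Hz`.  During a learning
or recall pulse this drive (≈1050 nA) saturates the stimulated neurons at
their refractory-limited maximum rate, which is the intended regime.

With these defaults the standby network settles into a unique
self-consistent asynchronous state with a mean excitatory rate of ≈0.3 Hz
and inhibitory rate of ≈1.1 Hz.  This is at the sparse end of the
0.5–1.0 Hz range reported for hippocampal pyramidal cells during
exploratory wakefulness; the isolated-neuron rate implied by the printed
parameters (V_∞ = −63.5 mV, σ_V ≈ 2.9 mV → ≈0.3 Hz by the Rice upcrossing
estimate) shows that the band cannot be reached without altering a default,
which we deliberately do not do.  All functional results below are obtained
in this ≈0.3 Hz state.

## Plasticity model

Each E→E synapse carries calcium `c`, early-phase weight `h` and late-phase
weight `z`; each excitatory neuron carries a protein amount `p`.

* **Calcium** decays with `tau_c = 48.8 ms` and jumps by `c_pre` per
  presynaptic spike (delayed by `t_c,delay = 18.8 ms`) and `c_post` per
  postsynaptic spike.  Two parameter sets exist: in-vitro
  (`c_pre = 1`, `c_post = 0.2758`) for isolated-synapse experiments and
  network-adjusted (`0.6`, `0.1655`) for recurrent-network runs, selected
  by one configuration flag.
* **Early phase**: relaxation toward `h_0` (effective time constant
  `10·tau_h = 6884 s`), potentiation toward 1 nC at rate `gamma_p` while
  `c ≥ theta_p = 3`, depression at rate `gamma_d` while `c ≥ theta_d =
  1.2`, and calcium-gated noise of amplitude `sigma_pl` that is exactly
  zero below `theta_d`.  After each stochastic step `h` is clipped to
  [0, 1 nC]: the drift confines `h` to this interval but the additive noise
  does not, and the clip keeps the threshold logic and the closed-form
  decay well defined.
* **Tags** are not persistent state: a synapse is LTP-tagged iff
  `h − h_0 > theta_tag` and LTD-tagged iff `h_0 − h > theta_tag`,
  re-evaluated from the instantaneous `h`.
* **Protein** is synthesised at rate `alpha = 1` while the summed incoming
  deviation `Σ_j |h_ji − h_0|` of a neuron exceeds `theta_pro`, and decays
  with `tau_p = 60 min`.
* **Late phase**: `tau_z dz/dt = p(1 − z)` when LTP-tagged and
  `−p(z + 0.5)` when LTD-tagged, i.e. `z ∈ [−0.5, 1]` with movement only
  when tag and protein coincide.

## Discretisation and the event-driven kernel

The fixed step is `dt = 0.2 ms`.  Membrane potentials use forward Euler;
all linear decays (OU currents, synaptic traces, calcium, protein, passive
early-phase relaxation) use the exact one-step exponential, which is
stabler than Euler at identical cost.  The per-step convention, shared by
the dense reference integrator and the production kernel, is: spike
increments are added to `c` first, the Heaviside gates are evaluated on the
post-increment calcium, `h` takes its Euler step, then `c` decays.  The
white-noise convention `Var(Γ) = 1/dt` makes every noisy step add
`sqrt(dt)·(amplitude)·N(0,1)` after dividing the SDE by its time constant.

The production kernel exploits that below `theta_d` the synapse dynamics
are deterministic exponentials: per-synapse state is stored with a
timestamp and advanced in closed form only when a spike event touches the
synapse, while synapses with `c ≥ theta_d` live in an active list that
takes dense stochastic steps.  This is an exact reorganisation, not an
approximation — the test suite checks the kernel against brute-force dense
integration to 1e-6 (observed agreement ≈1e-12).  The per-neuron deviation
sums that gate protein synthesis are maintained incrementally (one uniform
decay factor per step plus corrections from active synapses).

Randomness is split into five named PCG64 streams spawned from one master
seed — structure, background, stimulus, plasticity, protocol — and the
number of draws per step is a fixed function of the simulation state, so a
snapshot (which serialises the stream states) resumes bit-identically.
Snapshots are single checksummed container files; spike rasters, weight
matrices and measure reports are plain delimited text.

## Experiment protocols

The default schedule: 10 s of settling; three 0.1 s learning pulses
separated by 0.4 s breaks to the first `n_CA` excitatory neurons (default
150); at 20 s the full state is saved.  The early arm applies a 0.1 s
recall pulse to `⌊r·n_CA⌋ = 75` randomly drawn assembly neurons
immediately; the late arm reloads the snapshot and recalls at 28 810 s.
Because the snapshot restores the protocol RNG stream, both arms stimulate
the same recall subset.  An optional intermediate recall is applied in the
late arm without any reload, so its consequences propagate to the 8 h
recall.  A flag freezes early-phase plasticity after the reload to isolate
the passive component of recall improvement.

For the hours between stimuli the simulator fast-forwards: calcium and the
input currents are zeroed (they decay within tens of ms), `h` follows its
closed-form decay, `p` its exponential dynamics with the synthesis drive
re-evaluated from the decaying deviation sums, and tagged synapses
integrate `z` with the analytic protein integral; threshold events (drive
switching off, tags vanishing) are located in closed form inside each 1 s
cell of the coarse grid.  Fast-forwarding one stimulus-free hour of a
50-neuron network reproduces every `h` and `z` of the full spiking
simulation to better than 1e-3.

### Single-synapse induction protocols

The four classical protocols run on a two-neuron motif with one plastic
synapse, in-vitro calcium values, and a quiet background (`sigma_wn = 0`):
with spontaneous postsynaptic firing the uncontrolled calcium contribution
would blur the weak/strong distinction that defines the protocol classes.
The presynaptic neuron fires injected spike trains:

* **STET** — three 1 s Poisson trains at 100 Hz, 600 s apart;
* **WTET** — one 0.2 s Poisson train at 100 Hz;
* **SLFS** — 900 bursts at 1 Hz, each of 3 spikes 50 ms apart;
* **WLFS** — 900 bursts at 1 Hz, each of 2 spikes 73 ms apart.

All numbers are configuration keys.  They were tuned once, before freezing,
so that the four outcome classes are produced — STET: late-phase LTP
(tag and protein threshold crossed, z(8 h) ≫ 0); WTET: early-phase-only LTP
(tag crossed on the trial-average trace, protein threshold never crossed,
z(8 h) = 0); SLFS: late-phase LTD; WLFS: early-phase-only LTD.  The weak
protocols sit by construction in the window
`theta_tag < max|h − h_0| < theta_pro`, which is narrow: for WTET the
Poisson variability means only ~70–80 % of individual trials cross the tag
threshold, while the trial-average trace does so robustly; for WLFS the
73 ms intra-burst gap places the calcium peak just above `theta_d` so that
900 bursts accumulate the right amount of depression.

## Measures of recall quality

After recall the excitatory population splits into `as` (stimulated during
learning and recall), `ans` (learning only) and `ctrl` (neither).  Rates
use a trailing 0.5 s window `[t − 0.5 s, t)` at the measurement instants
(`t_learn = 11 s`, `t_recall ∈ {20.1 s, 28 810.1 s}`), so a measurement
just after a 0.1 s pulse covers the pulse plus the 0.4 s before it without
reaching past available data.  The pattern-completion coefficient is
`Q* = (ν̄_ans − ν̄_ctrl)/ν̄_as`; across trials `Q = ⟨Q*⟩` unless the mean
fails to exceed its standard deviation, in which case `Q = 0` (robustness
zeroing).  Trials with a silent `as` subpopulation leave `Q*` undefined and
are excluded with a logged warning.

The mutual information `MI_ν = H(ν_learn) + H(ν_recall) − H(joint)` uses
plug-in entropies over the empirical discrete distribution of windowed
rates across the excitatory population: counts in a 0.5 s window are
integers, so rates are exact multiples of 2 Hz and no binning choice
enters.  The log base defaults to 2 (bits; a switch allows natural log —
relative gains are base-invariant).  Relative gains between the early and
late recall carry the propagated error
`sqrt((ΔQ(10s)·Q(8h)/Q(10s)²)² + (ΔQ(8h)/Q(10s))²)`.

## Analytic consolidation theory

For persistent tags and synthesis the late-phase equation is linear with
coefficient `p(t)` and integrates to the closed forms `z_f(t)` (general
initial state) and `z_s(t)` (from rest).  The mean early-phase weight
decays as `h_d(t) = (h̃ − h_0)·exp(−0.1(t − t_al)/tau_h) + h_0`, the tag
vanishes at `t_tag = 10·tau_h·ln(|h̃ − h_0|/theta_tag) + t_al`, and the
late phase freezes at `z̃ = z_s(t_tag)`.  The passive weight change between
early and late recall is reported under two conventions behind one flag:
the default *elevation* reading `Δw = z̃·h_0 − (h̃ − h_0)` (zero when
nothing was learned and nothing consolidated) and the literal *absolute*
reading `Δw = z̃·h_0 − h̃`; every map output records the convention used.
The improvement maps over (τ_z, τ_p) and (τ_z, α) extract the Δw = 0
separatrix by sign-change bisection of the closed form along grid edges —
no plotting machinery enters the numerical result.

## Problem sizes and reproducibility of the shipped experiments

The shipped experiments use 3 trials per condition (the robustness-zeroing
aggregate is defined from two trials up), 20 trials for single-synapse
protocols, 3 seeds for the standby baseline, and the full 1600/400 network
for all network-level results; the 50-neuron fixture is used where a small
network suffices (kernel-vs-theory equivalences, snapshot semantics,
fast-forward fidelity).  With these sizes a full learning/recall trial
including the 8 h arm takes on the order of a minute on one core.  Standard
deviations over 3 trials are reported alongside every aggregate but are,
of course, coarser than what a 10-trial study resolves.

## What the simulations do and do not show

The synthetic stimuli and the network generator emulate the study
conditions — random connectivity, OU background, putative-input-neuron
stimulation — not real recordings: there is no spatial structure, no
synaptic transmission failure, no conductance-based inhibition, no
heterogeneity across neurons.  Passing tests therefore demonstrate the
internal consistency of the model chain (spikes → calcium → two-phase
weights → recall statistics → closed-form theory), not agreement with
biological data beyond the parameter provenance.  Known limitations:

* the standby firing rate of the default network is ≈0.3 Hz, at or below
  the low end of the in-vivo range (see above);
* inhibitory synapses are static; sleep-like replay, dopamine-modulated
  thresholds and multi-protein cascades are out of scope;
* the weak induction protocols are tuned stand-ins: their pulse-level
  parameters are configuration keys, and other parameterisations inside
  the same thresholds window would serve equally.
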