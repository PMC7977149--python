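"""Parameter containers for neurons, network topology, couplings, plasticity,
stimulation and experiment schedules.

Internal unit conventions (used by every module unless a docstring says
otherwise): time in seconds, currents in nA, charges/weights in nC, membrane
potentials in mV, resistances in MOhm.  With these units ``R * I`` is directly
in mV and a synaptic weight in nC injected as an instantaneous current
amplitude of ``w / 1 s`` is directly in nA.  Configuration files carry
unit-suffixed keys (``tau_mem_ms`` etc.); :mod:`stcnet.config` converts.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace

__all__ = [
    "NeuronParams",
    "TopologyParams",
    "CouplingParams",
    "PlasticityParams",
    "StimulusParams",
    "ScheduleParams",
    "MeasureParams",
    "SingleSynapseProtocols",
    "SimulationConfig",
    "H0_DEFAULT",
]

#: Baseline excitatory-to-excitatory coupling strength (nC).  Also the
#: normalisation factor that converts the dimensionless late-phase weight
#: into charge.
H0_DEFAULT = 0.420075


class ParameterError(ValueError):
    """A parameter value violates one of the model's invariants."""


@dataclass
class NeuronParams:
    """Leaky integrate-and-fire neuron and background-input parameters.

    The membrane obeys
    ``tau_mem dV/dt = V_rev - V + R * (I_syn + I_bg + I_stim)``;
    spikes are emitted when ``V`` crosses ``V_th``, after which ``V`` is held
    at ``V_reset`` for ``t_ref``.  The background current ``I_bg`` is an
    Ornstein-Uhlenbeck process with mean ``I_0``, relaxation time ``tau_syn``
    and white-noise amplitude ``sigma_wn`` (nA sqrt(s)), giving a stationary
    standard deviation of ``sigma_wn / sqrt(2 tau_syn)``.
    """

    tau_mem: float = 10e-3      # membrane time constant (s)
    R: float = 10.0             # membrane resistance (MOhm)
    V_rev: float = -65.0        # reversal / resting potential (mV)
    V_reset: float = -70.0      # post-spike reset potential (mV)
    V_th: float = -55.0         # spike threshold (mV)
    t_ref: float = 2e-3         # absolute refractory period (s)
    tau_syn: float = 5e-3       # synaptic / input-current time constant (s)
    t_ax_delay: float = 3e-3    # axonal conduction delay (s)
    I_0: float = 0.15           # mean background current (nA)
    sigma_wn: float = 0.05      # background white-noise amplitude (nA s^1/2)
    dt: float = 2e-4            # simulation time step (s)

    def validate(self) -> None:
        for name in ("tau_mem", "tau_syn", "t_ref", "t_ax_delay", "dt"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be > 0")
        if not (self.V_reset <= self.V_rev < self.V_th):
            raise ParameterError("require V_reset <= V_rev < V_th")
        if not self.dt < self.tau_syn:
            raise ParameterError("require dt < tau_syn")
        if self.sigma_wn < 0:
            raise ParameterError("sigma_wn must be >= 0")


@dataclass
class TopologyParams:
    """Sizes and random-connectivity probability of the two populations."""

    N_e: int = 1600             # excitatory neurons
    N_i: int = 400              # inhibitory neurons
    p_c: float = 0.1            # independent connection probability
    structure_seed: int | None = None  # overrides the structure RNG stream

    def validate(self) -> None:
        if self.N_e <= 0 or self.N_i < 0:
            raise ParameterError("population sizes must be positive")
        if not (0.0 <= self.p_c <= 1.0):
            raise ParameterError("p_c must lie in [0, 1]")


@dataclass
class CouplingParams:
    """Fixed coupling strengths by connection class (nC).

    E->E synapses are plastic with total weight ``h + h_0 * z``; the three
    classes involving inhibitory neurons carry the fixed magnitudes below
    (inhibitory synapses act with negative sign on the postsynaptic current).
    ``None`` fields default to multiples of ``h_0``: ``w_ei = 2 h_0`` and, as
    the reference inhibition setting used throughout the network study,
    ``w_ie = w_ii = 4 h_0``.
    """

    h_0: float = H0_DEFAULT
    w_ei: float | None = None
    w_ie: float | None = None
    w_ii: float | None = None

    def __post_init__(self) -> None:
        if self.w_ei is None:
            self.w_ei = 2.0 * self.h_0
        if self.w_ie is None:
            self.w_ie = 4.0 * self.h_0
        if self.w_ii is None:
            self.w_ii = 4.0 * self.h_0

    def validate(self) -> None:
        for name in ("h_0", "w_ei", "w_ie", "w_ii"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be >= 0")


@dataclass
class PlasticityParams:
    """Calcium-based early phase, tagging, protein synthesis and late phase.

    The per-synapse calcium trace decays with ``tau_c`` and jumps by
    ``c_pre`` for every presynaptic spike (arriving ``t_c_delay`` after
    emission) and by ``c_post`` for every postsynaptic spike.  The early-phase
    weight ``h`` relaxes to ``h_0``, potentiates toward 1 nC above the calcium
    threshold ``theta_p`` and depresses above ``theta_d``, with
    calcium-gated noise of amplitude ``sigma_pl``.  A synapse whose deviation
    ``|h - h_0|`` exceeds ``theta_tag`` is tagged; a neuron whose summed
    incoming deviation exceeds ``theta_pro`` synthesises proteins ``p`` with
    rate ``alpha``; tag plus protein move the late-phase weight ``z``.

    ``calcium_mode`` selects the spike calcium contributions: ``"invitro"``
    uses (1, 0.2758) for isolated-synapse experiments, ``"network"`` the
    network-adjusted (0.6, 0.1655).
    """

    t_c_delay: float = 0.0188   # delay of presynaptically triggered calcium (s)
    tau_c: float = 0.0488       # calcium time constant (s)
    tau_h: float = 688.4        # early-phase time constant (s)
    tau_p: float = 3600.0       # protein time constant (s)
    tau_z: float = 3600.0       # late-phase time constant (s)
    gamma_p: float = 1645.6     # potentiation rate factor
    gamma_d: float = 313.1      # depression rate factor
    theta_p: float = 3.0        # calcium threshold for potentiation
    theta_d: float = 1.2        # calcium threshold for depression
    sigma_pl: float = 0.290436  # plasticity noise amplitude (nC s^1/2)
    alpha: float = 1.0          # protein synthesis rate
    theta_pro: float = 0.210037  # protein synthesis threshold (nC)
    theta_tag: float = 0.0840149  # tagging threshold (nC)
    h_0: float = H0_DEFAULT     # early-phase baseline / relaxation target (nC)
    calcium_mode: str = "network"
    c_pre: float = field(init=False)
    c_post: float = field(init=False)
    h_max: float = 1.0          # hard bounds for h after the noisy step (nC)
    h_min: float = 0.0

    _CALCIUM = {"invitro": (1.0, 0.2758), "network": (0.6, 0.1655)}

    def __post_init__(self) -> None:
        try:
            self.c_pre, self.c_post = self._CALCIUM[self.calcium_mode]
        except KeyError:
            raise ParameterError(
                f"calcium_mode must be one of {sorted(self._CALCIUM)}"
            ) from None

    def validate(self) -> None:
        for name in ("t_c_delay", "tau_c", "tau_h", "tau_p", "tau_z"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be > 0")
        if not self.theta_d < self.theta_p:
            raise ParameterError("require theta_d < theta_p")
        if not self.theta_tag < self.theta_pro:
            raise ParameterError("require theta_tag < theta_pro")
        for name in ("gamma_p", "gamma_d", "sigma_pl", "alpha"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be >= 0")


@dataclass
class StimulusParams:
    """Learning/recall stimulation delivered by putative input neurons.

    While a pulse is active the stimulus current follows an OU process with
    mean ``w_stim * N_stim * f_stim`` and white-noise amplitude
    ``w_stim * sqrt(N_stim * f_stim)``; outside pulses it decays to zero with
    the synaptic time constant.
    """

    w_stim: float = H0_DEFAULT  # input-synapse strength (nC)
    N_stim: int = 25            # number of putative input neurons
    f_stim: float = 100.0       # input firing frequency (Hz)
    r: float = 0.5              # fraction of the assembly stimulated at recall
    n_CA: int = 150             # assembly size (neurons receiving learning input)

    def validate(self) -> None:
        if not (0.0 < self.r <= 1.0):
            raise ParameterError("r must lie in (0, 1]")
        if self.N_stim <= 0 or self.f_stim <= 0:
            raise ParameterError("N_stim and f_stim must be > 0")
        if self.n_CA <= 0:
            raise ParameterError("n_CA must be > 0")
        if self.w_stim < 0:
            raise ParameterError("w_stim must be >= 0")

    @property
    def mean_drive(self) -> float:
        """Mean of the active stimulus OU process (nA)."""
        return self.w_stim * self.N_stim * self.f_stim

    @property
    def noise_amplitude(self) -> float:
        """White-noise amplitude of the stimulus OU process (nA s^1/2)."""
        return self.w_stim * (self.N_stim * self.f_stim) ** 0.5


@dataclass
class ScheduleParams:
    """Timing of the settle -> learn -> recall experiment (all in seconds).

    Learning consists of ``n_pulses`` stimulus pulses of ``pulse_len`` each,
    separated by ``pulse_gap`` breaks, starting at ``settle``.  The state is
    snapshotted at ``snapshot_time``; the early-recall arm applies a
    ``recall_len`` pulse immediately, the late arm reloads the snapshot and
    recalls at ``recall_8h_time``.  ``resume_before`` is the span of full
    spiking simulation re-inserted before a recall that follows a
    fast-forwarded period, so the measurement window is fully covered by
    spiking dynamics.
    """

    settle: float = 10.0
    pulse_len: float = 0.1
    pulse_gap: float = 0.4
    n_pulses: int = 3
    snapshot_time: float = 20.0
    recall_len: float = 0.1
    recall_8h_time: float = 28810.0
    t_learn: float = 11.0
    resume_before: float = 1.0
    intermediate_recall: float | None = None

    def validate(self) -> None:
        for name in ("settle", "pulse_len", "pulse_gap", "recall_len",
                     "resume_before"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be >= 0")
        learn_end = self.settle + self.n_pulses * self.pulse_len \
            + (self.n_pulses - 1) * self.pulse_gap
        if self.snapshot_time < learn_end:
            raise ParameterError("snapshot_time must follow the last pulse")
        if self.recall_8h_time <= self.snapshot_time:
            raise ParameterError("recall_8h_time must follow snapshot_time")
        if self.intermediate_recall is not None and not (
            self.snapshot_time + self.recall_len
            < self.intermediate_recall
            < self.recall_8h_time - self.resume_before
        ):
            raise ParameterError(
                "intermediate recall must fall strictly between the early "
                "and late recalls"
            )

    def pulse_times(self) -> list[tuple[float, float]]:
        """(start, end) of each learning pulse."""
        out = []
        t = self.settle
        for _ in range(self.n_pulses):
            out.append((t, t + self.pulse_len))
            t += self.pulse_len + self.pulse_gap
        return out


@dataclass
class MeasureParams:
    """Recall-quality measurement settings.

    Rates use a trailing window ``[t - window, t)`` so that a measurement at
    ``t`` just after a 0.1 s recall pulse covers the pulse plus the 0.4 s
    preceding it without reaching past available data.
    """

    window: float = 0.5         # sliding-rate window (s)
    mi_log_base: float = 2.0    # entropy log base (2 -> bits)

    def validate(self) -> None:
        if self.window <= 0:
            raise ParameterError("window must be > 0")
        if self.mi_log_base <= 1:
            raise ParameterError("mi_log_base must be > 1")


@dataclass
class SingleSynapseProtocols:
    """Induction-protocol schedules for the isolated-synapse experiments.

    Each protocol drives the presynaptic neuron with injected spikes.  The
    tetanic protocols use Poisson trains at ``f_tet`` Hz; the low-frequency
    protocols use scripted bursts repeated at 1 Hz.  Defaults were tuned once
    so that the four protocols produce their canonical outcome classes
    (late-phase LTP, early-phase-only LTP, late-phase LTD, early-phase-only
    LTD) and then frozen.
    """

    f_tet: float = 100.0          # tetanus Poisson rate (Hz)
    stet_block_len: float = 1.0   # s, per tetanus block
    stet_n_blocks: int = 3
    stet_block_gap: float = 600.0  # s between block starts minus block len
    wtet_block_len: float = 0.2   # s, single weak tetanus
    lfs_duration: float = 900.0   # s of 1 Hz burst trains
    lfs_burst_rate: float = 1.0   # Hz, burst repetition
    slfs_spikes_per_burst: int = 3
    slfs_intra_gap: float = 0.05  # s between spikes inside a strong burst
    wlfs_spikes_per_burst: int = 2
    wlfs_intra_gap: float = 0.073  # s between the two spikes of a weak burst
    measure_at: float = 28800.0   # read out z this long after protocol onset
    quiet_background: bool = True  # in-vitro: no background noise


@dataclass
class SimulationConfig:
    """Full configuration of one simulation/experiment."""

    neuron: NeuronParams = field(default_factory=NeuronParams)
    topology: TopologyParams = field(default_factory=TopologyParams)
    coupling: CouplingParams = field(default_factory=CouplingParams)
    plasticity: PlasticityParams = field(default_factory=PlasticityParams)
    stimulus: StimulusParams = field(default_factory=StimulusParams)
    schedule: ScheduleParams = field(default_factory=ScheduleParams)
    measure: MeasureParams = field(default_factory=MeasureParams)
    single_synapse: SingleSynapseProtocols = field(
        default_factory=SingleSynapseProtocols)
    seed: int = 0

    def validate(self) -> "SimulationConfig":
        for f in fields(self):
            section = getattr(self, f.name)
            if hasattr(section, "validate"):
                section.validate()
        if self.stimulus.n_CA > self.topology.N_e:
            raise ParameterError("n_CA cannot exceed N_e")
        return self

    def replace(self, **sections) -> "SimulationConfig":
        return replace(self, **sections)
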