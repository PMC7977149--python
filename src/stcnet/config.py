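"""Configuration files.

A single TOML file with sections ``[neuron]``, ``[topology]``,
``[coupling]``, ``[plasticity]``, ``[protocol]`` and ``[measure]`` configures
a run.  Every model symbol is a key carrying its unit as a suffix
(``tau_mem_ms``, ``theta_pro_nC``, ...) to keep the mixed nC/nA/ms/s units of
the model equations unambiguous; an empty file yields exactly the model's
default parameter tables.  Unknown sections or keys are rejected with the
offending key path.
"""

from __future__ import annotations

import hashlib
import math
import tomllib
from dataclasses import replace
from pathlib import Path

from .params import (CouplingParams, MeasureParams, NeuronParams,
                     ParameterError, PlasticityParams, ScheduleParams,
                     SimulationConfig, SingleSynapseProtocols,
                     StimulusParams, TopologyParams)

__all__ = ["ConfigError", "load_config", "loads_config", "dump_config",
           "dumps_config", "config_digest"]


class ConfigError(ValueError):
    """Configuration file violates the schema."""


# (section, key) -> (config attribute path, unit scale to internal units)
# Internal units: s, nA, nC, mV, MOhm.  Keys for the inhibition couplings are
# expressed as multiples of h_0, the convention used throughout the study.
_SCHEMA: dict[str, dict[str, tuple[str, float | None]]] = {
    "neuron": {
        "dt_ms": ("neuron.dt", 1e-3),
        "tau_mem_ms": ("neuron.tau_mem", 1e-3),
        "tau_syn_ms": ("neuron.tau_syn", 1e-3),
        "t_ax_delay_ms": ("neuron.t_ax_delay", 1e-3),
        "t_ref_ms": ("neuron.t_ref", 1e-3),
        "R_MOhm": ("neuron.R", 1.0),
        "V_rev_mV": ("neuron.V_rev", 1.0),
        "V_reset_mV": ("neuron.V_reset", 1.0),
        "V_th_mV": ("neuron.V_th", 1.0),
        "I_0_nA": ("neuron.I_0", 1.0),
        "sigma_wn_nA_sqrt_s": ("neuron.sigma_wn", 1.0),
    },
    "topology": {
        "N_e": ("topology.N_e", None),
        "N_i": ("topology.N_i", None),
        "p_c": ("topology.p_c", 1.0),
        "structure_seed": ("topology.structure_seed", None),
    },
    "coupling": {
        "h_0_nC": ("coupling.h_0", 1.0),
        "w_ei_h0": ("coupling.w_ei", "h0"),
        "w_ie_h0": ("coupling.w_ie", "h0"),
        "w_ii_h0": ("coupling.w_ii", "h0"),
    },
    "plasticity": {
        "t_c_delay_s": ("plasticity.t_c_delay", 1.0),
        "tau_c_s": ("plasticity.tau_c", 1.0),
        "tau_h_s": ("plasticity.tau_h", 1.0),
        "tau_p_min": ("plasticity.tau_p", 60.0),
        "tau_z_min": ("plasticity.tau_z", 60.0),
        "gamma_p": ("plasticity.gamma_p", 1.0),
        "gamma_d": ("plasticity.gamma_d", 1.0),
        "theta_p": ("plasticity.theta_p", 1.0),
        "theta_d": ("plasticity.theta_d", 1.0),
        "sigma_pl_nC_sqrt_s": ("plasticity.sigma_pl", 1.0),
        "alpha": ("plasticity.alpha", 1.0),
        "theta_pro_nC": ("plasticity.theta_pro", 1.0),
        "theta_tag_nC": ("plasticity.theta_tag", 1.0),
        "calcium_mode": ("plasticity.calcium_mode", None),
    },
    "protocol": {
        "seed": ("seed", None),
        "w_stim_nC": ("stimulus.w_stim", 1.0),
        "N_stim": ("stimulus.N_stim", None),
        "f_stim_Hz": ("stimulus.f_stim", 1.0),
        "r": ("stimulus.r", 1.0),
        "n_CA": ("stimulus.n_CA", None),
        "settle_s": ("schedule.settle", 1.0),
        "pulse_len_s": ("schedule.pulse_len", 1.0),
        "pulse_gap_s": ("schedule.pulse_gap", 1.0),
        "n_pulses": ("schedule.n_pulses", None),
        "snapshot_time_s": ("schedule.snapshot_time", 1.0),
        "recall_len_s": ("schedule.recall_len", 1.0),
        "recall_8h_time_s": ("schedule.recall_8h_time", 1.0),
        "t_learn_s": ("schedule.t_learn", 1.0),
        "resume_before_s": ("schedule.resume_before", 1.0),
        "intermediate_recall_s": ("schedule.intermediate_recall", 1.0),
        "ss_f_tet_Hz": ("single_synapse.f_tet", 1.0),
        "ss_stet_block_len_s": ("single_synapse.stet_block_len", 1.0),
        "ss_stet_n_blocks": ("single_synapse.stet_n_blocks", None),
        "ss_stet_block_gap_s": ("single_synapse.stet_block_gap", 1.0),
        "ss_wtet_block_len_s": ("single_synapse.wtet_block_len", 1.0),
        "ss_lfs_duration_s": ("single_synapse.lfs_duration", 1.0),
        "ss_lfs_burst_rate_Hz": ("single_synapse.lfs_burst_rate", 1.0),
        "ss_slfs_spikes_per_burst":
            ("single_synapse.slfs_spikes_per_burst", None),
        "ss_slfs_intra_gap_s": ("single_synapse.slfs_intra_gap", 1.0),
        "ss_wlfs_spikes_per_burst":
            ("single_synapse.wlfs_spikes_per_burst", None),
        "ss_wlfs_intra_gap_s": ("single_synapse.wlfs_intra_gap", 1.0),
        "ss_measure_at_s": ("single_synapse.measure_at", 1.0),
        "ss_quiet_background": ("single_synapse.quiet_background", None),
    },
    "measure": {
        "window_s": ("measure.window", 1.0),
        "mi_log_base": ("measure.mi_log_base", 1.0),
    },
}


def loads_config(text: str) -> SimulationConfig:
    """Parse a configuration string into a validated full configuration."""
    try:
        data = tomllib.loads(text)
    except tomllib.TOMLDecodeError as e:
        raise ConfigError(f"not valid TOML: {e}") from None
    cfg = SimulationConfig()
    sections: dict[str, dict] = {
        "neuron": {}, "topology": {}, "coupling": {}, "plasticity": {},
        "stimulus": {}, "schedule": {}, "measure": {}, "single_synapse": {},
    }
    top: dict = {}
    for sec, entries in data.items():
        if sec not in _SCHEMA:
            raise ConfigError(f"unknown section [{sec}]")
        if not isinstance(entries, dict):
            raise ConfigError(f"[{sec}] must be a table")
        for key, raw in entries.items():
            if key not in _SCHEMA[sec]:
                raise ConfigError(f"unknown key {sec}.{key}")
            path, scale = _SCHEMA[sec][key]
            if scale == "h0":
                h0 = data.get("coupling", {}).get("h_0_nC",
                                                  cfg.coupling.h_0)
                value = float(raw) * h0
            elif scale is None:
                value = raw
            else:
                if not isinstance(raw, (int, float)) or isinstance(raw, bool):
                    raise ConfigError(f"{sec}.{key} must be a number")
                value = float(raw) * scale
            if "." in path:
                subsec, fieldname = path.split(".")
                sections[subsec][fieldname] = value
            else:
                top[path] = value
    try:
        for name, overrides in sections.items():
            if overrides:
                cfg = replace(cfg, **{name: replace(getattr(cfg, name),
                                                    **overrides)})
        cfg = replace(cfg, **top)
        cfg.validate()
    except (ParameterError, TypeError) as e:
        raise ConfigError(str(e)) from None
    return cfg


def load_config(path) -> SimulationConfig:
    """Load and validate a configuration file (empty file -> all defaults)."""
    return loads_config(Path(path).read_text())


def _fmt(v) -> str:
    if isinstance(v, bool):
        return "true" if v else "false"
    if isinstance(v, int):
        return str(v)
    if isinstance(v, float):
        return repr(v)
    return f'"{v}"'


def dumps_config(cfg: SimulationConfig) -> str:
    """Serialise a configuration with every key explicit (lossless)."""
    lines = []
    for sec in ("neuron", "topology", "coupling", "plasticity", "protocol",
                "measure"):
        lines.append(f"[{sec}]")
        for key, (path, scale) in _SCHEMA[sec].items():
            if "." in path:
                subsec, fieldname = path.split(".")
                value = getattr(getattr(cfg, subsec), fieldname)
            else:
                value = getattr(cfg, path)
            if value is None:
                continue
            if scale == "h0":
                value = value / cfg.coupling.h_0
            elif scale not in (None,):
                value = value / scale
            if isinstance(value, float) and math.isclose(
                    value, round(value), rel_tol=0, abs_tol=1e-12):
                value = float(value)  # keep float formatting stable
            lines.append(f"{key} = {_fmt(value)}")
        lines.append("")
    return "\n".join(lines)


def dump_config(cfg: SimulationConfig, path) -> None:
    Path(path).write_text(dumps_config(cfg))


def config_digest(cfg: SimulationConfig) -> str:
    """Stable short digest identifying a configuration."""
    return hashlib.sha256(dumps_config(cfg).encode()).hexdigest()[:16]
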