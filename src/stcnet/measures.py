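"""Recall-performance measures.

After recall the excitatory population splits into three groups: ``as``
(assembly neurons stimulated by both the learning and the recall stimulus),
``ans`` (assembly neurons stimulated during learning only) and ``ctrl``
(the remaining excitatory neurons).  Pattern completion is quantified by

    Q* = (nu_ans - nu_ctrl) / nu_as

from the mean subpopulation rates; across trials the coefficient is averaged
with a robustness rule that zeroes means not exceeding their standard
deviation.  Independently of the predefined pattern, the mutual information
MI_nu between the per-neuron rate distributions during learning and during
recall measures how similar the recall activity state is to the learning
activity state.

Rates use a trailing sliding window; with the default 0.5 s window every
rate is an integer multiple of 2 Hz, so entropies are plug-in estimates over
the empirical discrete distribution of windowed spike counts — no binning
choices enter.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .params import MeasureParams

__all__ = [
    "PopulationPartition",
    "RecallQualityResult",
    "sliding_rate",
    "population_rates",
    "pattern_completion_Q_star",
    "aggregate_Q",
    "mutual_information_activity",
    "relative_gain",
    "recall_quality",
    "TrialAggregate",
    "aggregate_trials",
    "write_measures_report",
]

log = logging.getLogger(__name__)


@dataclass
class PopulationPartition:
    """Disjoint, exhaustive split of the excitatory population."""

    as_set: np.ndarray
    ans_set: np.ndarray
    ctrl_set: np.ndarray

    @classmethod
    def from_assembly(cls, assembly, recall_subset, n_e):
        assembly = np.asarray(assembly)
        recall_subset = np.asarray(recall_subset)
        ans = np.setdiff1d(assembly, recall_subset)
        ctrl = np.setdiff1d(np.arange(n_e), assembly)
        return cls(as_set=np.sort(recall_subset), ans_set=ans, ctrl_set=ctrl)

    def validate(self, n_e: int) -> None:
        allsets = np.concatenate([self.as_set, self.ans_set, self.ctrl_set])
        if len(np.unique(allsets)) != allsets.size or allsets.size != n_e:
            raise ValueError("partition must be disjoint and exhaustive")


@dataclass
class RecallQualityResult:
    """Subpopulation rates and recall-quality measures of one trial/arm."""

    nu_as: float
    nu_ans: float
    nu_ctrl: float
    Q_star: float | None     # None when nu_as = 0 (undefined)
    MI_nu: float


def sliding_rate(spike_log, neuron: int, t: float,
                 window: float = 0.5) -> float:
    """Firing rate (Hz) of one neuron in the trailing window ``[t-w, t)``."""
    if window <= 0:
        raise ValueError("window must be > 0")
    if t - window < -1e-12:
        raise ValueError("window reaches before the simulation start")
    times, ids = spike_log
    lo, hi = np.searchsorted(times, (t - window, t))
    return float(np.count_nonzero(ids[lo:hi] == neuron)) / window


def population_rates(spike_log, neurons, t: float,
                     window: float = 0.5) -> np.ndarray:
    """Windowed rates (Hz) of every neuron in ``neurons`` at time ``t``."""
    neurons = np.asarray(neurons)
    times, ids = spike_log
    lo, hi = np.searchsorted(times, (t - window, t))
    counts = np.bincount(ids[lo:hi].astype(np.int64),
                         minlength=int(neurons.max()) + 1 if neurons.size
                         else 0)
    return counts[neurons] / window


def pattern_completion_Q_star(nu_as: float, nu_ans: float,
                              nu_ctrl: float) -> float | None:
    """Pattern-completion coefficient ``(nu_ans - nu_ctrl) / nu_as``.

    Returns ``None`` (undefined, to be excluded from trial averages) when the
    stimulated subpopulation was silent.
    """
    if nu_as == 0:
        log.warning("Q* undefined: stimulated subpopulation is silent")
        return None
    return (nu_ans - nu_ctrl) / nu_as


def aggregate_Q(q_values) -> tuple[float, float]:
    """Trial aggregation with robustness zeroing.

    Returns ``(Q, dQ)`` where ``dQ`` is the across-trial sample standard
    deviation and ``Q`` is the trial mean unless the mean fails to exceed
    ``dQ``, in which case pattern completion is considered absent and ``Q``
    is 0.  Undefined per-trial values (``None``) are excluded.
    """
    vals = np.array([q for q in q_values if q is not None], float)
    if vals.size < 2:
        raise ValueError("need at least 2 defined trials")
    mean = float(vals.mean())
    dq = float(vals.std(ddof=1))
    return (mean if mean > dq else 0.0), dq


def _entropy(labels, base: float) -> float:
    _, counts = np.unique(labels, return_counts=True)
    pr = counts / counts.sum()
    return float(-np.sum(pr * np.log(pr)) / math.log(base))


def mutual_information_activity(rates_learn, rates_recall,
                                base: float = 2.0) -> float:
    """Plug-in mutual information between two per-neuron rate vectors.

    ``MI = H(learn) + H(recall) - H(learn, recall)`` over the empirical
    distributions across neurons; symmetric, nonnegative, and bounded by the
    smaller marginal entropy.  Base 2 gives bits.
    """
    a = np.asarray(rates_learn)
    b = np.asarray(rates_recall)
    if a.shape != b.shape:
        raise ValueError("rate vectors must have equal length")
    ha = _entropy(a, base)
    hb = _entropy(b, base)
    # joint alphabet via pairing of the two label sequences
    _, ia = np.unique(a, return_inverse=True)
    _, ib = np.unique(b, return_inverse=True)
    hab = _entropy(ia.astype(np.int64) * (ib.max() + 1) + ib, base)
    return ha + hb - hab


def relative_gain(q10: float, q8: float, dq10: float | None = None,
                  dq8: float | None = None):
    """Relative gain ``(q8 - q10) / q10`` with propagated error.

    The error combines the uncertainties of both measurements:
    ``sqrt((dq10 * q8 / q10^2)^2 + (dq8 / q10)^2)``.  Without error inputs
    only the gain is returned.
    """
    if q10 == 0:
        raise ZeroDivisionError("relative gain undefined for q10 = 0")
    gain = (q8 - q10) / q10
    if dq10 is None and dq8 is None:
        return gain
    dq10 = dq10 or 0.0
    dq8 = dq8 or 0.0
    err = math.hypot(dq10 * q8 / q10 ** 2, dq8 / q10)
    return gain, err


def recall_quality(spike_log, partition: PopulationPartition,
                   t_recall: float, t_learn: float, n_e: int,
                   measure: MeasureParams | None = None
                   ) -> RecallQualityResult:
    """Evaluate one trial/arm: subpopulation rates, Q* and MI_nu.

    Rates are taken in the trailing ``measure.window`` ending at
    ``t_recall``; the mutual information compares the excitatory
    population's rate vector at ``t_recall`` with the one at ``t_learn``.
    """
    m = measure or MeasureParams()
    exc = np.arange(n_e)
    r_recall = population_rates(spike_log, exc, t_recall, m.window)
    r_learn = population_rates(spike_log, exc, t_learn, m.window)
    nu_as = float(r_recall[partition.as_set].mean())
    nu_ans = float(r_recall[partition.ans_set].mean())
    nu_ctrl = float(r_recall[partition.ctrl_set].mean())
    return RecallQualityResult(
        nu_as=nu_as, nu_ans=nu_ans, nu_ctrl=nu_ctrl,
        Q_star=pattern_completion_Q_star(nu_as, nu_ans, nu_ctrl),
        MI_nu=mutual_information_activity(r_learn, r_recall,
                                          base=m.mi_log_base))


@dataclass
class TrialAggregate:
    """Across-trial aggregate of one arm."""

    Q: float
    dQ: float
    MI: float
    dMI: float
    per_trial: list[RecallQualityResult]


def aggregate_trials(results) -> TrialAggregate:
    """Aggregate per-trial recall-quality results of one arm."""
    results = list(results)
    Q, dQ = aggregate_Q([r.Q_star for r in results])
    mis = np.array([r.MI_nu for r in results])
    return TrialAggregate(Q=Q, dQ=dQ, MI=float(mis.mean()),
                          dMI=float(mis.std(ddof=1)) if mis.size > 1 else 0.0,
                          per_trial=results)


def write_measures_report(path, per_trial: dict[str, list],
                          reference_arm: str | None = None) -> None:
    """Tab-delimited recall-quality report.

    ``per_trial`` maps arm name to the list of per-trial
    :class:`RecallQualityResult`.  One row per (trial, arm), followed by an
    aggregate block with Q, dQ, <MI>, dMI per arm and, when a
    ``reference_arm`` is given, relative gains with propagated errors
    against it.
    """
    aggs = {arm: aggregate_trials(rs) for arm, rs in per_trial.items()}
    with open(path, "w") as f:
        f.write("trial\tarm\tnu_as_Hz\tnu_ans_Hz\tnu_ctrl_Hz\tQ_star\tMI_nu\n")
        for arm, rs in per_trial.items():
            for k, r in enumerate(rs):
                q = "nan" if r.Q_star is None else f"{r.Q_star:.6g}"
                f.write(f"{k}\t{arm}\t{r.nu_as:.6g}\t{r.nu_ans:.6g}\t"
                        f"{r.nu_ctrl:.6g}\t{q}\t{r.MI_nu:.6g}\n")
        f.write("# aggregate\n# arm\tQ\tdQ\tMI\tdMI\n")
        for arm, a in aggs.items():
            f.write(f"# {arm}\t{a.Q:.6g}\t{a.dQ:.6g}\t{a.MI:.6g}\t"
                    f"{a.dMI:.6g}\n")
        if reference_arm and reference_arm in aggs:
            ref = aggs[reference_arm]
            for arm, a in aggs.items():
                if arm == reference_arm or ref.Q == 0:
                    continue
                gq, eq = relative_gain(ref.Q, a.Q, ref.dQ, a.dQ)
                gm, em = relative_gain(ref.MI, a.MI, ref.dMI, a.dMI)
                f.write(f"# gain {reference_arm}->{arm}\t"
                        f"Q: {gq:.6g} +/- {eq:.6g}\t"
                        f"MI: {gm:.6g} +/- {em:.6g}\n")
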