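"""Closed-form consolidation dynamics and the passive-improvement criterion.

For a synapse with a persistent LTP tag and active protein synthesis, the
late-phase equation is linear with the time-dependent coefficient
``p(t) = alpha + (p_0 - alpha) exp(-t / tau_p)`` and integrates to

    z_f(t) = 1 - (1 - z_0) exp(-(tau_p (alpha - p_0) e^{-t/tau_p}
                                 + alpha t - alpha tau_p + p_0 tau_p) / tau_z)

which for ``z_0 = p_0 = 0`` reduces to

    z_s(t) = 1 - exp(-alpha (t + tau_p e^{-t/tau_p} - tau_p) / tau_z).

After learning the mean early-phase weight decays back to baseline,

    h_d(t) = (h_tilde - h_0) exp(-0.1 (t - t_al) / tau_h) + h_0,

so the tag (which requires ``|h - h_0| > theta_tag``) vanishes at

    t_tag = 10 tau_h ln(|h_tilde - h_0| / theta_tag) + t_al,

freezing the late phase at ``z_tilde = z_s(t_tag)``.  The passive weight
change between an early recall (at ``t_al``, late phase still ~0) and a late
recall (8 h, early phase decayed) is then

    dw = z_tilde * h_0 - (h_tilde - h_0);

``dw > 0`` means the passage of time alone improves the stored weight
(passive improvement), ``dw < 0`` passive deterioration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .params import H0_DEFAULT

__all__ = [
    "TheoryParams",
    "TagNeverSetError",
    "z_full",
    "z_simple",
    "h_decay",
    "tag_vanishing_time",
    "z_with_tag_cutoff",
    "z_tilde",
    "passive_weight_change",
    "improvement_map",
    "ImprovementMap",
]


class TagNeverSetError(ValueError):
    """The post-learning elevation never reached the tagging threshold."""


@dataclass
class TheoryParams:
    """Inputs to the closed-form consolidation expressions.

    ``h_tilde`` is the mean early-phase weight measured at ``t_al`` seconds
    after learning (absolute value, nC).  Time constants in seconds.
    """

    tau_p: float = 3600.0
    tau_z: float = 3600.0
    alpha: float = 1.0
    p_0: float = 0.0
    z_0: float = 0.0
    h_tilde: float = 2 * H0_DEFAULT
    h_0: float = H0_DEFAULT
    theta_tag: float = 0.0840149
    tau_h: float = 688.4
    t_al: float = 10.0

    def replace(self, **kw) -> "TheoryParams":
        return replace(self, **kw)


def z_full(t, params: TheoryParams):
    """Late-phase weight under a persistent tag with general initial state."""
    pr = params
    t = np.asarray(t, float)
    ex = (pr.tau_p * (pr.alpha - pr.p_0) * np.exp(-t / pr.tau_p)
          + pr.alpha * t - pr.alpha * pr.tau_p + pr.p_0 * pr.tau_p)
    return (1.0 - (1.0 - pr.z_0) * np.exp(-ex / pr.tau_z))[()]


def z_simple(t, params: TheoryParams):
    """Late-phase weight from rest (``z_0 = p_0 = 0``), persistent tag."""
    pr = params
    t = np.asarray(t, float)
    ex = pr.alpha * (t + pr.tau_p * np.exp(-t / pr.tau_p) - pr.tau_p)
    return (1.0 - np.exp(-ex / pr.tau_z))[()]


def h_decay(t, params: TheoryParams):
    """Mean early-phase weight decaying back to ``h_0`` from ``t_al`` on."""
    pr = params
    t = np.asarray(t, float)
    if np.any(t < pr.t_al):
        raise ValueError("h_decay is defined for t >= t_al")
    return ((pr.h_tilde - pr.h_0)
            * np.exp(-0.1 * (t - pr.t_al) / pr.tau_h) + pr.h_0)[()]


def tag_vanishing_time(params: TheoryParams) -> float:
    """Time at which the decaying elevation reaches the tagging threshold."""
    pr = params
    dev = abs(pr.h_tilde - pr.h_0)
    if dev < pr.theta_tag:
        raise TagNeverSetError(
            "elevation below theta_tag: the tag is never set")
    return 10.0 * pr.tau_h * math.log(dev / pr.theta_tag) + pr.t_al


def z_with_tag_cutoff(t, params: TheoryParams):
    """``z_simple`` frozen once the tag has vanished."""
    t_tag = tag_vanishing_time(params)
    return z_simple(np.minimum(np.asarray(t, float), t_tag), params)


def z_tilde(params: TheoryParams) -> float:
    """Frozen late-phase value ``z_s(t_tag)`` (valid when t_tag < 8 h)."""
    return float(z_simple(tag_vanishing_time(params), params))


def passive_weight_change(params: TheoryParams,
                          convention: str = "elevation") -> float:
    """Passive total-weight change ``dw`` between early and late recall (nC).

    ``convention`` resolves what the early-phase symbol in
    ``dw = z_tilde h_0 - h_tilde`` denotes:

    * ``"elevation"`` (default): ``h_tilde`` enters as the elevation above
      baseline, ``dw = z_tilde h_0 - (h_tilde - h_0)``.  This makes ``dw = 0``
      when nothing was learned and nothing consolidated.
    * ``"absolute"``: the literal reading with the absolute weight,
      ``dw = z_tilde h_0 - h_tilde``.
    """
    pr = params
    try:
        zt = z_tilde(pr)
    except TagNeverSetError:
        zt = 0.0
    if convention == "elevation":
        return zt * pr.h_0 - (pr.h_tilde - pr.h_0)
    if convention == "absolute":
        return zt * pr.h_0 - pr.h_tilde
    raise ValueError("convention must be 'elevation' or 'absolute'")


@dataclass
class ImprovementMap:
    """Signed passive-weight-change surface with its zero-level separatrix."""

    x_name: str          # always "tau_z"
    y_name: str          # "tau_p" or "alpha"
    x: np.ndarray
    y: np.ndarray
    dw: np.ndarray       # shape (len(y), len(x))
    separatrix: np.ndarray  # (k, 2) polyline points (x, y); may be empty
    convention: str


def _dw_at(params, x, y, y_name, convention):
    return passive_weight_change(
        params.replace(tau_z=x, **{y_name: y}), convention)


def improvement_map(params: TheoryParams, tau_z_grid, other_grid,
                    other: str = "tau_p",
                    convention: str = "elevation") -> ImprovementMap:
    """Evaluate ``dw`` over a (tau_z, tau_p) or (tau_z, alpha) grid.

    The zero-level separatrix between the improvement (``dw > 0``) and
    deterioration regimes is extracted by sign-change bisection of the
    closed-form ``dw`` along grid edges (no plotting machinery involved).
    """
    if other not in ("tau_p", "alpha"):
        raise ValueError("other must be 'tau_p' or 'alpha'")
    xs = np.asarray(tau_z_grid, float)
    ys = np.asarray(other_grid, float)
    if np.any(xs <= 0) or np.any(ys <= 0):
        raise ValueError("grid values must be > 0")
    dw = np.array([[_dw_at(params, x, y, other, convention) for x in xs]
                   for y in ys])

    def bisect(fixed, lo, hi, along_x):
        for _ in range(60):
            mid = 0.5 * (lo + hi)
            v = (_dw_at(params, mid, fixed, other, convention) if along_x
                 else _dw_at(params, fixed, mid, other, convention))
            flo = (_dw_at(params, lo, fixed, other, convention) if along_x
                   else _dw_at(params, fixed, lo, other, convention))
            if (v > 0) == (flo > 0):
                lo = mid
            else:
                hi = mid
        return 0.5 * (lo + hi)

    pts = []
    for iy in range(len(ys)):
        for ix in range(len(xs) - 1):
            if (dw[iy, ix] > 0) != (dw[iy, ix + 1] > 0):
                pts.append((bisect(ys[iy], xs[ix], xs[ix + 1], True), ys[iy]))
    for ix in range(len(xs)):
        for iy in range(len(ys) - 1):
            if (dw[iy, ix] > 0) != (dw[iy + 1, ix] > 0):
                pts.append((xs[ix], bisect(xs[ix], ys[iy], ys[iy + 1],
                                           False)))
    sep = np.array(sorted(pts)) if pts else np.empty((0, 2))
    return ImprovementMap(x_name="tau_z", y_name=other, x=xs, y=ys, dw=dw,
                          separatrix=sep, convention=convention)
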