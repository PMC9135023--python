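"""Work-based gait cost metrics.

Four measures of positive mechanical work per stride, all in units of
``m g l_H``:

* **Net COM Work (NCW)** -- positive-part integral of net ground reaction
  force dotted with COM velocity; equals the positive fluctuations of the
  COM's kinetic plus gravitational potential energy.
* **Individual Limbs COM Work (ILCW)** -- per-limb positive-part integrals
  of each limb's force dotted with COM velocity, summed.  Unlike NCW it
  cannot cancel simultaneous positive and negative work between limbs.
* **Limb Extension Work (LEW)** -- per-limb positive-part integrals of the
  axial leg force times the leg length rate: the work of actively extending
  each strut-like limb.
* **Net System Work (NSW)** -- positive fluctuations of the total
  mechanical energy including trunk rotational kinetic energy.

Plus the Cavagna-convention percent (pendular) recovery and the force-rate
regularization penalty used inside the optimization.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum
from typing import Dict, Optional, Tuple

import numpy as np

from .trajectory import Trajectory

__all__ = [
    "Metric",
    "WorkBreakdown",
    "DEFAULT_C1",
    "positive_part_integral",
    "positive_increments",
    "ncw",
    "ilcw",
    "lew",
    "nsw",
    "percent_recovery",
    "force_rate_penalty",
    "evaluate_works",
    "smooth_objective",
    "SmoothedObjective",
]

#: Force-rate penalty coefficient (forces in body weights, time normalized
#: to the stride period).
DEFAULT_C1 = 3e-5


class Metric(str, Enum):
    NCW = "ncw"
    ILCW = "ilcw"
    LEW = "lew"


def positive_part_integral(t: np.ndarray, p: np.ndarray) -> float:
    """Exact integral of ``max(p, 0)`` for a piecewise-linear sampled signal.

    Sign-crossing segments are split analytically, so the result is the
    exact positive-part integral of the linear interpolant (not a trapezoid
    of the clipped samples).
    """
    t = np.asarray(t, float)
    p = np.asarray(p, float)
    dt = np.diff(t)
    p0, p1 = p[:-1], p[1:]
    both_pos = (p0 >= 0) & (p1 >= 0)
    up = (p0 < 0) & (p1 > 0)
    down = (p0 > 0) & (p1 < 0)
    out = np.zeros_like(dt)
    out[both_pos] = 0.5 * (p0[both_pos] + p1[both_pos]) * dt[both_pos]
    out[up] = 0.5 * dt[up] * p1[up] ** 2 / (p1[up] - p0[up])
    out[down] = 0.5 * dt[down] * p0[down] ** 2 / (p0[down] - p1[down])
    return float(out.sum())


def positive_increments(series: np.ndarray) -> float:
    """Sum of positive increments of a sampled energy series: the exact
    positive-part integral of its piecewise-linear rate."""
    d = np.diff(np.asarray(series, float))
    return float(d[d > 0].sum())


def _check_periodic(traj: Trajectory) -> None:
    if not traj.periodic:
        warnings.warn(
            "work metric evaluated on a non-periodic trajectory; "
            "per-stride normalization is ambiguous",
            stacklevel=3,
        )


def ncw(traj: Trajectory) -> float:
    """Net COM Work: positive-part integral of ``F_net . V_COM``."""
    _check_periodic(traj)
    power = np.einsum("ij,ij->i", traj.net_force(), traj.com_velocity)
    return positive_part_integral(traj.t, power)


def ilcw(traj: Trajectory) -> float:
    """Individual Limbs COM Work: sum over footfalls of the positive-part
    integrals of each limb force dotted with COM velocity."""
    _check_periodic(traj)
    v = traj.com_velocity
    total = 0.0
    for tr in traj.footfalls:
        power = np.einsum("ij,ij->i", traj.limb_force_vectors(tr), v)
        total += positive_part_integral(traj.t, power)
    return total


def lew(traj: Trajectory) -> float:
    """Limb Extension Work: sum over footfalls of the positive-part
    integrals of axial force times limb length rate."""
    _check_periodic(traj)
    total = 0.0
    for tr in traj.footfalls:
        _, _, ldot = traj.limb_kinematics(tr)
        total += positive_part_integral(traj.t, tr.force * ldot)
    return total


def nsw(traj: Trajectory) -> float:
    """Net System Work: positive fluctuations of total mechanical energy
    (gravitational potential + translational + rotational kinetic)."""
    _check_periodic(traj)
    return positive_increments(traj.total_energy())


def percent_recovery(traj: Trajectory) -> float:
    """Cavagna-convention pendular recovery, in percent.

    ``100 (W+_Ek + W+_Ep - W+_{Ek+Ep}) / (W+_Ek + W+_Ep)`` where ``W+`` is
    the positive-part integral of the named COM energy's rate.  Rotational
    energy is deliberately excluded (COM convention).  Returns NaN when the
    COM energies do not fluctuate at all.
    """
    ep, ek = traj.com_energies()
    w_ep = positive_increments(ep)
    w_ek = positive_increments(ek)
    denom = w_ep + w_ek
    if denom <= 0.0:
        warnings.warn("no COM energy fluctuation; recovery undefined")
        return float("nan")
    w_sum = positive_increments(ep + ek)
    return 100.0 * (w_ep + w_ek - w_sum) / denom


def force_rate_penalty(traj: Trajectory, c1: float = DEFAULT_C1) -> float:
    """Regularization penalty ``c1 * sum_i int (dF_i/dt')^2 dt'``.

    Forces are in body weights and time is normalized to the stride period
    (``t' = t / T``).  Force rates stored on the trajectory are used when
    present; otherwise they are obtained by finite differences.
    """
    if c1 == 0.0:
        return 0.0
    T = traj.duration
    tp = (traj.t - traj.t[0]) / T
    bw = traj.body.mass * traj.body.g
    total = 0.0
    for tr in traj.footfalls:
        if tr.force_rate is not None:
            r = tr.force_rate / bw
        else:
            r = np.gradient(tr.force / bw, tp)
        total += np.trapezoid(r**2, tp)
    return c1 * float(total)


@dataclass
class WorkBreakdown:
    """All work metrics evaluated on one trajectory (per stride, m g l_H)."""

    ncw: float
    nsw: float
    ilcw: float
    lew: float
    percent_recovery: float
    force_rate_penalty: float
    #: per physical limb: positive/negative extension work
    limb_extension: Dict[str, Tuple[float, float]] = field(default_factory=dict)
    #: per physical limb: positive/negative COM work
    limb_com: Dict[str, Tuple[float, float]] = field(default_factory=dict)

    def as_record(self) -> Dict[str, float]:
        rec = {
            "ncw": self.ncw,
            "nsw": self.nsw,
            "ilcw": self.ilcw,
            "lew": self.lew,
            "percent_recovery": self.percent_recovery,
            "force_rate_penalty": self.force_rate_penalty,
        }
        for limb, (pos, neg) in self.limb_extension.items():
            rec[f"lew_pos_{limb}"] = pos
            rec[f"lew_neg_{limb}"] = neg
        for limb, (pos, neg) in self.limb_com.items():
            rec[f"ilcw_pos_{limb}"] = pos
            rec[f"ilcw_neg_{limb}"] = neg
        return rec


def evaluate_works(traj: Trajectory, c1: float = DEFAULT_C1) -> WorkBreakdown:
    """Evaluate the full work breakdown of a (full-stride) trajectory."""
    v = traj.com_velocity
    limb_ext: Dict[str, Tuple[float, float]] = {}
    limb_com: Dict[str, Tuple[float, float]] = {}
    for limb in traj.limb_labels():
        e_pos = e_neg = c_pos = c_neg = 0.0
        for tr in traj.footfalls:
            if tr.limb != limb:
                continue
            _, _, ldot = traj.limb_kinematics(tr)
            p_ext = tr.force * ldot
            e_pos += positive_part_integral(traj.t, p_ext)
            e_neg += positive_part_integral(traj.t, -p_ext)
            p_com = np.einsum("ij,ij->i", traj.limb_force_vectors(tr), v)
            c_pos += positive_part_integral(traj.t, p_com)
            c_neg += positive_part_integral(traj.t, -p_com)
        limb_ext[limb] = (e_pos, e_neg)
        limb_com[limb] = (c_pos, c_neg)
    return WorkBreakdown(
        ncw=ncw(traj),
        nsw=nsw(traj),
        ilcw=ilcw(traj),
        lew=lew(traj),
        percent_recovery=percent_recovery(traj),
        force_rate_penalty=force_rate_penalty(traj, c1),
        limb_extension=limb_ext,
        limb_com=limb_com,
    )


@dataclass(frozen=True)
class SmoothedObjective:
    """NLP-facing description of a work metric.

    Inside the transcription the positive-part function is handled with
    nonnegative epigraph slack variables: one slack ``s`` per power term per
    node with ``s >= power`` and ``s >= 0``, and the objective integrates
    the slacks.  Minimization drives each slack onto ``|power|+`` exactly,
    so the exact metric is recoverable from the solution.
    """

    metric: Metric
    #: number of power terms (slack channels) per collocation node
    n_terms: int

    def exact(self, traj: Trajectory) -> float:
        """Exact positive-part quadrature of the same metric."""
        return {Metric.NCW: ncw, Metric.ILCW: ilcw, Metric.LEW: lew}[self.metric](traj)


def smooth_objective(metric: Metric | str) -> SmoothedObjective:
    """Return the slack-variable description of ``metric`` for the NLP.

    NCW has a single power term (net force dotted with COM velocity); ILCW
    and LEW have one per footfall channel (five in the half-cycle
    formulation).
    """
    metric = Metric(metric)
    n = 1 if metric is Metric.NCW else 5
    return SmoothedObjective(metric=metric, n_terms=n)
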