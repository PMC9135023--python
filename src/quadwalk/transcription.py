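"""Direct-collocation transcription of the half-cycle gait optimization.

The periodic, left-right symmetric stride is reduced to its first half
cycle, ``t' = t/T in [0, 0.5]``.  States are the planar trunk kinematics,
the five footfall-channel actuator forces (LH, RH, LFt, LFl, RF) and the
running integral of the leading left-fore force; controls are the force
rates; static decision parameters are the left-limb footfall positions.
Footfall timing is not prescribed: contact emerges from complementarity
conditions (force only when the limb is at or below its maximum length,
and the left-fore trailing footfall is excluded once the leading footfall
has produced force), relaxed by penalized relaxation parameters.

The result is a dense nonlinear program with analytic objective gradient
and constraint Jacobians, solver-agnostic but sized for an SQP method.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace as _dc_replace
from typing import Dict, Optional, Tuple

import numpy as np

from .core_model import BodyModel, GaitTask, Limb, Variant
from .objectives import DEFAULT_C1, Metric, smooth_objective
from .trajectory import FootfallTrace, Trajectory

__all__ = [
    "TranscriptionSpec",
    "DecisionVector",
    "HalfCycle",
    "QuadNLP",
    "build_nlp",
    "relaxation_schedule",
    "mirror_half_cycle",
    "DEFAULT_W0",
]

#: initial relaxation-parameter penalty weight (round 0 of the schedule)
DEFAULT_W0 = 1.0

#: footfall channel order used throughout the transcription
CHANNELS = (Limb.LH, Limb.RH, Limb.LFT, Limb.LFL, Limb.RF)
#: which static parameter (0: hind, 1: fore) each channel's footfall follows
_FOOT_PARAM = np.array([0, 0, 1, 1, 1])
_I_LH, _I_RH, _I_LFT, _I_LFL, _I_RF = range(5)


def relaxation_schedule(round_index: int, w0: float = DEFAULT_W0) -> float:
    """Penalty weight of the relaxation parameters at a given round.

    The weight grows geometrically, tenfold per round: ``w0 * 10**round``.
    """
    if round_index < 0:
        raise ValueError("round_index must be nonnegative")
    return w0 * 10.0**round_index


@dataclass(frozen=True)
class TranscriptionSpec:
    """Discretization and regularization settings for one NLP build."""

    n_nodes: int = 16
    collocation_rule: str = "trapezoidal"  # or "hermite_simpson"
    relaxation_penalty: float = DEFAULT_W0
    c1: float = DEFAULT_C1
    #: None -> the extra trailing/leading fore force-rate complementarity is
    #: applied exactly when the metric is NCW
    include_rate_exclusion: Optional[bool] = None
    #: upper bound of the relaxation parameters (clamped in late rounds)
    eps_upper: float = 10.0
    bounds: Dict[str, Tuple[float, float]] = field(
        default_factory=lambda: {
            "y": (0.05, 2.0),
            "theta": (-math.pi / 2, math.pi / 2),
            "vx": (-2.0, 3.0),
            "vy": (-3.0, 3.0),
            "omega": (-8.0, 8.0),
            "force": (0.0, 10.0),
            "force_rate": (-400.0, 400.0),
            "slack": (0.0, 100.0),
            "integral": (0.0, 20.0),
        }
    )

    def __post_init__(self) -> None:
        if self.n_nodes < 8:
            raise ValueError("n_nodes must be at least 8")
        if self.relaxation_penalty <= 0:
            raise ValueError("relaxation_penalty must be positive")
        if self.c1 < 0:
            raise ValueError("c1 must be nonnegative")
        if self.collocation_rule not in ("trapezoidal", "hermite_simpson"):
            raise ValueError(f"unknown collocation rule {self.collocation_rule!r}")
        for lo, hi in self.bounds.values():
            if lo > hi:
                raise ValueError("infeasible bounds")


@dataclass
class DecisionVector:
    """Decoded view of the flat NLP decision vector.

    ``Q``: node states, ``(n, ns)`` with columns
    ``x, y[, theta], vx, vy[, omega], F_LH, F_RH, F_LFt, F_LFl, F_RF, J``
    (bracketed columns absent for the point-mass variant; ``J`` is the
    running integral of ``F_LFl`` in normalized time).
    ``R``: force-rate controls ``(n, 5)`` (dF/dt').
    ``S``: objective slack variables ``(n, n_terms)``.
    ``xf``: left-limb footfall positions ``(hind, fore-trailing)``.
    ``eps``: relaxation parameters of the complementarity families.
    """

    Q: np.ndarray
    R: np.ndarray
    S: np.ndarray
    xf: np.ndarray
    eps: np.ndarray


@dataclass
class HalfCycle:
    """Solved half cycle in physical (nondimensional) quantities."""

    tau: np.ndarray  # normalized time in [0, 0.5]
    states: np.ndarray  # (n, 6): x, y, theta, vx, vy, omega
    forces: np.ndarray  # (n, 5) channel forces, body weights
    force_rates: np.ndarray  # (n, 5) dF/dt'
    foot_x: np.ndarray  # (5,) channel footfall positions
    body: BodyModel
    task: GaitTask


def mirror_half_cycle(half: HalfCycle, tol: float = 1e-5) -> Trajectory:
    """Mirror a symmetric half cycle into one full periodic stride.

    Right-limb histories in the second half equal the left-limb histories of
    the first half (and vice versa), with footfalls translated by ``D/2``.
    Refuses to mirror if the symmetry/periodicity boundary residuals exceed
    ``tol``.
    """
    D = half.task.stride
    T = half.task.period
    st, F = half.states, half.forces
    residuals = [
        st[-1, 0] - st[0, 0] - D / 2.0,
        *(st[-1, 1:] - st[0, 1:]),
        F[0, _I_LH],
        F[0, _I_LFL],
        F[-1, _I_RH],
        F[-1, _I_LFT],
        F[-1, _I_LH] - F[0, _I_RH],
        F[-1, _I_RF] - F[0, _I_LFT],
        F[-1, _I_LFL] - F[0, _I_RF],
    ]
    resid = float(np.max(np.abs(residuals)))
    if resid > tol:
        raise ValueError(
            f"half cycle violates symmetry boundary conditions (residual {resid:.2e})"
        )

    n = half.tau.size
    t_full = np.concatenate([half.tau, half.tau[1:] + 0.5]) * T
    states_full = np.vstack([st, st[1:]])
    states_full[n:, 0] += D / 2.0

    nfull = 2 * n - 1
    R = half.force_rates
    xh, xft = half.foot_x[_I_LH], half.foot_x[_I_LFT]
    x_rh, x_lfl, x_rf = half.foot_x[_I_RH], half.foot_x[_I_LFL], half.foot_x[_I_RF]

    def trace(limb, attach, x_foot, first, second):
        f = np.zeros(nfull)
        r = np.zeros(nfull)
        if first is not None:
            f[:n] = F[:, first]
            r[:n] = R[:, first]
        if second is not None:
            f[n:] = F[1:, second]
            r[n:] = R[1:, second]
        return FootfallTrace(limb, attach, x_foot, f, r)

    feet = [
        trace("LH", "hip", xh, _I_LH, _I_RH),
        trace("RH", "hip", x_rh, _I_RH, None),
        trace("RH", "hip", xh + D / 2.0, None, _I_LH),
        trace("LF", "shoulder", xft, _I_LFT, None),
        trace("LF", "shoulder", x_lfl, _I_LFL, _I_RF),
        trace("RF", "shoulder", x_rf, _I_RF, _I_LFT),
        trace("RF", "shoulder", x_rf + D, None, _I_LFL),
    ]
    return Trajectory(
        t=t_full,
        states=states_full,
        footfalls=feet,
        body=half.body,
        task=half.task,
        periodic=True,
        meta={"symmetry_residual": resid, "n_half_nodes": n},
    )


class QuadNLP:
    """Half-cycle gait optimization transcribed as a dense NLP.

    Exposes ``objective``/``gradient``, equality and inequality constraint
    vectors with analytic Jacobians, simple variable bounds, and helpers to
    encode, decode, resample and mirror decision vectors.  Inequalities use
    the convention ``g(z) >= 0``.
    """

    def __init__(
        self,
        body: BodyModel,
        task: GaitTask,
        metric: Metric | str,
        spec: TranscriptionSpec,
    ):
        if abs(body.mass - 1.0) > 1e-12 or abs(body.g - 1.0) > 1e-12 or abs(
            body.l_H_max - 1.0
        ) > 1e-12:
            raise ValueError("transcription expects a nondimensionalized body")
        self.body = body
        self.task = task
        self.metric = Metric(metric)
        self.spec = spec
        self.smoothed = smooth_objective(self.metric)
        self.point_mass = body.is_point_mass

        self.n = spec.n_nodes
        self.T = task.period
        self.D = task.stride
        self.h = 0.5 / (self.n - 1)
        self.tau = np.linspace(0.0, 0.5, self.n)

        # state layout
        self.nq = 4 if self.point_mass else 6
        self.ns = self.nq + 5 + 1
        self.iF = self.nq  # first force column within a node state
        self.iJ = self.nq + 5
        if self.point_mass:
            self.ix, self.iy, self.ivx, self.ivy = 0, 1, 2, 3
            self.ith = self.iom = None
        else:
            self.ix, self.iy, self.ith, self.ivx, self.ivy, self.iom = range(6)

        self.n_terms = self.smoothed.n_terms
        self.use_rate_exclusion = (
            spec.include_rate_exclusion
            if spec.include_rate_exclusion is not None
            else self.metric is Metric.NCW
        )
        self.n_eps = 3 if self.use_rate_exclusion else 2  # limb-length, fore-exclusion [, fore force-rate]

        n, ns = self.n, self.ns
        self.off_Q = 0
        self.off_R = n * ns
        self.off_S = self.off_R + n * 5
        self.off_xf = self.off_S + n * self.n_terms
        self.off_eps = self.off_xf + 2
        self.nz = self.off_eps + self.n_eps

        b = np.empty(5)
        b[:2] = body.hip_offset
        b[2:] = body.shoulder_offset
        self.b = b
        self.lmax = np.array([body.max_length(ch) for ch in CHANNELS])
        self.foot_const = np.array([0.0, -self.D / 2, 0.0, self.D, self.D / 2])

        # trapezoidal quadrature weights on the tau grid
        wq = np.full(n, self.h)
        wq[0] = wq[-1] = self.h / 2
        self.wq = wq

        self.relax_weight = float(spec.relaxation_penalty)
        self._cache_key = None
        self._cache = None
        self._count_constraints()

    # ------------------------------------------------------------------
    # layout helpers
    # ------------------------------------------------------------------
    def q_idx(self, k: int, col: int) -> int:
        return self.off_Q + k * self.ns + col

    def decode(self, z: np.ndarray) -> DecisionVector:
        n, ns = self.n, self.ns
        Q = z[self.off_Q : self.off_R].reshape(n, ns)
        R = z[self.off_R : self.off_S].reshape(n, 5)
        S = z[self.off_S : self.off_xf].reshape(n, self.n_terms)
        xf = z[self.off_xf : self.off_eps]
        eps = z[self.off_eps :]
        return DecisionVector(Q, R, S, xf, eps)

    def encode(self, dv: DecisionVector) -> np.ndarray:
        return np.concatenate(
            [dv.Q.ravel(), dv.R.ravel(), dv.S.ravel(), dv.xf, dv.eps]
        )

    def full_states(self, Q: np.ndarray) -> np.ndarray:
        """Node states as (n, 6) columns x, y, theta, vx, vy, omega."""
        n = Q.shape[0]
        out = np.zeros((n, 6))
        out[:, 0] = Q[:, self.ix]
        out[:, 1] = Q[:, self.iy]
        out[:, 3] = Q[:, self.ivx]
        out[:, 4] = Q[:, self.ivy]
        if not self.point_mass:
            out[:, 2] = Q[:, self.ith]
            out[:, 5] = Q[:, self.iom]
        return out

    def channel_foot_x(self, xf: np.ndarray) -> np.ndarray:
        return xf[_FOOT_PARAM] + self.foot_const

    # ------------------------------------------------------------------
    # bounds
    # ------------------------------------------------------------------
    def bounds(self) -> np.ndarray:
        """Variable bounds, shape (nz, 2); fixed values have lb == ub."""
        bd = self.spec.bounds
        n, ns = self.n, self.ns
        lb = np.full(self.nz, -np.inf)
        ub = np.full(self.nz, np.inf)
        Ql = np.empty((n, ns))
        Qu = np.empty((n, ns))
        Ql[:, self.ix], Qu[:, self.ix] = -1.0, self.D / 2 + 1.0
        Ql[:, self.iy], Qu[:, self.iy] = bd["y"]
        Ql[:, self.ivx], Qu[:, self.ivx] = bd["vx"]
        Ql[:, self.ivy], Qu[:, self.ivy] = bd["vy"]
        if not self.point_mass:
            Ql[:, self.ith], Qu[:, self.ith] = bd["theta"]
            Ql[:, self.iom], Qu[:, self.iom] = bd["omega"]
        Ql[:, self.iF : self.iF + 5], Qu[:, self.iF : self.iF + 5] = bd["force"]
        Ql[:, self.iJ], Qu[:, self.iJ] = bd["integral"]

        # boundary fixings: phase origin, reference-limb liftoff/touchdown
        Ql[0, self.ix] = Qu[0, self.ix] = 0.0
        Ql[-1, self.ix] = Qu[-1, self.ix] = self.D / 2
        Ql[0, self.iJ] = Qu[0, self.iJ] = 0.0
        for k, ch in ((0, _I_LH), (0, _I_LFL), (-1, _I_RH), (-1, _I_LFT)):
            Ql[k, self.iF + ch] = Qu[k, self.iF + ch] = 0.0

        lb[self.off_Q : self.off_R] = Ql.ravel()
        ub[self.off_Q : self.off_R] = Qu.ravel()
        lb[self.off_R : self.off_S], ub[self.off_R : self.off_S] = bd["force_rate"]
        lb[self.off_S : self.off_xf], ub[self.off_S : self.off_xf] = bd["slack"]
        lb[self.off_xf : self.off_eps] = -3.0
        ub[self.off_xf : self.off_eps] = 3.0 + self.D
        lb[self.off_eps :] = 0.0
        ub[self.off_eps :] = self.spec.eps_upper
        return np.column_stack([lb, ub])

    # ------------------------------------------------------------------
    # constraint counting
    # ------------------------------------------------------------------
    def _count_constraints(self) -> None:
        n = self.n
        self.m_defect = (n - 1) * self.ns
        self.m_periodic = 3 if self.point_mass else 5
        self.m_couple = 3
        self.m_eq = self.m_defect + self.m_periodic + self.m_couple
        self.m_slack = n * self.n_terms
        self.m_length_comp = n * 5
        self.m_fore_excl = n
        self.m_rate_excl = 2 * n if self.use_rate_exclusion else 0
        self.m_height = 0 if self.point_mass else 2 * n
        self.m_ineq = self.m_slack + self.m_length_comp + self.m_fore_excl + self.m_rate_excl + self.m_height

    # ------------------------------------------------------------------
    # geometry and dynamics
    # ------------------------------------------------------------------
    def _geometry(self, Q: np.ndarray, xf: np.ndarray) -> dict:
        """Vectorized limb geometry and its partial derivatives.

        All arrays have shape (n, 5): one column per footfall channel.
        Partials are with respect to the trunk coordinates and each
        channel's own footfall x position (``df`` suffix).
        """
        n = Q.shape[0]
        x, y = Q[:, self.ix], Q[:, self.iy]
        vx, vy = Q[:, self.ivx], Q[:, self.ivy]
        if self.point_mass:
            c = np.ones(n)
            s = np.zeros(n)
            om = np.zeros(n)
        else:
            th = Q[:, self.ith]
            c, s = np.cos(th), np.sin(th)
            om = Q[:, self.iom]
        b = self.b[None, :]
        fx = self.channel_foot_x(xf)[None, :]

        dx = x[:, None] + b * c[:, None] - fx
        dy = y[:, None] + b * s[:, None]
        l = np.hypot(dx, dy)
        l = np.maximum(l, 1e-9)  # guard; bounds keep geometry away from 0
        inv_l = 1.0 / l
        ux, uy = dx * inv_l, dy * inv_l

        dux_dx = (1.0 - ux**2) * inv_l
        dux_dy = -ux * uy * inv_l
        duy_dx = dux_dy
        duy_dy = (1.0 - uy**2) * inv_l
        ddx_dth = -b * s[:, None]
        ddy_dth = b * c[:, None]
        dl_dth = ux * ddx_dth + uy * ddy_dth
        dux_dth = (ddx_dth - ux * dl_dth) * inv_l
        duy_dth = (ddy_dth - uy * dl_dth) * inv_l
        dux_df = -dux_dx
        duy_df = -duy_dx

        vax = vx[:, None] - b * s[:, None] * om[:, None]
        vay = vy[:, None] + b * c[:, None] * om[:, None]
        w = b * (c[:, None] * uy - s[:, None] * ux)  # moment arm (= dl/dtheta)
        ldot = ux * vax + uy * vay

        g = {
            "l": l, "ux": ux, "uy": uy, "w": w, "ldot": ldot,
            "vax": vax, "vay": vay, "c": c, "s": s, "om": om,
            "dux_dx": dux_dx, "dux_dy": dux_dy, "dux_dth": dux_dth, "dux_df": dux_df,
            "duy_dx": duy_dx, "duy_dy": duy_dy, "duy_dth": duy_dth, "duy_df": duy_df,
            "dl_dx": ux, "dl_dy": uy, "dl_dth": dl_dth, "dl_df": -ux,
            "dldot_dvx": ux, "dldot_dvy": uy, "dldot_dom": w,
            "dldot_dx": dux_dx * vax + duy_dx * vay,
            "dldot_dy": dux_dy * vax + duy_dy * vay,
            "dldot_df": dux_df * vax + duy_df * vay,
        }
        if not self.point_mass:
            g["dldot_dth"] = (
                dux_dth * vax + duy_dth * vay
                - ux * b * c[:, None] * om[:, None]
                - uy * b * s[:, None] * om[:, None]
            )
            g["dw_dx"] = b * (c[:, None] * duy_dx - s[:, None] * dux_dx)
            g["dw_dy"] = b * (c[:, None] * duy_dy - s[:, None] * dux_dy)
            g["dw_dth"] = b * (
                -s[:, None] * uy + c[:, None] * duy_dth
                - c[:, None] * ux - s[:, None] * dux_dth
            )
            g["dw_df"] = b * (c[:, None] * duy_df - s[:, None] * dux_df)
        return g

    def _dynamics(self, dv: DecisionVector, g: dict):
        """Normalized-time state derivative ``f`` and its Jacobians.

        Returns ``f`` (n, ns), ``A = df/dstate`` (n, ns, ns) and
        ``P = df/dxf`` (n, ns, 2).  Row count follows the supplied states,
        so the same routine serves the Hermite-Simpson midpoints.
        """
        n, ns = dv.Q.shape[0], self.ns
        T = self.T
        F = dv.Q[:, self.iF : self.iF + 5]
        ux, uy = g["ux"], g["uy"]

        f = np.zeros((n, ns))
        A = np.zeros((n, ns, ns))
        P = np.zeros((n, ns, 2))

        f[:, self.ix] = T * dv.Q[:, self.ivx]
        f[:, self.iy] = T * dv.Q[:, self.ivy]
        A[:, self.ix, self.ivx] = T
        A[:, self.iy, self.ivy] = T

        # translational accelerations (mass = 1)
        f[:, self.ivx] = T * np.sum(F * ux, axis=1)
        f[:, self.ivy] = T * (np.sum(F * uy, axis=1) - 1.0)
        A[:, self.ivx, self.ix] = T * np.sum(F * g["dux_dx"], axis=1)
        A[:, self.ivx, self.iy] = T * np.sum(F * g["dux_dy"], axis=1)
        A[:, self.ivy, self.ix] = T * np.sum(F * g["duy_dx"], axis=1)
        A[:, self.ivy, self.iy] = T * np.sum(F * g["duy_dy"], axis=1)
        for j in range(5):
            A[:, self.ivx, self.iF + j] = T * ux[:, j]
            A[:, self.ivy, self.iF + j] = T * uy[:, j]
            p = _FOOT_PARAM[j]
            P[:, self.ivx, p] += T * F[:, j] * g["dux_df"][:, j]
            P[:, self.ivy, p] += T * F[:, j] * g["duy_df"][:, j]

        if not self.point_mass:
            f[:, self.ith] = T * dv.Q[:, self.iom]
            A[:, self.ith, self.iom] = T
            A[:, self.ivx, self.ith] = T * np.sum(F * g["dux_dth"], axis=1)
            A[:, self.ivy, self.ith] = T * np.sum(F * g["duy_dth"], axis=1)
            inv_i = 1.0 / self.body.inertia
            w = g["w"]
            f[:, self.iom] = T * inv_i * np.sum(F * w, axis=1)
            A[:, self.iom, self.ix] = T * inv_i * np.sum(F * g["dw_dx"], axis=1)
            A[:, self.iom, self.iy] = T * inv_i * np.sum(F * g["dw_dy"], axis=1)
            A[:, self.iom, self.ith] = T * inv_i * np.sum(F * g["dw_dth"], axis=1)
            for j in range(5):
                A[:, self.iom, self.iF + j] = T * inv_i * w[:, j]
                P[:, self.iom, _FOOT_PARAM[j]] += T * inv_i * F[:, j] * g["dw_df"][:, j]

        # force states evolve with the force-rate controls
        f[:, self.iF : self.iF + 5] = dv.R

        # running integral of the leading left-fore force (normalized time)
        f[:, self.iJ] = F[:, _I_LFL]
        A[:, self.iJ, self.iF + _I_LFL] = 1.0
        return f, A, P

    # control Jacobian of f: force rows are exactly the controls
    def _control_block(self) -> np.ndarray:
        B = np.zeros((self.ns, 5))
        for j in range(5):
            B[self.iF + j, j] = 1.0
        return B

    # ------------------------------------------------------------------
    # power terms of the smoothed objective
    # ------------------------------------------------------------------
    def _power_terms(self, dv: DecisionVector, g: dict):
        """Per-node power terms (scaled by T) and their derivatives.

        Returns ``p`` (n, n_terms) plus derivative arrays with respect to
        node states (n, n_terms, ns) and footfall parameters (n, n_terms, 2).
        """
        n, ns = self.n, self.ns
        T = self.T
        F = dv.Q[:, self.iF : self.iF + 5]
        vx, vy = dv.Q[:, self.ivx], dv.Q[:, self.ivy]
        nt = self.n_terms
        p = np.zeros((n, nt))
        dp_dq = np.zeros((n, nt, ns))
        dp_dxf = np.zeros((n, nt, 2))

        if self.metric is Metric.LEW:
            ldot = g["ldot"]
            p[:] = T * F * ldot
            for j in range(5):
                dp_dq[:, j, self.ix] = T * F[:, j] * g["dldot_dx"][:, j]
                dp_dq[:, j, self.iy] = T * F[:, j] * g["dldot_dy"][:, j]
                dp_dq[:, j, self.ivx] = T * F[:, j] * g["dldot_dvx"][:, j]
                dp_dq[:, j, self.ivy] = T * F[:, j] * g["dldot_dvy"][:, j]
                dp_dq[:, j, self.iF + j] = T * ldot[:, j]
                if not self.point_mass:
                    dp_dq[:, j, self.ith] = T * F[:, j] * g["dldot_dth"][:, j]
                    dp_dq[:, j, self.iom] = T * F[:, j] * g["dldot_dom"][:, j]
                dp_dxf[:, j, _FOOT_PARAM[j]] = T * F[:, j] * g["dldot_df"][:, j]
        else:
            ux, uy = g["ux"], g["uy"]
            pv = ux * vx[:, None] + uy * vy[:, None]  # u . v_com per channel
            terms = F * pv * T
            if self.metric is Metric.ILCW:
                p[:] = terms
                idx = range(5)
            else:  # NCW: single net term
                p[:, 0] = np.sum(terms, axis=1)
                idx = [0] * 5
            for j, row in zip(range(5), idx):
                dp_dq[:, row, self.ix] += T * F[:, j] * (
                    g["dux_dx"][:, j] * vx + g["duy_dx"][:, j] * vy
                )
                dp_dq[:, row, self.iy] += T * F[:, j] * (
                    g["dux_dy"][:, j] * vx + g["duy_dy"][:, j] * vy
                )
                dp_dq[:, row, self.ivx] += T * F[:, j] * ux[:, j]
                dp_dq[:, row, self.ivy] += T * F[:, j] * uy[:, j]
                dp_dq[:, row, self.iF + j] += T * pv[:, j]
                if not self.point_mass:
                    dp_dq[:, row, self.ith] += T * F[:, j] * (
                        g["dux_dth"][:, j] * vx + g["duy_dth"][:, j] * vy
                    )
                dp_dxf[:, row, _FOOT_PARAM[j]] += T * F[:, j] * (
                    g["dux_df"][:, j] * vx + g["duy_df"][:, j] * vy
                )
        return p, dp_dq, dp_dxf

    # ------------------------------------------------------------------
    # full evaluation (cached)
    # ------------------------------------------------------------------
    def _evaluate(self, z: np.ndarray) -> dict:
        key = z.tobytes()
        if self._cache_key == key:
            return self._cache
        dv = self.decode(z)
        g = self._geometry(dv.Q, dv.xf)
        f, A, P = self._dynamics(dv, g)
        out = {"dv": dv, "geom": g}

        out.update(self._build_objective(dv, g))
        out.update(self._build_equalities(dv, f, A, P))
        out.update(self._build_inequalities(dv, g))
        self._cache_key = key
        self._cache = out
        return out

    def _build_objective(self, dv: DecisionVector, g: dict) -> dict:
        wq = self.wq
        c1 = self.spec.c1
        work_term = 2.0 * float(wq @ dv.S.sum(axis=1))
        rate_term = 2.0 * c1 * float(wq @ (dv.R**2).sum(axis=1))
        relax_term = self.relax_weight * float(dv.eps.sum())
        grad = np.zeros(self.nz)
        gS = np.repeat(2.0 * wq[:, None], self.n_terms, axis=1)
        grad[self.off_S : self.off_xf] = gS.ravel()
        grad[self.off_R : self.off_S] = (4.0 * c1 * wq[:, None] * dv.R).ravel()
        grad[self.off_eps :] = self.relax_weight
        return {
            "obj": work_term + rate_term + relax_term,
            "grad": grad,
            "obj_parts": {
                "work": work_term,
                "force_rate": rate_term,
                "relaxation": relax_term,
            },
        }

    def _build_equalities(self, dv, f, A, P) -> dict:
        n, ns, nz = self.n, self.ns, self.nz
        h = self.h
        Q = dv.Q
        ceq = np.zeros(self.m_eq)
        Jeq = np.zeros((self.m_eq, nz))
        B = self._control_block()

        rule = self.spec.collocation_rule
        if rule == "trapezoidal":
            defect = Q[1:] - Q[:-1] - 0.5 * h * (f[:-1] + f[1:])
            ceq[: self.m_defect] = defect.ravel()
            for k in range(n - 1):
                r0 = k * ns
                q0, q1 = self.off_Q + k * ns, self.off_Q + (k + 1) * ns
                Jeq[r0 : r0 + ns, q0 : q0 + ns] = -np.eye(ns) - 0.5 * h * A[k]
                Jeq[r0 : r0 + ns, q1 : q1 + ns] = np.eye(ns) - 0.5 * h * A[k + 1]
                u0 = self.off_R + k * 5
                u1 = self.off_R + (k + 1) * 5
                Jeq[r0 : r0 + ns, u0 : u0 + 5] = -0.5 * h * B
                Jeq[r0 : r0 + ns, u1 : u1 + 5] = -0.5 * h * B
                Jeq[r0 : r0 + ns, self.off_xf : self.off_xf + 2] = -0.5 * h * (
                    P[k] + P[k + 1]
                )
        else:  # hermite_simpson
            Qm = 0.5 * (Q[:-1] + Q[1:]) + (h / 8.0) * (f[:-1] - f[1:])
            Rm = 0.5 * (dv.R[:-1] + dv.R[1:])
            dvm = DecisionVector(Qm, Rm, dv.S, dv.xf, dv.eps)
            gm = self._geometry(Qm, dv.xf)
            fm, Am, Pm = self._dynamics(dvm, gm)
            defect = Q[1:] - Q[:-1] - (h / 6.0) * (f[:-1] + 4.0 * fm + f[1:])
            ceq[: self.m_defect] = defect.ravel()
            I = np.eye(ns)
            for k in range(n - 1):
                r0 = k * ns
                q0, q1 = self.off_Q + k * ns, self.off_Q + (k + 1) * ns
                dxm_d0 = 0.5 * I + (h / 8.0) * A[k]
                dxm_d1 = 0.5 * I - (h / 8.0) * A[k + 1]
                Jeq[r0 : r0 + ns, q0 : q0 + ns] = (
                    -I - (h / 6.0) * (A[k] + 4.0 * Am[k] @ dxm_d0)
                )
                Jeq[r0 : r0 + ns, q1 : q1 + ns] = (
                    I - (h / 6.0) * (A[k + 1] + 4.0 * Am[k] @ dxm_d1)
                )
                u0 = self.off_R + k * 5
                u1 = self.off_R + (k + 1) * 5
                # midpoint state depends on controls through f's force rows
                dxm_du0 = (h / 8.0) * B
                dxm_du1 = -(h / 8.0) * B
                Jeq[r0 : r0 + ns, u0 : u0 + 5] = -(h / 6.0) * (
                    B + 4.0 * (Am[k] @ dxm_du0 + 0.5 * B)
                )
                Jeq[r0 : r0 + ns, u1 : u1 + 5] = -(h / 6.0) * (
                    B + 4.0 * (Am[k] @ dxm_du1 + 0.5 * B)
                )
                dxm_dp = (h / 8.0) * (P[k] - P[k + 1])
                Jeq[r0 : r0 + ns, self.off_xf : self.off_xf + 2] = -(h / 6.0) * (
                    P[k] + 4.0 * (Am[k] @ dxm_dp + Pm[k]) + P[k + 1]
                )

        # periodicity of the trunk kinematics (x handled via fixed bounds)
        row = self.m_defect
        kin_cols = (
            [self.iy, self.ivx, self.ivy]
            if self.point_mass
            else [self.iy, self.ith, self.ivx, self.ivy, self.iom]
        )
        for col in kin_cols:
            ceq[row] = Q[-1, col] - Q[0, col]
            Jeq[row, self.q_idx(n - 1, col)] = 1.0
            Jeq[row, self.q_idx(0, col)] = -1.0
            row += 1

        # left/right force hand-off at the half-cycle boundary
        couple = (
            (self.iF + _I_LH, self.iF + _I_RH),
            (self.iF + _I_RF, self.iF + _I_LFT),
            (self.iF + _I_LFL, self.iF + _I_RF),
        )
        for end_col, start_col in couple:
            ceq[row] = Q[-1, end_col] - Q[0, start_col]
            Jeq[row, self.q_idx(n - 1, end_col)] = 1.0
            Jeq[row, self.q_idx(0, start_col)] = -1.0
            row += 1
        return {"ceq": ceq, "Jeq": Jeq}

    def _build_inequalities(self, dv: DecisionVector, g: dict) -> dict:
        n, ns, nz = self.n, self.ns, self.nz
        Q = dv.Q
        F = Q[:, self.iF : self.iF + 5]
        cin = np.zeros(self.m_ineq)
        Jin = np.zeros((self.m_ineq, nz))

        p, dp_dq, dp_dxf = self._power_terms(dv, g)
        row = 0
        # epigraph slacks: s - p >= 0
        for k in range(n):
            q0 = self.off_Q + k * ns
            for j in range(self.n_terms):
                cin[row] = dv.S[k, j] - p[k, j]
                Jin[row, self.off_S + k * self.n_terms + j] = 1.0
                Jin[row, q0 : q0 + ns] = -dp_dq[k, j]
                Jin[row, self.off_xf : self.off_xf + 2] = -dp_dxf[k, j]
                row += 1

        # limb complementarity: F (lmax - l) + eps5 >= 0
        l = g["l"]
        slackl = self.lmax[None, :] - l
        i_eps5 = self.off_eps
        for k in range(n):
            q0 = self.off_Q + k * ns
            for j in range(5):
                cin[row] = F[k, j] * slackl[k, j] + dv.eps[0]
                Jin[row, q0 + self.iF + j] = slackl[k, j]
                Jin[row, q0 + self.ix] = -F[k, j] * g["dl_dx"][k, j]
                Jin[row, q0 + self.iy] = -F[k, j] * g["dl_dy"][k, j]
                if not self.point_mass:
                    Jin[row, q0 + self.ith] = -F[k, j] * g["dl_dth"][k, j]
                Jin[row, self.off_xf + _FOOT_PARAM[j]] = -F[k, j] * g["dl_df"][k, j]
                Jin[row, i_eps5] = 1.0
                row += 1

        # trailing/leading fore exclusion: eps6 - F_LFt * J >= 0
        i_eps6 = self.off_eps + 1
        for k in range(n):
            q0 = self.off_Q + k * ns
            cin[row] = dv.eps[1] - F[k, _I_LFT] * Q[k, self.iJ]
            Jin[row, q0 + self.iF + _I_LFT] = -Q[k, self.iJ]
            Jin[row, q0 + self.iJ] = -F[k, _I_LFT]
            Jin[row, i_eps6] = 1.0
            row += 1

        # optional force-rate complementarity: eps7 +/- F_LFt * Fdot_LFl >= 0
        if self.use_rate_exclusion:
            i_eps7 = self.off_eps + 2
            for k in range(n):
                q0 = self.off_Q + k * ns
                u0 = self.off_R + k * 5
                prod = F[k, _I_LFT] * dv.R[k, _I_LFL]
                for sign in (+1.0, -1.0):
                    cin[row] = dv.eps[2] + sign * prod
                    Jin[row, q0 + self.iF + _I_LFT] = sign * dv.R[k, _I_LFL]
                    Jin[row, u0 + _I_LFL] = sign * F[k, _I_LFT]
                    Jin[row, i_eps7] = 1.0
                    row += 1

        # hip and shoulder stay above ground
        if not self.point_mass:
            c, s = g["c"], g["s"]
            for k in range(n):
                q0 = self.off_Q + k * ns
                for b in (self.body.hip_offset, self.body.shoulder_offset):
                    cin[row] = Q[k, self.iy] + b * s[k]
                    Jin[row, q0 + self.iy] = 1.0
                    Jin[row, q0 + self.ith] = b * c[k]
                    row += 1
        return {"cin": cin, "Jin": Jin}

    # ------------------------------------------------------------------
    # public NLP interface
    # ------------------------------------------------------------------
    def objective(self, z: np.ndarray) -> float:
        return self._evaluate(z)["obj"]

    def gradient(self, z: np.ndarray) -> np.ndarray:
        return self._evaluate(z)["grad"]

    def eq_constraints(self, z: np.ndarray) -> np.ndarray:
        return self._evaluate(z)["ceq"]

    def eq_jacobian(self, z: np.ndarray) -> np.ndarray:
        return self._evaluate(z)["Jeq"]

    def ineq_constraints(self, z: np.ndarray) -> np.ndarray:
        return self._evaluate(z)["cin"]

    def ineq_jacobian(self, z: np.ndarray) -> np.ndarray:
        return self._evaluate(z)["Jin"]

    def objective_parts(self, z: np.ndarray) -> Dict[str, float]:
        return dict(self._evaluate(z)["obj_parts"])

    def with_spec(self, **changes) -> "QuadNLP":
        """New NLP sharing body/task/metric with modified spec fields."""
        return QuadNLP(self.body, self.task, self.metric,
                       _dc_replace(self.spec, **changes))

    # ------------------------------------------------------------------
    # diagnostics and conversion
    # ------------------------------------------------------------------
    def complementarity_residuals(self, z: np.ndarray) -> Dict[str, float]:
        """Worst-node residuals of the exact (unrelaxed) complementarity
        conditions, in body-weight product units."""
        dv = self.decode(z)
        g = self._geometry(dv.Q, dv.xf)
        F = dv.Q[:, self.iF : self.iF + 5]
        viol5 = np.maximum(0.0, -F * (self.lmax[None, :] - g["l"]))
        res = {
            "limb_length": float(viol5.max()),
            "fore_exclusion": float((F[:, _I_LFT] * dv.Q[:, self.iJ]).max()),
        }
        if self.use_rate_exclusion:
            res["fore_force_rate"] = float(
                np.abs(F[:, _I_LFT] * dv.R[:, _I_LFL]).max()
            )
        return res

    def resample(self, z: np.ndarray, n_new: int) -> Tuple["QuadNLP", np.ndarray]:
        """Linearly resample a decision vector onto ``n_new`` nodes.

        Used both for the protocol's downsampling step and for midpoint
        mesh refinement (``n_new = 2 n - 1``).  Returns the new NLP and
        the resampled vector.
        """
        dv = self.decode(z)
        tau_new = np.linspace(0.0, 0.5, n_new)
        nlp = self.with_spec(n_nodes=n_new)

        def interp(arr):
            return np.column_stack(
                [np.interp(tau_new, self.tau, arr[:, j]) for j in range(arr.shape[1])]
            )

        dv_new = DecisionVector(
            interp(dv.Q), interp(dv.R), interp(dv.S), dv.xf.copy(), dv.eps.copy()
        )
        return nlp, nlp.encode(dv_new)

    def half_cycle(self, z: np.ndarray) -> HalfCycle:
        dv = self.decode(z)
        return HalfCycle(
            tau=self.tau.copy(),
            states=self.full_states(dv.Q),
            forces=dv.Q[:, self.iF : self.iF + 5].copy(),
            force_rates=dv.R.copy(),
            foot_x=self.channel_foot_x(dv.xf),
            body=self.body,
            task=self.task,
        )

    def to_trajectory(self, z: np.ndarray, tol: float = 1e-5) -> Trajectory:
        """Mirror the half-cycle solution into a full periodic stride."""
        return mirror_half_cycle(self.half_cycle(z), tol=tol)


def build_nlp(
    body: BodyModel,
    task: GaitTask,
    metric: Metric | str,
    spec: Optional[TranscriptionSpec] = None,
) -> QuadNLP:
    """Build the half-cycle direct-collocation NLP for one gait problem."""
    return QuadNLP(body, task, Metric(metric), spec or TranscriptionSpec())
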