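"""Multi-start staged solution of the gait NLP.

Each restart follows a staged protocol: an initial solve with a loose
relaxation-parameter penalty, re-solves with the penalty increased tenfold
per round (the final rounds also clamp the relaxation parameters to the
complementarity tolerance), then a midpoint mesh-refinement step and a
final solve on the refined grid.  A restart is *accepted* when the solver
converged, the unrelaxed complementarity conditions hold at every node,
and the work metrics are stable under mesh refinement.  Among accepted
restarts the one with the smallest total objective (work plus force-rate
and relaxation penalties) is the "pseudoglobal" optimum.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional

import numpy as np
from scipy.optimize import minimize

from .objectives import WorkBreakdown, evaluate_works
from .trajectory import Trajectory
from .transcription import DecisionVector, QuadNLP, relaxation_schedule

__all__ = [
    "SolveSettings",
    "SolveReport",
    "MultistartResult",
    "random_guess",
    "staged_solve",
    "multistart",
]


@dataclass(frozen=True)
class SolveSettings:
    """Tunable knobs of the staged solve and acceptance tests."""

    #: iteration caps per penalty round (length sets the number of rounds)
    round_maxiter: tuple = (300, 150, 150)
    #: iteration cap of the post-refinement solve
    refine_maxiter: int = 80
    #: rounds (counted from the end) with relaxation parameters clamped
    clamp_last_rounds: int = 2
    #: initial relaxation penalty weight (grows tenfold per round)
    w0: float = 1.0
    #: node-wise complementarity acceptance threshold (bw * l_H units)
    complementarity_tol: float = 1e-4
    #: accepted change of the work objective under mesh refinement (m g l_H)
    mesh_tol: float = 5e-3
    #: symmetry residual allowed when mirroring the half cycle
    symmetry_tol: float = 1e-5
    #: SLSQP convergence tolerance
    ftol: float = 1e-8
    #: maximum admissible constraint violation at the solution
    feas_tol: float = 1e-5


@dataclass
class SolveReport:
    """Outcome of one staged solve (one restart)."""

    seed: int
    converged: bool
    mesh_ok: bool
    complementarity_ok: bool
    objective: float
    objective_parts: Dict[str, float]
    works: Optional[WorkBreakdown]
    trajectory: Optional[Trajectory]
    z: Optional[np.ndarray] = None
    nlp: Optional[QuadNLP] = None
    rounds: List[dict] = field(default_factory=list)
    wall_time: float = 0.0

    @property
    def accepted(self) -> bool:
        return self.converged and self.mesh_ok and self.complementarity_ok


@dataclass
class MultistartResult:
    best: Optional[SolveReport]
    reports: List[SolveReport]

    @property
    def n_accepted(self) -> int:
        return sum(r.accepted for r in self.reports)


def random_guess(nlp: QuadNLP, seed: int) -> np.ndarray:
    """Deterministic random initial decision vector for one restart.

    Trunk height is sampled near standing, horizontal progress is linear
    from 0 to D/2 at the task speed, pitch is small and random, and each
    footfall channel gets a nonnegative random smooth force profile scaled
    so the mean total vertical force roughly supports body weight.
    Footfall positions are sampled within +/- D/2 of the mean position of
    the limb's attachment point.
    """
    rng = np.random.default_rng(seed)
    n = nlp.n
    tau = nlp.tau
    D, T = nlp.D, nlp.T
    body = nlp.body

    Q = np.zeros((n, nlp.ns))
    Q[:, nlp.ix] = np.linspace(0.0, D / 2, n)
    Q[:, nlp.iy] = rng.uniform(0.82, 0.98)
    Q[:, nlp.ivx] = nlp.task.speed
    if not nlp.point_mass:
        Q[:, nlp.ith] = rng.normal(0.0, 0.03)

    # random smooth nonnegative force profiles per channel
    knots = np.linspace(0.0, 0.5, 6)
    F = np.empty((n, 5))
    for j in range(5):
        vals = rng.uniform(0.0, 1.0, knots.size)
        F[:, j] = np.interp(tau, knots, vals)
    # enforce the reference-limb endpoint zeros with smooth windows
    ramp_up = np.clip(tau / 0.15, 0.0, 1.0)
    ramp_dn = np.clip((0.5 - tau) / 0.15, 0.0, 1.0)
    F[:, 0] *= ramp_up  # LH starts at zero
    F[:, 3] *= ramp_up  # LFl starts at zero
    F[:, 1] *= ramp_dn  # RH ends at zero
    F[:, 2] *= ramp_dn  # LFt ends at zero
    total = F.sum(axis=1).mean()
    if total > 1e-9:
        F *= rng.uniform(0.9, 1.1) / total
    Q[:, nlp.iF : nlp.iF + 5] = F

    # integral of the leading fore force, normalized time
    J = np.concatenate([[0.0], np.cumsum(0.5 * (F[1:, 3] + F[:-1, 3]) * nlp.h)])
    Q[:, nlp.iJ] = J

    R = np.column_stack([np.gradient(F[:, j], tau) for j in range(5)])

    # footfall parameters near the mean attachment positions
    hip_mean = D / 4 + body.hip_offset
    sh_mean = D / 4 + body.shoulder_offset
    xf = np.array(
        [
            hip_mean + rng.uniform(-D / 2, D / 2),
            sh_mean - D / 2 + rng.uniform(-D / 2, D / 2),
        ]
    )

    # consistent slacks and relaxation parameters
    dv = DecisionVector(Q, R, np.zeros((n, nlp.n_terms)), xf, np.zeros(nlp.n_eps))
    g = nlp._geometry(Q, xf)
    p, _, _ = nlp._power_terms(dv, g)
    dv.S[:] = np.maximum(p, 0.0) + 1e-3
    viol5 = np.maximum(0.0, -(F * (nlp.lmax[None, :] - g["l"]))).max()
    dv.eps[0] = viol5 + 1e-3
    dv.eps[1] = (F[:, 2] * J).max() + 1e-3
    if nlp.n_eps > 2:
        dv.eps[2] = np.abs(F[:, 2] * R[:, 3]).max() + 1e-3
    z = nlp.encode(dv)
    bounds = nlp.bounds()
    return np.clip(z, bounds[:, 0], bounds[:, 1])


def _solve_round(nlp: QuadNLP, z0: np.ndarray, maxiter: int, ftol: float):
    bounds = nlp.bounds()
    cons = [
        {"type": "eq", "fun": nlp.eq_constraints, "jac": nlp.eq_jacobian},
        {"type": "ineq", "fun": nlp.ineq_constraints, "jac": nlp.ineq_jacobian},
    ]
    try:
        res = minimize(
            nlp.objective,
            np.clip(z0, bounds[:, 0], bounds[:, 1]),
            jac=nlp.gradient,
            bounds=bounds,
            constraints=cons,
            method="SLSQP",
            options={"maxiter": maxiter, "ftol": ftol},
        )
    except (ValueError, FloatingPointError, np.linalg.LinAlgError) as exc:
        return None, f"solver exception: {exc}"
    if not np.all(np.isfinite(res.x)):
        return None, "non-finite iterate"
    return res, None


def _feasibility(nlp: QuadNLP, z: np.ndarray) -> float:
    ceq = nlp.eq_constraints(z)
    cin = nlp.ineq_constraints(z)
    return max(
        float(np.abs(ceq).max(initial=0.0)),
        float(np.maximum(0.0, -cin).max(initial=0.0)),
    )


def staged_solve(
    nlp: QuadNLP, z0: np.ndarray, settings: SolveSettings = SolveSettings(), seed: int = -1
) -> SolveReport:
    """Run the staged penalty/mesh protocol from one initial guess.

    Solver failure at any round is reported through the convergence flag,
    never raised.
    """
    t_start = time.perf_counter()
    rounds_log: List[dict] = []
    z = z0.copy()
    cur = nlp
    n_rounds = len(settings.round_maxiter)
    failure = None

    for ridx, maxiter in enumerate(settings.round_maxiter):
        w = relaxation_schedule(ridx, settings.w0)
        clamp = ridx >= n_rounds - settings.clamp_last_rounds
        eps_ub = settings.complementarity_tol if clamp else cur.spec.eps_upper
        cur = cur.with_spec(relaxation_penalty=w, eps_upper=eps_ub)
        res, err = _solve_round(cur, z, maxiter, settings.ftol)
        if res is None:
            failure = err
            break
        z = res.x
        rounds_log.append(
            {
                "round": ridx,
                "penalty": w,
                "n_nodes": cur.n,
                "maxiter": maxiter,
                "status": int(res.status),
                "objective": float(res.fun),
                "feasibility": _feasibility(cur, z),
                "kkt_message": str(res.message),
            }
        )

    converged = False
    mesh_ok = False
    comp_ok = False
    works = None
    traj = None
    obj = float("inf")
    parts: Dict[str, float] = {}

    if failure is None:
        # work metrics on the coarse solution (for the mesh-stability flag)
        try:
            traj_coarse = cur.to_trajectory(z, tol=max(
                settings.symmetry_tol, 10 * _feasibility(cur, z)
            ))
            works_coarse = evaluate_works(traj_coarse, c1=cur.spec.c1)
        except ValueError:
            works_coarse = None

        # midpoint mesh refinement + final solve
        fine, z_f = cur.resample(z, 2 * cur.n - 1)
        res, err = _solve_round(fine, z_f, settings.refine_maxiter, settings.ftol)
        if res is None:
            failure = err
        else:
            z = res.x
            cur = fine
            feas = _feasibility(cur, z)
            rounds_log.append(
                {
                    "round": "refine",
                    "penalty": cur.relax_weight,
                    "n_nodes": cur.n,
                    "maxiter": settings.refine_maxiter,
                    "status": int(res.status),
                    "objective": float(res.fun),
                    "feasibility": feas,
                    "kkt_message": str(res.message),
                }
            )
            # status 8 is SLSQP's linesearch stall, routinely hit at
            # numerically converged points; accept it when feasible
            converged = bool(res.status in (0, 8) and feas < settings.feas_tol)
            comp = cur.complementarity_residuals(z)
            comp_ok = max(comp.values()) <= settings.complementarity_tol
            obj = float(res.fun)
            parts = cur.objective_parts(z)
            try:
                traj = cur.to_trajectory(z, tol=max(settings.symmetry_tol, 10 * feas))
                works = evaluate_works(traj, c1=cur.spec.c1)
            except ValueError:
                traj, works = None, None
                converged = False
            if works is not None and works_coarse is not None:
                key = cur.metric.value
                delta = abs(
                    getattr(works, key) - getattr(works_coarse, key)
                )
                mesh_ok = delta <= settings.mesh_tol
            rounds_log[-1]["complementarity"] = comp

    if failure is not None:
        rounds_log.append({"round": "failed", "error": failure})

    return SolveReport(
        seed=seed,
        converged=converged,
        mesh_ok=mesh_ok,
        complementarity_ok=comp_ok,
        objective=obj,
        objective_parts=parts,
        works=works,
        trajectory=traj,
        z=z if failure is None else None,
        nlp=cur,
        rounds=rounds_log,
        wall_time=time.perf_counter() - t_start,
    )


def multistart(
    nlp_factory: Callable[[], QuadNLP],
    n_guesses: int,
    base_seed: int,
    settings: SolveSettings = SolveSettings(),
    progress: Optional[Callable[[int, SolveReport], None]] = None,
) -> MultistartResult:
    """Multi-start search: independent restarts, pseudoglobal selection.

    Restart ``k`` uses seed ``base_seed + k``.  Returns the accepted report
    with the smallest total objective together with all reports; ``best``
    is None when no restart was accepted.
    """
    if n_guesses < 1:
        raise ValueError("n_guesses must be at least 1")
    reports: List[SolveReport] = []
    for k in range(n_guesses):
        nlp = nlp_factory()
        seed = base_seed + k
        z0 = random_guess(nlp, seed)
        report = staged_solve(nlp, z0, settings, seed=seed)
        reports.append(report)
        if progress is not None:
            progress(k, report)
    accepted = [r for r in reports if r.accepted]
    best = min(accepted, key=lambda r: r.objective) if accepted else None
    return MultistartResult(best=best, reports=reports)
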