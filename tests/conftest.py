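"""Shared fixtures: bodies, tasks, and synthetic dynamically-consistent
trajectories (built by integrating the trunk dynamics under random smooth
force histories, so work-energy bookkeeping holds by construction)."""

from __future__ import annotations

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from quadwalk.core_model import BodyModel, GaitTask, Variant
from quadwalk.trajectory import FootfallTrace, Trajectory

HORSE_TASK = GaitTask(speed=0.4348, stride=1.345)


@pytest.fixture(scope="session")
def body_distributed() -> BodyModel:
    return BodyModel(variant=Variant.DISTRIBUTED)


@pytest.fixture(scope="session")
def body_point() -> BodyModel:
    return BodyModel(variant=Variant.POINT)


@pytest.fixture(scope="session")
def task() -> GaitTask:
    return HORSE_TASK


def random_consistent_trajectory(
    body: BodyModel, seed: int, duration: float = 1.5, n: int = 151
) -> Trajectory:
    """Integrate the trunk under random smooth nonnegative leg forces.

    Two footfalls (one hip, one shoulder); forces are clipped sinusoid
    mixtures scaled to roughly support body weight.  The result is
    dynamically consistent but generally not periodic.
    """
    rng = np.random.default_rng(seed)
    feet = np.array([rng.uniform(-1.0, 0.2), rng.uniform(0.2, 1.4)])
    offsets = np.array([body.hip_offset, body.shoulder_offset])
    amp = rng.uniform(0.2, 0.8, size=(2, 3))
    freq = rng.uniform(0.5, 3.0, size=(2, 3))
    phase = rng.uniform(0, 2 * np.pi, size=(2, 3))
    base = rng.uniform(0.3, 0.7, size=2)

    def forces(t):
        f = base + np.sum(amp * np.sin(2 * np.pi * freq * t + phase), axis=1)
        return np.clip(f, 0.0, None)

    point = body.is_point_mass
    inertia = None if point else body.inertia

    def rhs(t, s):
        x, y, th, vx, vy, om = s
        c, sn = (1.0, 0.0) if point else (np.cos(th), np.sin(th))
        ax = x + offsets * c - feet
        ay = y + offsets * sn
        l = np.hypot(ax, ay)
        ux, uy = ax / l, ay / l
        f = forces(t)
        out_om = 0.0
        if not point:
            w = offsets * (c * uy - sn * ux)
            out_om = np.sum(f * w) / inertia
        return [vx, vy, 0.0 if point else om,
                np.sum(f * ux) / body.mass,
                np.sum(f * uy) / body.mass - body.g,
                out_om]

    s0 = [0.0, rng.uniform(0.85, 0.95), 0.0, rng.uniform(0.2, 0.5),
          rng.uniform(-0.1, 0.1), 0.0]
    t_eval = np.linspace(0.0, duration, n)
    sol = solve_ivp(rhs, (0, duration), s0, t_eval=t_eval, rtol=1e-10, atol=1e-12)
    assert sol.success
    F = np.array([forces(t) for t in t_eval])
    traces = [
        FootfallTrace("LH", "hip", feet[0], F[:, 0]),
        FootfallTrace("LF", "shoulder", feet[1], F[:, 1]),
    ]
    return Trajectory(t=t_eval, states=sol.y.T, footfalls=traces, body=body,
                      periodic=False)


@pytest.fixture()
def consistent_traj(body_distributed) -> Trajectory:
    return random_consistent_trajectory(body_distributed, seed=7)
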