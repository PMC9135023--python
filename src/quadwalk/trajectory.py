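"""Time-sampled gait trajectories.

A :class:`Trajectory` holds trunk kinematics on a time grid together with a
list of footfall traces -- one per (limb, contact point) pair -- each
carrying the scalar axial force history acting through that fixed footfall.
A full symmetric stride built by mirroring a solved half cycle contains up
to seven such traces (a limb that both lifts off and touches down within the
stride contributes two).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np

from .core_model import BodyModel, GaitTask

__all__ = ["FootfallTrace", "Trajectory"]

_STATE_COLS = ("x", "y", "theta", "vx", "vy", "omega")


@dataclass
class FootfallTrace:
    """Axial force history of one limb acting through one fixed footfall."""

    limb: str  # physical limb label: LH, RH, LF or RF
    attachment: str  # "hip" or "shoulder"
    x_foot: float
    force: np.ndarray
    force_rate: Optional[np.ndarray] = None  # dF/dt', t' = t/T

    def __post_init__(self) -> None:
        self.force = np.asarray(self.force, dtype=float)
        if np.any(self.force < -1e-9):
            raise ValueError("footfall forces must be nonnegative")


@dataclass
class Trajectory:
    """Trunk kinematics plus per-footfall forces over one stride (or part).

    ``states`` has columns ``(x, y, theta, vx, vy, omega)``; for the
    point-mass variant the ``theta``/``omega`` columns are identically zero.
    Times are in internal units of ``sqrt(l_H / g)``.
    """

    t: np.ndarray
    states: np.ndarray
    footfalls: List[FootfallTrace]
    body: BodyModel
    task: Optional[GaitTask] = None
    periodic: bool = True
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.states = np.asarray(self.states, dtype=float)
        n = self.t.size
        if self.states.shape != (n, 6):
            raise ValueError("states must have shape (n, 6)")
        for tr in self.footfalls:
            if tr.force.shape != (n,):
                raise ValueError("footfall force length mismatch")

    # -- basic accessors -------------------------------------------------
    def col(self, name: str) -> np.ndarray:
        return self.states[:, _STATE_COLS.index(name)]

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0])

    @property
    def com_velocity(self) -> np.ndarray:
        return self.states[:, 3:5]

    # -- limb kinematics -------------------------------------------------
    def _offset(self, trace: FootfallTrace) -> float:
        if trace.attachment == "hip":
            return self.body.hip_offset
        if trace.attachment == "shoulder":
            return self.body.shoulder_offset
        raise ValueError(f"unknown attachment {trace.attachment!r}")

    def attachment_point(self, trace: FootfallTrace) -> np.ndarray:
        """Attachment-point positions, shape (n, 2)."""
        b = self._offset(trace)
        x, y, th = self.states[:, 0], self.states[:, 1], self.states[:, 2]
        if self.body.is_point_mass:
            return np.column_stack([x + b, y])
        return np.column_stack([x + b * np.cos(th), y + b * np.sin(th)])

    def attachment_velocity(self, trace: FootfallTrace) -> np.ndarray:
        b = self._offset(trace)
        th = self.states[:, 2]
        vx, vy, om = self.states[:, 3], self.states[:, 4], self.states[:, 5]
        if self.body.is_point_mass:
            return np.column_stack([vx, vy])
        return np.column_stack([vx - b * np.sin(th) * om, vy + b * np.cos(th) * om])

    def limb_kinematics(
        self, trace: FootfallTrace
    ) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Vectorized strut kinematics: ``(length, unit_vector, length_rate)``.

        ``unit_vector`` points from the foot to the attachment, shape (n, 2).
        """
        a = self.attachment_point(trace)
        va = self.attachment_velocity(trace)
        d = a - np.array([trace.x_foot, 0.0])
        length = np.hypot(d[:, 0], d[:, 1])
        if np.any(length < 1e-12):
            raise ValueError("degenerate limb geometry in trajectory")
        u = d / length[:, None]
        length_rate = np.einsum("ij,ij->i", u, va)
        return length, u, length_rate

    def limb_force_vectors(self, trace: FootfallTrace) -> np.ndarray:
        """Ground-reaction force vector of the trace on the trunk, (n, 2)."""
        _, u, _ = self.limb_kinematics(trace)
        return trace.force[:, None] * u

    def net_force(self) -> np.ndarray:
        """Net ground reaction force (sum over footfalls), shape (n, 2)."""
        total = np.zeros((self.t.size, 2))
        for tr in self.footfalls:
            total += self.limb_force_vectors(tr)
        return total

    # -- energies --------------------------------------------------------
    def com_energies(self) -> Tuple[np.ndarray, np.ndarray]:
        """Gravitational potential and translational kinetic energy series."""
        m, g = self.body.mass, self.body.g
        ep = m * g * self.states[:, 1]
        ek = 0.5 * m * (self.states[:, 3] ** 2 + self.states[:, 4] ** 2)
        return ep, ek

    def rotational_energy(self) -> np.ndarray:
        if self.body.is_point_mass:
            return np.zeros(self.t.size)
        return 0.5 * self.body.inertia * self.states[:, 5] ** 2

    def total_energy(self) -> np.ndarray:
        ep, ek = self.com_energies()
        return ep + ek + self.rotational_energy()

    # -- per-limb grouping ----------------------------------------------
    def limb_labels(self) -> List[str]:
        seen: List[str] = []
        for tr in self.footfalls:
            if tr.limb not in seen:
                seen.append(tr.limb)
        return seen

    def limb_force_magnitude(self, limb: str) -> np.ndarray:
        """Total axial force magnitude of one physical limb (its traces
        summed; traces of one limb do not overlap in a valid gait)."""
        out = np.zeros(self.t.size)
        for tr in self.footfalls:
            if tr.limb == limb:
                out += tr.force
        return out

    def translated(self, dx: float) -> "Trajectory":
        """Copy of the trajectory shifted horizontally by ``dx``."""
        states = self.states.copy()
        states[:, 0] += dx
        feet = [
            FootfallTrace(tr.limb, tr.attachment, tr.x_foot + dx, tr.force.copy(),
                          None if tr.force_rate is None else tr.force_rate.copy())
            for tr in self.footfalls
        ]
        return Trajectory(self.t.copy(), states, feet, self.body, self.task,
                          self.periodic, dict(self.meta))
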