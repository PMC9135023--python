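"""Planar quadruped body model: geometry, nondimensionalization and trunk dynamics.

The body is a single rigid trunk with four massless prismatic legs (struts).
Hindlimbs attach at the hips (acetabulum), forelimbs at the shoulders
(glenoid).  Each leg pushes along the axis from its fixed footfall to its
attachment point.  Two body variants are supported:

* ``distributed_mass`` -- the trunk carries a pitch moment of inertia set by
  the Murphy number ``4 I / (m GAD^2)``; forces applied off the center of
  mass produce pitch accelerations.
* ``point_mass`` -- rotational dynamics are omitted.  The attachment points
  stay at the hip/shoulder offsets of a permanently level trunk, so limb
  length constraints are preserved while forces produce no moments.

Internally everything is nondimensional: trunk mass, gravitational
acceleration and the maximum hindlimb length are all 1, so energies and
works are natively in units of ``m g l_H``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from enum import Enum
from typing import Iterable, Mapping, Tuple

__all__ = [
    "Variant",
    "Limb",
    "BodyModel",
    "GaitTask",
    "TrunkState",
    "Footfall",
    "DegenerateGeometryError",
    "limb_geometry",
    "trunk_dynamics",
    "nondimensionalize",
    "murphy_number",
]


class Variant(str, Enum):
    """Trunk mass model."""

    DISTRIBUTED = "distributed_mass"
    POINT = "point_mass"


class Limb(str, Enum):
    """Footfall channels of the half-cycle formulation.

    The left forelimb acts through two footfalls: a trailing (caudal) one,
    ``LFT``, from which it lifts off, and a leading (rostral) one, ``LFL``,
    one stride length further forward, on which it touches down.
    """

    LH = "LH"
    RH = "RH"
    LFT = "LFt"
    LFL = "LFl"
    RF = "RF"

    @property
    def is_hind(self) -> bool:
        return self in (Limb.LH, Limb.RH)


class DegenerateGeometryError(ValueError):
    """Raised when a limb has (near-)zero length, so its axis is undefined."""


@dataclass(frozen=True)
class BodyModel:
    """Geometric and inertial description of the trunk-and-struts quadruped.

    Parameters are stored in whatever unit system the caller uses; the
    ``nondimensionalize`` function maps an SI description to internal units
    where ``mass = g = l_H_max = 1``.

    Attributes
    ----------
    mass : trunk mass.
    g : gravitational acceleration.
    l_H_max : maximum hindlimb length (pes to hip in standing); the
        reference length of the model.
    l_F_max : maximum forelimb length, in the same units.
    gad : glenoacetabular distance (hips to shoulders).
    com_fraction : position of the COM along the hip->shoulder axis as a
        fraction of ``gad``, measured from the hips.
    murphy : Murphy number ``4 I / (m gad^2)``; ignored by the point-mass
        variant.
    variant : mass model, see :class:`Variant`.
    """

    mass: float = 1.0
    g: float = 1.0
    l_H_max: float = 1.0
    l_F_max: float = 1.0
    gad: float = 1.0
    com_fraction: float = 0.57
    murphy: float = 0.82
    variant: Variant = Variant.DISTRIBUTED

    def __post_init__(self) -> None:
        for name in ("mass", "g", "l_H_max", "l_F_max", "gad"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0.0 <= self.com_fraction <= 1.0:
            raise ValueError("com_fraction must lie in [0, 1]")
        if self.murphy < 0:
            raise ValueError("murphy must be nonnegative")
        # accept plain strings for convenience
        if not isinstance(self.variant, Variant):
            object.__setattr__(self, "variant", Variant(self.variant))

    @property
    def inertia(self) -> float:
        """Pitch moment of inertia, recovered from the Murphy number."""
        return self.murphy * self.mass * self.gad**2 / 4.0

    @property
    def hip_offset(self) -> float:
        """Signed distance from COM to hips along the trunk axis (negative:
        hips are caudal of the COM)."""
        return -self.com_fraction * self.gad

    @property
    def shoulder_offset(self) -> float:
        """Signed distance from COM to shoulders along the trunk axis."""
        return (1.0 - self.com_fraction) * self.gad

    def attachment_offset(self, limb: Limb) -> float:
        return self.hip_offset if limb.is_hind else self.shoulder_offset

    def max_length(self, limb: Limb) -> float:
        return self.l_H_max if limb.is_hind else self.l_F_max

    @property
    def is_point_mass(self) -> bool:
        return self.variant is Variant.POINT


@dataclass(frozen=True)
class GaitTask:
    """One optimization task: nondimensional speed and stride length.

    ``speed`` is ``U' = U / sqrt(g l_H)``; ``stride`` is ``D' = D / l_H``.
    The stride period (in units of ``sqrt(l_H / g)``) is derived, not free:
    ``T' = D' / U'``.
    """

    speed: float
    stride: float

    def __post_init__(self) -> None:
        if self.speed < 0:
            raise ValueError("speed must be nonnegative")
        if self.stride <= 0:
            raise ValueError("stride must be positive")

    @property
    def period(self) -> float:
        if self.speed == 0.0:
            raise ValueError("zero-speed task has no stride period")
        return self.stride / self.speed


@dataclass(frozen=True)
class TrunkState:
    """Planar trunk kinematics.

    ``theta`` is the pitch of the hip->shoulder axis above horizontal,
    counterclockwise positive (radians).  For the point-mass variant
    ``theta`` and ``omega`` are identically zero.
    """

    x: float
    y: float
    theta: float = 0.0
    vx: float = 0.0
    vy: float = 0.0
    omega: float = 0.0

    def __post_init__(self) -> None:
        if abs(self.theta) > math.pi / 2 + 1e-12:
            raise ValueError("pitch must lie within +/- pi/2")


@dataclass(frozen=True)
class Footfall:
    """A fixed ground-contact point for one footfall channel."""

    limb: Limb
    x_foot: float

    def __post_init__(self) -> None:
        if not isinstance(self.limb, Limb):
            object.__setattr__(self, "limb", Limb(self.limb))


def _attachment(state: TrunkState, body: BodyModel, limb: Limb):
    """Attachment point and its velocity for one limb."""
    b = body.attachment_offset(limb)
    if body.is_point_mass:
        ax, ay = state.x + b, state.y
        vax, vay = state.vx, state.vy
    else:
        c, s = math.cos(state.theta), math.sin(state.theta)
        ax, ay = state.x + b * c, state.y + b * s
        vax = state.vx - b * s * state.omega
        vay = state.vy + b * c * state.omega
    return ax, ay, vax, vay


def limb_geometry(
    state: TrunkState, body: BodyModel, foot: Footfall
) -> Tuple[float, Tuple[float, float], float]:
    """Length, axis and length rate of one strut limb.

    Returns ``(length, unit_vector, length_rate)`` where ``unit_vector``
    points from the foot to the attachment point (the direction a pushing
    force acts on the trunk) and ``length_rate`` is ``d length / dt`` given
    the trunk velocities.

    Raises
    ------
    DegenerateGeometryError
        if the attachment point coincides with the foot.
    ValueError
        if the attachment point is below ground.
    """
    ax, ay, vax, vay = _attachment(state, body, foot.limb)
    if ay < -1e-9:
        raise ValueError("attachment point below ground")
    dx, dy = ax - foot.x_foot, ay
    length = math.hypot(dx, dy)
    if length < 1e-12:
        raise DegenerateGeometryError(f"zero-length limb {foot.limb}")
    ux, uy = dx / length, dy / length
    length_rate = ux * vax + uy * vay
    return length, (ux, uy), length_rate


def trunk_dynamics(
    state: TrunkState,
    forces: Mapping[Footfall, float] | Iterable[Tuple[Footfall, float]],
    body: BodyModel,
) -> Tuple[float, float, float]:
    """Trunk accelerations ``(ax, ay, alpha)`` under axial leg forces.

    Each force is a scalar pushing force (must be nonnegative) acting along
    the limb axis, applied to the trunk at the limb's attachment point.  For
    the point-mass variant ``alpha`` is identically zero and moments are
    ignored.
    """
    items = forces.items() if isinstance(forces, Mapping) else forces
    fx = 0.0
    fy = 0.0
    torque = 0.0
    for foot, force in items:
        if force < 0:
            raise ValueError(f"negative force on {foot.limb}")
        if force == 0.0:
            continue
        _, (ux, uy), _ = limb_geometry(state, body, foot)
        fx += force * ux
        fy += force * uy
        if not body.is_point_mass:
            b = body.attachment_offset(foot.limb)
            rx = b * math.cos(state.theta)
            ry = b * math.sin(state.theta)
            torque += force * (rx * uy - ry * ux)
    ax = fx / body.mass
    ay = fy / body.mass - body.g
    alpha = 0.0 if body.is_point_mass else torque / body.inertia
    return ax, ay, alpha


def nondimensionalize(
    body_SI: BodyModel, speed_SI: float, stride_SI: float
) -> Tuple[BodyModel, GaitTask]:
    """Map an SI body and task to internal units ``m = g = l_H_max = 1``.

    Speed maps to ``U' = U / sqrt(g l_H)``, stride to ``D' = D / l_H``;
    length ratios and the dimensionless Murphy number carry over unchanged.
    Works computed downstream are then in units of ``m g l_H``.
    """
    if speed_SI < 0:
        raise ValueError("speed must be nonnegative")
    if stride_SI <= 0:
        raise ValueError("stride must be positive")
    l = body_SI.l_H_max
    body = replace(
        body_SI,
        mass=1.0,
        g=1.0,
        l_H_max=1.0,
        l_F_max=body_SI.l_F_max / l,
        gad=body_SI.gad / l,
    )
    u_prime = speed_SI / math.sqrt(body_SI.g * l)
    d_prime = stride_SI / l
    return body, GaitTask(speed=u_prime, stride=d_prime)


def murphy_number(inertia: float, mass: float, gad: float) -> float:
    """Dimensionless pitch inertia ``4 I / (m gad^2)``.

    Values below one mean a contact impulse at one end of the body pitches
    the other end downward.
    """
    if inertia < 0 or mass <= 0 or gad <= 0:
        raise ValueError("arguments must be positive (inertia nonnegative)")
    return 4.0 * inertia / (mass * gad**2)
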