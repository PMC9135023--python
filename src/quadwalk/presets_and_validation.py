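"""Shipped body presets and conservative toy systems for validation.

The horse preset carries the model dimensions of an adult Warmblood horse
and the walking task (nondimensional speed 0.43, stride length 1.34).

The toy systems are conservative one-degree-of-freedom mechanisms with
known pendular-recovery behaviour, used as analytic oracles for the energy
and work bookkeeping: a point pendulum and a bead on a frictionless wire
recover 100% of COM energy fluctuation; a physical pendulum and a rolling
ball do not, because energy passes through rotational kinetic energy which
the COM accounting ignores; and a quadruped reduced to a passive 4-bar
linkage recovers 100% in a parallelogram (trot-like) vault but less in a
staggered (four-beat-like) vault.
"""

from __future__ import annotations

import importlib.resources as _resources
import math
from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

import numpy as np
import yaml
from scipy.integrate import solve_ivp

from .core_model import BodyModel, GaitTask, Variant, nondimensionalize
from .objectives import percent_recovery
from .trajectory import Trajectory

__all__ = [
    "load_preset_config",
    "load_config",
    "config_to_model",
    "horse_preset",
    "ToySystem",
    "simulate_toy",
]


def load_config(source) -> dict:
    """Read a structured-text (YAML) configuration from a path or mapping."""
    if isinstance(source, dict):
        return source
    with open(source) as fh:
        return yaml.safe_load(fh)


def load_preset_config(name: str) -> dict:
    """Raw configuration dict of a packaged preset (``horse`` or
    ``horse_anatomical``)."""
    ref = _resources.files("quadwalk") / "presets" / f"{name}.yaml"
    if not ref.is_file():
        raise KeyError(f"unknown preset {name!r}")
    return yaml.safe_load(ref.read_text())


def config_to_model(cfg: dict) -> Tuple[BodyModel, GaitTask, dict]:
    """Build a nondimensional body and task from a configuration dict.

    Returns ``(body, task, optimization_options)``; the body/task section
    may be in SI units (they are nondimensionalized here).
    """
    bc = dict(cfg["body"])
    tc = dict(cfg["task"])
    body_si = BodyModel(**bc)
    speed = float(tc["speed"])
    if "stride" in tc:
        stride = float(tc["stride"])
    else:
        stride = speed * float(tc["stride_period"])
    body, task = nondimensionalize(body_si, speed, stride)
    return body, task, dict(cfg.get("optimization", {}))


def horse_preset(
    variant: Variant | str = Variant.DISTRIBUTED, anatomical: bool = False
) -> Tuple[BodyModel, GaitTask]:
    """The Warmblood horse walking preset, nondimensionalized.

    With ``anatomical=False`` (the main model) forelimb length and
    glenoacetabular distance equal the hindlimb length; with
    ``anatomical=True`` they take their measured values (1.14 m, 1.63 m).
    Either way the task is ``U' = 0.43``, ``D' = 1.34``.
    """
    cfg = load_preset_config("horse_anatomical" if anatomical else "horse")
    cfg["body"]["variant"] = Variant(variant)
    body, task, _ = config_to_model(cfg)
    return body, task


# ----------------------------------------------------------------------
# conservative toy systems
# ----------------------------------------------------------------------

_TOY_KINDS = (
    "point_pendulum",
    "physical_pendulum",
    "bead_on_wire",
    "rolling_ball",
    "passive_4bar",
)


@dataclass
class ToySystem:
    """A conservative one-degree-of-freedom validation mechanism.

    ``params`` are geometric/inertial settings (defaults chosen to make
    the recovery contrasts pronounced); ``q0``/``qdot0`` are the initial
    generalized coordinate and rate.
    """

    kind: str
    params: Dict[str, float] = field(default_factory=dict)
    q0: float = 0.5
    qdot0: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in _TOY_KINDS:
            raise ValueError(f"unknown toy system {self.kind!r}")


def _fourbar_pose(phi: float, p: Dict[str, float]):
    """Trunk pose of the passive 4-bar as a function of the hind-leg angle.

    Hind foot at the origin, fore foot at ``(sep, 0)``; rigid legs of
    length ``l_h``/``l_f``, trunk of length ``gad``.  The shoulder is the
    upper intersection of the circle of radius ``gad`` about the hip with
    the circle of radius ``l_f`` about the fore foot.
    """
    lh, lf, gad = p["l_h"], p["l_f"], p["gad"]
    cf = p["com_fraction"]
    hip = np.array([lh * math.sin(phi), lh * math.cos(phi)])
    foot2 = np.array([p["sep"], 0.0])
    d = foot2 - hip
    r = np.hypot(d[0], d[1])
    # circle-circle intersection (hip, gad) x (foot2, l_f)
    a = (gad**2 - lf**2 + r**2) / (2 * r)
    h2 = gad**2 - a**2
    if h2 < 0:
        raise ValueError("4-bar linkage cannot close for this configuration")
    h = math.sqrt(h2)
    mid = hip + a * d / r
    perp = np.array([-d[1], d[0]]) / r
    shoulder = mid + h * perp  # upper branch
    com = hip + cf * (shoulder - hip)
    theta = math.atan2(shoulder[1] - hip[1], shoulder[0] - hip[0])
    return com, theta


def _toy_model(system: ToySystem):
    """Return (rhs, state_map, body) for one toy system.

    ``state_map(q, qdot)`` gives the trunk-style state row
    ``(x, y, theta, vx, vy, omega)``; ``body`` carries mass and inertia so
    that the standard energy bookkeeping applies.
    """
    p = system.params
    g = 1.0

    def body_with_inertia(inertia: float) -> BodyModel:
        if inertia == 0.0:
            return BodyModel(variant=Variant.POINT)
        return BodyModel(murphy=4.0 * inertia, gad=1.0, variant=Variant.DISTRIBUTED)

    kind = system.kind
    if kind == "point_pendulum":
        L = p.setdefault("length", 1.0)

        def rhs(t, s):
            return [s[1], -g / L * math.sin(s[0])]

        def smap(q, qd):
            return (L * math.sin(q), -L * math.cos(q), 0.0,
                    L * math.cos(q) * qd, L * math.sin(q) * qd, 0.0)

        return rhs, smap, body_with_inertia(0.0)

    if kind == "physical_pendulum":
        r = p.setdefault("pivot_distance", 1.0)
        k2 = p.setdefault("gyration_sq", 1.0 / 3.0)  # rod-like

        def rhs(t, s):
            return [s[1], -g * r * math.sin(s[0]) / (r**2 + k2)]

        def smap(q, qd):
            return (r * math.sin(q), -r * math.cos(q), q,
                    r * math.cos(q) * qd, r * math.sin(q) * qd, qd)

        return rhs, smap, body_with_inertia(k2)

    if kind == "bead_on_wire":
        # frictionless wire y = A cos(2 pi x / lam)
        A = p.setdefault("amplitude", 0.15)
        lam = p.setdefault("wavelength", 2.0)
        w = 2 * math.pi / lam

        def slope(x):
            return -A * w * math.sin(w * x)

        def curv(x):
            return -A * w**2 * math.cos(w * x)

        def rhs(t, s):
            yp, ypp = slope(s[0]), curv(s[0])
            return [s[1], -(yp * ypp * s[1] ** 2 + g * yp) / (1 + yp**2)]

        def smap(q, qd):
            return (q, A * math.cos(w * q), 0.0, qd, slope(q) * qd, 0.0)

        return rhs, smap, body_with_inertia(0.0)

    if kind == "rolling_ball":
        # uniform sphere rolling without slipping inside a circular valley
        rho = p.setdefault("ball_radius", 0.1)
        Rv = p.setdefault("valley_radius", 1.0)
        Re = Rv - rho  # COM orbit radius

        def rhs(t, s):
            return [s[1], -g * math.sin(s[0]) / (Re * 7.0 / 5.0)]

        def smap(q, qd):
            # spin follows rolling: omega_ball = v / rho
            return (Re * math.sin(q), -Re * math.cos(q), 0.0,
                    Re * math.cos(q) * qd, Re * math.sin(q) * qd, Re * qd / rho)

        return rhs, smap, body_with_inertia(0.4 * rho**2)

    # passive_4bar
    p.setdefault("l_h", 1.0)
    p.setdefault("l_f", 1.0)
    p.setdefault("gad", 1.0)
    p.setdefault("com_fraction", 0.57)
    p.setdefault("sep", 1.0)  # foot separation; == gad -> parallelogram
    murphy = p.setdefault("murphy", 0.82)
    inertia = murphy * p["gad"] ** 2 / 4.0
    dphi = 1e-6

    def pose(q):
        return _fourbar_pose(q, p)

    def energies_terms(q, qd):
        com0, th0 = pose(q)
        com1, th1 = pose(q + dphi)
        com_1, th_1 = pose(q - dphi)
        drdq = (com1 - com_1) / (2 * dphi)
        dthdq = (th1 - th_1) / (2 * dphi)
        return com0, th0, drdq, dthdq

    def mass_fn(q):
        _, _, drdq, dthdq = energies_terms(q, 0.0)
        return float(drdq @ drdq) + inertia * dthdq**2

    def rhs(t, s):
        q, qd = s
        M0 = mass_fn(q)
        Mp = mass_fn(q + dphi)
        Mm = mass_fn(q - dphi)
        dM = (Mp - Mm) / (2 * dphi)
        com1, _ = pose(q + dphi)
        com_1, _ = pose(q - dphi)
        dV = g * (com1[1] - com_1[1]) / (2 * dphi)
        return [qd, -(0.5 * dM * qd**2 + dV) / M0]

    def smap(q, qd):
        com, th, drdq, dthdq = energies_terms(q, qd)
        v = drdq * qd
        return (com[0], com[1], th, v[0], v[1], dthdq * qd)

    return rhs, smap, body_with_inertia(inertia)


def simulate_toy(
    system: ToySystem,
    duration: float = 12.0,
    n_eval: int = 2001,
    until_rest: bool = False,
) -> Tuple[Trajectory, float]:
    """Forward-integrate a conservative toy system and evaluate recovery.

    Returns the trajectory (no footfalls; trunk-style states only) and the
    Cavagna percent recovery of its COM energy series.  Total mechanical
    energy is conserved to integrator tolerance.  With ``until_rest`` the
    integration stops at the next turning point (zero generalized rate),
    which makes the recovery of a released system exactly its closed-form
    value, free of partial-oscillation windowing.
    """
    rhs, smap, body = _toy_model(system)
    y0 = [system.q0, system.qdot0]
    if until_rest:
        if system.kind == "passive_4bar":
            # vaulting is inverted-pendulum motion: the natural window is a
            # symmetric pass over the top, ending at the mirrored angle
            target = -system.q0

            def turning(t, s):
                return s[0] - target

            turning.direction = 1.0 if system.qdot0 >= 0 else -1.0
        else:
            direction = 1.0 if rhs(0.0, y0)[1] < 0 else -1.0

            def turning(t, s):
                return s[1]

            turning.direction = direction
        turning.terminal = True
        probe = solve_ivp(
            rhs, (0.0, 10.0 * duration), y0, events=[turning],
            rtol=1e-8, atol=1e-10,
        )
        if not probe.success or not probe.t_events[0].size:
            raise RuntimeError("no turning point found for until_rest")
        duration = float(probe.t_events[0][0])
    t_eval = np.linspace(0.0, duration, n_eval)
    sol = solve_ivp(
        rhs, (0.0, duration), y0, t_eval=t_eval, rtol=1e-10, atol=1e-12
    )
    if not sol.success:
        raise RuntimeError(f"toy integration failed: {sol.message}")
    states = np.array([smap(q, qd) for q, qd in sol.y.T])
    traj = Trajectory(
        t=t_eval,
        states=states,
        footfalls=[],
        body=body,
        periodic=False,
        meta={"toy": system.kind, "params": dict(system.params)},
    )
    return traj, percent_recovery(traj)
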