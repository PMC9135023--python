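"""Optional matplotlib views of solved gaits (GRF traces, gait bars,
power traces).  Imported lazily so the core library has no hard
matplotlib dependency."""

from __future__ import annotations

from typing import Optional

import numpy as np

from .gait_metrics import GaitDiagram, gait_diagram, power_traces
from .trajectory import Trajectory

__all__ = ["plot_grf", "plot_gait_bars", "plot_power"]

_LIMB_ORDER = ("LH", "LF", "RH", "RF")


def _axes(ax):
    if ax is None:
        import matplotlib.pyplot as plt

        _, ax = plt.subplots()
    return ax


def plot_grf(traj: Trajectory, ax=None):
    """Per-limb ground reaction force magnitude over one stride."""
    ax = _axes(ax)
    tp = (traj.t - traj.t[0]) / traj.duration
    bw = traj.body.mass * traj.body.g
    for limb in _LIMB_ORDER:
        ax.plot(tp, traj.limb_force_magnitude(limb) / bw, label=limb)
    ax.set_xlabel("time (fraction of stride)")
    ax.set_ylabel("GRF (body weights)")
    ax.legend(frameon=False)
    return ax


def plot_gait_bars(diagram_or_traj, threshold: float = 0.02, ax=None):
    """Hildebrand-style stance bars (black = limb in stance)."""
    if isinstance(diagram_or_traj, Trajectory):
        diagram: GaitDiagram = gait_diagram(diagram_or_traj, threshold)
    else:
        diagram = diagram_or_traj
    ax = _axes(ax)
    for row, limb in enumerate(reversed(_LIMB_ORDER)):
        for a, b in diagram.stance_intervals[limb]:
            ax.barh(row, b - a, left=a, height=0.6, color="k")
    ax.set_yticks(range(len(_LIMB_ORDER)))
    ax.set_yticklabels(list(reversed(_LIMB_ORDER)))
    ax.set_xlim(0, 1)
    ax.set_xlabel("time (fraction of stride)")
    return ax


def plot_power(traj: Trajectory, kind: str = "net", ax=None):
    """Power traces: ``net`` (COM and system), ``com`` or ``extension``."""
    ax = _axes(ax)
    tp = (traj.t - traj.t[0]) / traj.duration
    tr = power_traces(traj)
    if kind == "net":
        ax.plot(tp, tr["net_com_power"], "k-", label="net COM power")
        ax.plot(tp, tr["net_system_power"], "k--", label="net system power")
    elif kind in ("com", "extension"):
        prefix = "com_power_" if kind == "com" else "ext_power_"
        for limb in _LIMB_ORDER:
            col = f"{prefix}{limb}"
            if col in tr:
                ax.plot(tp, tr[col], label=limb)
    else:
        raise ValueError(f"unknown power plot kind {kind!r}")
    ax.axhline(0.0, color="0.7", lw=0.5)
    ax.set_xlabel("time (fraction of stride)")
    ax.set_ylabel("power (m g l_H per time unit)")
    ax.legend(frameon=False)
    return ax
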