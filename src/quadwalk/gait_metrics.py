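"""Post-processing of solved gaits: stance diagrams, classification, power.

Stance is defined by the ground reaction force of a limb exceeding a
threshold (default 0.02 body weights), the same convention used for the
reported duty factors and footfall diagrams.  Classification distinguishes
the three characteristic solution families of the work-objective study:

* ``compliant_high_duty`` -- duty factors close to one with single-hump
  forces (typical of minimizing net COM work);
* ``single_stance_vaulting`` -- alternating periods with exactly one limb
  in stance (typical of minimizing individual-limbs COM work);
* ``four_beat_singlefoot`` -- four staggered touchdowns, support
  alternating between two and three limbs, duty factors near 0.5 (the
  stereotypical quadrupedal walk, obtained when minimizing limb extension
  work with a distributed-mass trunk).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Tuple

import numpy as np
import pandas as pd

from .objectives import DEFAULT_C1, WorkBreakdown, evaluate_works
from .trajectory import Trajectory

__all__ = [
    "STANCE_THRESHOLD",
    "GaitDiagram",
    "gait_diagram",
    "classify_gait",
    "power_traces",
    "work_table",
]

#: stance detection threshold, body weights
STANCE_THRESHOLD = 0.02

_LIMB_ORDER = ("LH", "LF", "RH", "RF")


@dataclass
class GaitDiagram:
    """Per-limb stance structure of one full stride.

    Intervals and phases are fractions of the stride.  ``phases`` gives
    each limb's first touchdown relative to the reference limb (LH).
    ``support_sequence`` run-length encodes the number of supporting limbs
    (e.g. ``"2-3-2-3"`` for a singlefoot walk).
    """

    stance_intervals: Dict[str, List[Tuple[float, float]]]
    duty_factors: Dict[str, float]
    phases: Dict[str, float]
    support_sequence: str
    min_support: int
    max_support: int
    threshold: float = STANCE_THRESHOLD
    features: dict = field(default_factory=dict)


def _stance_intervals(
    tp: np.ndarray, f: np.ndarray, threshold: float
) -> List[Tuple[float, float]]:
    """Closure of {t : f > threshold} as intervals in stride fractions.

    Crossing times are located by linear interpolation; gaps shorter than
    one grid step are merged.
    """
    above = f > threshold
    if not above.any():
        return []
    if above.all():
        return [(0.0, 1.0)]
    h = tp[1] - tp[0]
    edges: List[List[float]] = []
    # rising/falling crossings with linear interpolation
    start: Optional[float] = tp[0] if above[0] else None
    for k in range(len(tp) - 1):
        f0, f1 = f[k], f[k + 1]
        if not above[k] and above[k + 1]:
            tc = tp[k] + (threshold - f0) / (f1 - f0) * (tp[k + 1] - tp[k])
            start = tc
        elif above[k] and not above[k + 1]:
            tc = tp[k] + (threshold - f0) / (f1 - f0) * (tp[k + 1] - tp[k])
            edges.append([start if start is not None else tp[k], tc])
            start = None
    if start is not None:
        edges.append([start, tp[-1]])
    # merge sub-grid gaps
    merged: List[List[float]] = [edges[0]]
    for a, b in edges[1:]:
        if a - merged[-1][1] < h:
            merged[-1][1] = b
        else:
            merged.append([a, b])
    # merge across the periodic wrap
    if len(merged) > 1 and merged[0][0] <= 0.0 + 1e-12 and merged[-1][1] >= 1.0 - 1e-12:
        pass  # handled implicitly: interval list stays within [0, 1)
    return [(a, b) for a, b in merged]


def _touchdowns(intervals: List[Tuple[float, float]]) -> List[float]:
    """Touchdown times, treating an interval starting at 0 that continues a
    wrap-around stance (another interval ending at 1) as no touchdown."""
    if not intervals:
        return []
    tds = [a for a, _ in intervals]
    wraps = intervals[0][0] <= 1e-12 and intervals[-1][1] >= 1.0 - 1e-12
    if wraps and len(intervals) >= 1:
        tds = tds[1:] if len(intervals) > 1 else []
    return tds


def gait_diagram(
    traj: Trajectory, threshold: float = STANCE_THRESHOLD
) -> GaitDiagram:
    """Stance intervals, duty factors and limb phases of a full stride."""
    tp = (traj.t - traj.t[0]) / traj.duration
    bw = traj.body.mass * traj.body.g
    intervals: Dict[str, List[Tuple[float, float]]] = {}
    duty: Dict[str, float] = {}
    for limb in _LIMB_ORDER:
        f = traj.limb_force_magnitude(limb) / bw
        ivs = _stance_intervals(tp, f, threshold)
        intervals[limb] = ivs
        duty[limb] = float(sum(b - a for a, b in ivs))

    # phases relative to the reference limb's touchdown
    tds = {limb: _touchdowns(intervals[limb]) for limb in _LIMB_ORDER}
    ref = tds["LH"][0] if tds["LH"] else 0.0
    phases = {
        limb: float((tds[limb][0] - ref) % 1.0) if tds[limb] else float("nan")
        for limb in _LIMB_ORDER
    }

    # support count on a fine grid
    grid = np.linspace(0.0, 1.0, 2001, endpoint=False)
    support = np.zeros(grid.size, dtype=int)
    for limb in _LIMB_ORDER:
        in_st = np.zeros(grid.size, dtype=bool)
        for a, b in intervals[limb]:
            in_st |= (grid >= a) & (grid < b)
        support += in_st
    seq: List[int] = []
    for s in support:
        if not seq or seq[-1] != s:
            seq.append(int(s))
    if len(seq) > 1 and seq[0] == seq[-1]:
        seq = seq[:-1]
    n_td = sum(len(v) for v in tds.values())
    return GaitDiagram(
        stance_intervals=intervals,
        duty_factors=duty,
        phases=phases,
        support_sequence="-".join(map(str, seq)),
        min_support=int(support.min()),
        max_support=int(support.max()),
        threshold=threshold,
        features={"n_touchdowns": n_td},
    )


def _hump_count_segment(seg: np.ndarray, threshold: float, peak_scale: float) -> int:
    """Count force humps in one contiguous stance segment.

    Local maxima of the 3-point moving-average force, above the stance
    threshold and with prominence at least 10% of the limb's peak force
    (small load-shifting wobbles are not humps), merged unless separated
    by a trough at least 5% of the lower peak below it.
    """
    if seg.size < 3:
        return 1 if seg.size else 0
    from scipy.ndimage import uniform_filter1d
    from scipy.signal import find_peaks

    sm = uniform_filter1d(seg, size=3, mode="nearest")

    peaks, _ = find_peaks(sm, height=threshold, prominence=0.1 * peak_scale)
    peaks = list(peaks)
    if not peaks:
        return 1 if sm.max() > threshold else 0
    # merge peaks without a sufficient trough between them
    humps = [peaks[0]]
    for pk in peaks[1:]:
        lower = min(sm[humps[-1]], sm[pk])
        trough = sm[humps[-1] : pk + 1].min()
        if trough <= 0.95 * lower:
            humps.append(pk)
        elif sm[pk] > sm[humps[-1]]:
            humps[-1] = pk
    return len(humps)


def hump_counts(
    traj: Trajectory, threshold: float = STANCE_THRESHOLD
) -> Dict[str, int]:
    """Maximum hump count over each limb's stance intervals.

    A stance crossing the periodic stride boundary (one interval ending at
    1 and another starting at 0) is stitched back together before counting.
    """
    tp = (traj.t - traj.t[0]) / traj.duration
    bw = traj.body.mass * traj.body.g
    out: Dict[str, int] = {}
    for limb in _LIMB_ORDER:
        f = traj.limb_force_magnitude(limb) / bw
        ivs = _stance_intervals(tp, f, threshold)
        scale = float(f.max())
        wraps = (
            len(ivs) > 1 and ivs[0][0] <= 1e-12 and ivs[-1][1] >= 1.0 - 1e-12
        )
        segments = []
        inner = ivs
        if wraps:
            (a0, b0), (a1, b1) = ivs[0], ivs[-1]
            # drop the duplicated endpoint sample when stitching
            stitched = np.concatenate(
                [f[(tp >= a1) & (tp <= b1)][:-1], f[(tp >= a0) & (tp <= b0)]]
            )
            segments.append(stitched)
            inner = ivs[1:-1]
        for a, b in inner:
            segments.append(f[(tp >= a) & (tp <= b)])
        out[limb] = max(
            (_hump_count_segment(s, threshold, scale) for s in segments), default=0
        )
    return out


def classify_gait(
    diagram: GaitDiagram, traj: Optional[Trajectory] = None
) -> str:
    """Classify a gait diagram into one of the study's solution families.

    Returns ``"other"`` when no family matches; the diagram's ``features``
    dict then carries the measured feature vector.
    """
    humps = hump_counts(traj, diagram.threshold) if traj is not None else {}
    duties = [diagram.duty_factors[l] for l in _LIMB_ORDER]
    diagram.features.update(
        {
            "duty_factors": dict(diagram.duty_factors),
            "hump_counts": humps,
            "min_support": diagram.min_support,
            "max_support": diagram.max_support,
        }
    )
    single_hump = all(h <= 1 for h in humps.values()) if humps else True
    if min(duties) > 0.8 and single_hump:
        return "compliant_high_duty"
    has_single_stance = "1" in diagram.support_sequence.split("-")
    if has_single_stance:
        return "single_stance_vaulting"
    n_td = diagram.features.get("n_touchdowns", 0)
    if (
        n_td == 4
        and diagram.min_support >= 2
        and diagram.max_support <= 3
        and all(0.45 <= d <= 0.75 for d in duties)
    ):
        return "four_beat_singlefoot"
    return "other"


def power_traces(traj: Trajectory, include_per_limb: bool = True) -> pd.DataFrame:
    """Power time series of one full stride.

    Columns: ``net_com_power`` (net GRF dotted with COM velocity),
    ``net_system_power`` (rate of total mechanical energy), and per limb
    ``com_power_<limb>`` and ``ext_power_<limb>``.  Integrating the
    positive part of each trace reproduces the corresponding work metric.
    """
    v = traj.com_velocity
    data = {
        "net_com_power": np.einsum("ij,ij->i", traj.net_force(), v),
        "net_system_power": np.gradient(traj.total_energy(), traj.t),
    }
    if include_per_limb:
        for limb in traj.limb_labels():
            pc = np.zeros(traj.t.size)
            pe = np.zeros(traj.t.size)
            for tr in traj.footfalls:
                if tr.limb != limb:
                    continue
                pc += np.einsum("ij,ij->i", traj.limb_force_vectors(tr), v)
                _, _, ldot = traj.limb_kinematics(tr)
                pe += tr.force * ldot
            data[f"com_power_{limb}"] = pc
            data[f"ext_power_{limb}"] = pe
    return pd.DataFrame(data, index=pd.Index(traj.t, name="t"))


def work_table(
    solutions: Mapping[str, Trajectory | WorkBreakdown],
    c1: float = DEFAULT_C1,
) -> pd.DataFrame:
    """Cross-evaluation table of work metrics, one column per objective.

    Rows are NCW, NSW, ILCW, LEW and percent recovery; a missing solution
    yields a column of NaN.  On a consistent set of optima each metric's
    own optimizer attains the smallest value within that metric's row.
    """
    rows = ("NCW", "NSW", "ILCW", "LEW", "Percent Recovery")
    cols = {}
    for name in ("NCW", "ILCW", "LEW"):
        sol = solutions.get(name) or solutions.get(name.lower())
        if sol is None:
            cols[name] = [np.nan] * 5
            continue
        wb = sol if isinstance(sol, WorkBreakdown) else evaluate_works(sol, c1)
        cols[name] = [wb.ncw, wb.nsw, wb.ilcw, wb.lew, wb.percent_recovery]
    return pd.DataFrame(cols, index=pd.Index(rows, name="metric"))
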