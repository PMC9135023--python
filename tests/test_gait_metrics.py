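"""Gait diagrams, classification, power traces and the work table."""

import numpy as np
import pandas as pd
import pytest

from quadwalk.core_model import BodyModel, Variant
from quadwalk.gait_metrics import (
    GaitDiagram,
    classify_gait,
    gait_diagram,
    hump_counts,
    power_traces,
    work_table,
)
from quadwalk.objectives import evaluate_works, positive_part_integral
from quadwalk.trajectory import FootfallTrace, Trajectory
from conftest import random_consistent_trajectory


def _synthetic_gait(force_profiles, n=400, body=None):
    """Periodic trajectory with prescribed per-limb force profiles.

    Kinematics are a flat constant-speed walk; only the forces matter for
    stance analysis."""
    body = body or BodyModel(variant=Variant.DISTRIBUTED)
    t = np.linspace(0.0, 3.0, n)
    states = np.zeros((n, 6))
    states[:, 0] = 0.4 * t
    states[:, 1] = 0.95
    states[:, 3] = 0.4
    feet = {"LH": -0.5, "LF": 0.6, "RH": 0.1, "RF": 1.2}
    traces = [
        FootfallTrace(limb, "hip" if limb.endswith("H") else "shoulder",
                      feet[limb], np.asarray(prof, float))
        for limb, prof in force_profiles.items()
    ]
    return Trajectory(t, states, traces, body, periodic=True)


def _square(tp, start, stop, amp=1.0):
    """Periodic square force wave active on [start, stop) mod 1."""
    frac = tp % 1.0
    if start <= stop:
        on = (frac >= start) & (frac < stop)
    else:
        on = (frac >= start) | (frac < stop)
    return amp * on.astype(float)


class TestGaitDiagram:
    def test_square_wave_duty_factor(self):
        tp = np.linspace(0, 1, 400)
        profs = {limb: _square(tp, 0.1, 0.7) for limb in ("LH", "LF", "RH", "RF")}
        traj = _synthetic_gait(profs, n=400)
        d = gait_diagram(traj)
        for limb in ("LH", "LF", "RH", "RF"):
            assert d.duty_factors[limb] == pytest.approx(0.6, abs=0.02)

    def test_always_loaded_limb_has_duty_one(self):
        tp = np.linspace(0, 1, 300)
        profs = {"LH": np.ones_like(tp), "LF": _square(tp, 0.0, 0.5),
                 "RH": np.ones_like(tp), "RF": _square(tp, 0.5, 1.0)}
        d = gait_diagram(_synthetic_gait(profs, n=300))
        assert d.duty_factors["LH"] == pytest.approx(1.0)

    def test_never_loaded_limb_has_empty_stance(self):
        tp = np.linspace(0, 1, 300)
        profs = {"LH": np.zeros_like(tp), "LF": np.ones_like(tp),
                 "RH": np.ones_like(tp), "RF": np.ones_like(tp)}
        d = gait_diagram(_synthetic_gait(profs, n=300))
        assert d.stance_intervals["LH"] == []
        assert d.duty_factors["LH"] == 0.0

    def test_two_intervals_match_level_set_oracle(self):
        """A stance force dipping below threshold mid-stance (gap wider
        than a grid step) splits into two intervals matching the
        brute-force level set."""
        n = 1000
        tp = np.linspace(0, 1, n)
        f = _square(tp, 0.1, 0.4) + _square(tp, 0.5, 0.8)
        profs = {"LH": f, "LF": np.ones(n), "RH": np.ones(n), "RF": np.ones(n)}
        traj = _synthetic_gait(profs, n=n)
        d = gait_diagram(traj, threshold=0.02)
        assert len(d.stance_intervals["LH"]) == 2
        # brute-force level set measure
        measured = sum(b - a for a, b in d.stance_intervals["LH"])
        oracle = np.mean(f > 0.02)
        assert measured == pytest.approx(oracle, abs=0.01)

    def test_phases_relative_to_reference_limb(self):
        tp = np.linspace(0, 1, 800)
        profs = {
            "LH": _square(tp, 0.10, 0.65),
            "LF": _square(tp, 0.35, 0.90),
            "RH": _square(tp, 0.60, 0.15),
            "RF": _square(tp, 0.85, 0.40),
        }
        d = gait_diagram(_synthetic_gait(profs, n=800))
        assert d.phases["LH"] == 0.0
        assert d.phases["LF"] == pytest.approx(0.25, abs=0.02)
        assert d.phases["RH"] == pytest.approx(0.5, abs=0.02)
        # hind-hind separation is half a stride by symmetry
        assert (d.phases["RH"] - d.phases["LH"]) % 1 == pytest.approx(0.5, abs=0.02)

    def test_duty_and_phase_invariant_to_left_right_relabel(self):
        tp = np.linspace(0, 1, 800)
        profs = {
            "LH": _square(tp, 0.10, 0.65),
            "LF": _square(tp, 0.35, 0.90),
            "RH": _square(tp, 0.60, 0.15),
            "RF": _square(tp, 0.85, 0.40),
        }
        traj = _synthetic_gait(profs, n=800)
        swapped = _synthetic_gait(
            {"RH": profs["LH"], "RF": profs["LF"],
             "LH": profs["RH"], "LF": profs["RF"]}, n=800)
        d1, d2 = gait_diagram(traj), gait_diagram(swapped)
        assert sorted(d1.duty_factors.values()) == pytest.approx(
            sorted(d2.duty_factors.values())
        )


class TestClassification:
    def test_compliant_high_duty(self):
        tp = np.linspace(0, 1, 600)
        base = 0.5 + 0.2 * np.sin(2 * np.pi * tp)  # single smooth hump
        profs = {l: np.clip(base, 0.03, None) for l in ("LH", "LF", "RH", "RF")}
        traj = _synthetic_gait(profs, n=600)
        d = gait_diagram(traj)
        assert classify_gait(d, traj) == "compliant_high_duty"

    def test_single_stance_vaulting(self):
        tp = np.linspace(0, 1, 800)
        profs = {
            "LH": _square(tp, 0.00, 0.20),
            "LF": _square(tp, 0.25, 0.45),
            "RH": _square(tp, 0.50, 0.70),
            "RF": _square(tp, 0.75, 0.95),
        }
        traj = _synthetic_gait(profs, n=800)
        d = gait_diagram(traj)
        assert d.min_support <= 1
        assert classify_gait(d, traj) == "single_stance_vaulting"

    def test_four_beat_singlefoot_with_double_humps(self):
        tp = np.linspace(0, 1, 1200)

        def double_hump(start):
            # camel-shaped stance force: peaks near 1/4 and 3/4 of stance
            frac = (tp - start) % 1.0
            on = frac < 0.6
            s = np.sin(np.pi * frac / 0.6)
            shape = s * (1.0 - 0.6 * s**2)
            return np.where(on, np.abs(shape), 0.0)

        profs = {
            "LH": double_hump(0.0),
            "LF": double_hump(0.25),
            "RH": double_hump(0.5),
            "RF": double_hump(0.75),
        }
        traj = _synthetic_gait(profs, n=1200)
        d = gait_diagram(traj)
        label = classify_gait(d, traj)
        assert label == "four_beat_singlefoot"
        assert all(h == 2 for h in hump_counts(traj).values())
        assert d.min_support == 2 and d.max_support == 3

    def test_unclassifiable_returns_other_with_features(self):
        tp = np.linspace(0, 1, 400)
        profs = {
            "LH": _square(tp, 0.0, 0.3),
            "LF": _square(tp, 0.0, 0.3),
            "RH": _square(tp, 0.0, 0.3),
            "RF": _square(tp, 0.0, 0.3),
        }
        traj = _synthetic_gait(profs, n=400)
        d = gait_diagram(traj)
        assert classify_gait(d, traj) == "other"
        assert "duty_factors" in d.features


class TestPowerTraces:
    def test_positive_part_integrals_reproduce_work_breakdown(self, body_distributed):
        traj = random_consistent_trajectory(body_distributed, seed=13)
        traj.periodic = True
        wb = evaluate_works(traj)
        tr = power_traces(traj)
        assert positive_part_integral(traj.t, tr["net_com_power"].values) == (
            pytest.approx(wb.ncw, rel=1e-9)
        )
        ext_total = sum(
            positive_part_integral(traj.t, tr[f"ext_power_{l}"].values)
            for l in traj.limb_labels()
        )
        assert ext_total == pytest.approx(wb.lew, rel=1e-9)
        com_total = sum(
            positive_part_integral(traj.t, tr[f"com_power_{l}"].values)
            for l in traj.limb_labels()
        )
        assert com_total == pytest.approx(wb.ilcw, rel=1e-9)

    def test_point_mass_com_equals_extension_power(self, body_point):
        traj = random_consistent_trajectory(body_point, seed=14)
        traj.periodic = True
        tr = power_traces(traj)
        for limb in traj.limb_labels():
            np.testing.assert_allclose(
                tr[f"com_power_{limb}"], tr[f"ext_power_{limb}"], atol=1e-12
            )

    def test_constant_length_vault_has_zero_extension_power(self, body_point):
        n = 200
        phi = np.linspace(-0.3, 0.3, n)
        t = np.linspace(0, 1, n)
        states = np.zeros((n, 6))
        b = body_point.hip_offset
        l0 = 0.9
        states[:, 0] = l0 * np.sin(phi) - b
        states[:, 1] = l0 * np.cos(phi)
        dphi = (phi[-1] - phi[0]) / 1.0
        states[:, 3] = l0 * np.cos(phi) * dphi
        states[:, 4] = -l0 * np.sin(phi) * dphi
        traj = Trajectory(t, states,
                          [FootfallTrace("LH", "hip", 0.0, np.ones(n))],
                          body_point, periodic=True)
        tr = power_traces(traj)
        np.testing.assert_allclose(tr["ext_power_LH"], 0.0, atol=1e-10)


class TestWorkTable:
    def test_structure_and_missing_column(self, body_distributed):
        traj = random_consistent_trajectory(body_distributed, seed=15)
        traj.periodic = True
        table = work_table({"NCW": traj, "LEW": traj})
        assert list(table.columns) == ["NCW", "ILCW", "LEW"]
        assert list(table.index) == ["NCW", "NSW", "ILCW", "LEW", "Percent Recovery"]
        assert table["ILCW"].isna().all()
        assert table.loc["NCW", "NCW"] == table.loc["NCW", "LEW"]
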