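"""Longitudinal evaluation framework, checked against brute-force counting
on enumerable toy cohorts."""

import numpy as np
import pandas as pd
import pytest

from conftest import random_screens
from hccscreen.evaluate import (
    EXCLUDED,
    FP,
    TP,
    DetectionWindow,
    classify_screens,
    decile_risk,
    evaluate_positives,
    false_positive_burden,
    first_positive_comparison,
    patient_tpr,
    performance_curves,
    ppv_npv,
    screening_fpr,
    standard_windows,
)
from hccscreen.policy import apply_threshold, calibrate_threshold


# ---------------------------------------------------------------- brute force
def brute_force_measures(screens: pd.DataFrame, positive, window, include_excluded=True):
    """Naive per-screen loops implementing the definitions directly."""
    pos = list(np.asarray(positive, dtype=bool))
    rows = list(screens.itertuples())

    def region(r):
        if r.delta == 0:
            return FP
        if r.t > r.d - window.tau2:
            return EXCLUDED
        if r.t >= r.d - window.tau1:
            return TP
        return FP

    eligible_cases, detected_cases = set(), set()
    n_fp = n_fp_pos = 0
    n_pos = n_pos_tp = n_neg = n_neg_fp = 0
    fp_counts, fp_patients = {}, set()
    for r, p in zip(rows, pos):
        reg = region(r)
        if reg == TP:
            eligible_cases.add(r.patient_id)
            if p:
                detected_cases.add(r.patient_id)
        if reg == FP:
            n_fp += 1
            fp_patients.add(r.patient_id)
            if p:
                n_fp_pos += 1
                fp_counts[r.patient_id] = fp_counts.get(r.patient_id, 0) + 1
        if include_excluded or reg != EXCLUDED:
            if p:
                n_pos += 1
                n_pos_tp += reg == TP
            else:
                n_neg += 1
                n_neg_fp += reg == FP
    return {
        "tpr": len(detected_cases) / len(eligible_cases) if eligible_cases else np.nan,
        "fpr": n_fp_pos / n_fp if n_fp else np.nan,
        "ppv": n_pos_tp / n_pos if n_pos else np.nan,
        "npv": n_neg_fp / n_neg if n_neg else np.nan,
        "burden": sum(c > 2 for c in fp_counts.values()) / len(fp_patients) if fp_patients else np.nan,
    }


class TestWindows:
    def test_standard_window_boundaries(self):
        w = standard_windows(87.0)
        assert (w["A1"].tau1, w["A1"].tau2) == (6.0, 0.0)
        assert (w["B2"].tau1, w["B2"].tau2) == (12.0, 3.0)
        assert (w["C1"].tau1, w["C1"].tau2) == (24.0, 0.0)
        assert (w["D2"].tau1, w["D2"].tau2) == (87.0, 3.0)

    def test_invalid_window(self):
        with pytest.raises(ValueError):
            DetectionWindow(3.0, 6.0)


class TestClassification:
    def test_case_boundaries(self):
        screens = pd.DataFrame(
            {"patient_id": ["a"] * 4, "delta": 1, "d": 30.0, "t": [5.0, 6.0, 28.0, 30.0]}
        )
        c1 = classify_screens(screens, DetectionWindow(24.0, 0.0))
        assert list(c1) == [FP, TP, TP, TP]  # t = 6 = d - tau1 inclusive
        a2 = classify_screens(screens, DetectionWindow(6.0, 3.0))
        assert list(a2) == [FP, FP, EXCLUDED, EXCLUDED]  # t = 28 > d - 3

    def test_controls_always_fp_eligible(self):
        screens = pd.DataFrame({"patient_id": ["b"] * 3, "delta": 0, "d": 40.0, "t": [1.0, 39.0, 39.9]})
        assert (classify_screens(screens, DetectionWindow(6.0, 3.0)) == FP).all()

    def test_window_nesting_of_tp_sets(self):
        rng = np.random.default_rng(0)
        screens = random_screens(rng, n_cases=8, n_controls=0)
        w = standard_windows(float(screens["d"].max()))
        tp_sets = [set(screens.index[(classify_screens(screens, w[l]) == TP)]) for l in ("A1", "B1", "C1", "D1")]
        for smaller, larger in zip(tp_sets, tp_sets[1:]):
            assert smaller <= larger


class TestMeasuresAgainstBruteForce:
    @pytest.mark.parametrize("label", ["A1", "B1", "C1", "D1", "A2", "B2", "C2", "D2"])
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_oracle_equivalence_all_windows(self, label, seed):
        rng = np.random.default_rng(seed)
        screens = random_screens(rng)
        window = standard_windows(float(screens["d"].max()))[label]
        pos = screens["positive"].to_numpy()
        expected = brute_force_measures(screens, pos, window)
        m = evaluate_positives(screens, pos, window)
        for key in ("tpr", "fpr", "ppv", "npv"):
            np.testing.assert_equal(m[key], expected[key])
        np.testing.assert_equal(false_positive_burden(screens, pos, window), expected["burden"])

    @pytest.mark.parametrize("include_excluded", [True, False])
    def test_ppv_npv_excluded_region_modes(self, include_excluded):
        rng = np.random.default_rng(5)
        screens = random_screens(rng)
        window = DetectionWindow(12.0, 3.0)
        pos = screens["positive"].to_numpy()
        expected = brute_force_measures(screens, pos, window, include_excluded)
        ppv, npv = ppv_npv(screens, pos, window, include_excluded)
        np.testing.assert_equal(ppv, expected["ppv"])
        np.testing.assert_equal(npv, expected["npv"])


class TestMeasureEdgeCases:
    def test_case_without_in_window_screen_not_evaluable(self):
        screens = pd.DataFrame(
            {
                "patient_id": ["a", "a", "b"],
                "delta": [1, 1, 1],
                "d": [50.0, 50.0, 50.0],
                "t": [1.0, 10.0, 45.0],
            }
        )
        tpr, n = patient_tpr(screens, [True, True, True], DetectionWindow(24.0, 0.0))
        assert n == 1  # patient a only screened before d - 24
        assert tpr == 1.0

    def test_two_cases_one_detected(self):
        screens = pd.DataFrame(
            {"patient_id": ["a", "b"], "delta": 1, "d": 20.0, "t": [15.0, 15.0]}
        )
        tpr, n = patient_tpr(screens, [True, False], DetectionWindow(24.0, 0.0))
        assert (tpr, n) == (0.5, 2)

    def test_all_negative_controls_zero_fpr(self):
        screens = pd.DataFrame({"patient_id": ["a"] * 10, "delta": 0, "d": 40.0, "t": np.arange(10.0)})
        fpr, n = screening_fpr(screens, [False] * 10, DetectionWindow(6.0, 0.0))
        assert (fpr, n) == (0.0, 10)

    def test_one_in_ten_positive_fpr(self):
        screens = pd.DataFrame({"patient_id": ["a"] * 10, "delta": 0, "d": 40.0, "t": np.arange(10.0)})
        fpr, _ = screening_fpr(screens, [True] + [False] * 9, DetectionWindow(6.0, 0.0))
        assert fpr == pytest.approx(0.1)

    def test_perfect_algorithm_unit_predictive_values(self):
        screens = pd.DataFrame(
            {
                "patient_id": ["a", "a", "b", "b"],
                "delta": [1, 1, 0, 0],
                "d": [30.0, 30.0, 60.0, 60.0],
                "t": [2.0, 25.0, 10.0, 20.0],
            }
        )
        window = DetectionWindow(24.0, 0.0)
        pos = (classify_screens(screens, window) == TP).to_numpy()
        ppv, npv = ppv_npv(screens, pos, window)
        assert (ppv, npv) == (1.0, 1.0)

    def test_all_positive_ppv_collapses_to_tp_fraction(self):
        rng = np.random.default_rng(3)
        screens = random_screens(rng)
        window = DetectionWindow(24.0, 0.0)
        pos = np.ones(len(screens), bool)
        ppv, _ = ppv_npv(screens, pos, window)
        assert ppv == pytest.approx((classify_screens(screens, window) == TP).mean())

    def test_burden_simple_fraction(self):
        screens = pd.DataFrame(
            {
                "patient_id": np.repeat([f"p{i}" for i in range(10)], 3),
                "delta": 0,
                "d": 60.0,
                "t": np.tile([1.0, 2.0, 3.0], 10),
            }
        )
        pos = np.zeros(30, bool)
        pos[:3] = True  # one patient with 3 false positives
        assert false_positive_burden(screens, pos, DetectionWindow(6.0, 0.0)) == pytest.approx(0.1)
        assert false_positive_burden(screens, np.zeros(30, bool), DetectionWindow(6.0, 0.0)) == 0.0


class TestCurves:
    def test_tpr_fpr_monotone_in_threshold(self):
        rng = np.random.default_rng(4)
        screens = random_screens(rng, n_cases=10, n_controls=20)
        window = DetectionWindow(24.0, 0.0)
        curves = performance_curves(screens, window)
        # thresholds ascend, so both rates must be non-increasing
        assert (np.diff(curves["tpr"].dropna()) <= 1e-12).all()
        assert (np.diff(curves["fpr"].dropna()) <= 1e-12).all()

    def test_curve_extraction_matches_direct_fixed_fpr_computation(self):
        rng = np.random.default_rng(8)
        screens = random_screens(rng, n_cases=12, n_controls=30)
        window = DetectionWindow(24.0, 0.0)
        fp_mask = (classify_screens(screens, window) == FP).to_numpy()
        thr, achieved = calibrate_threshold(screens, fp_mask, 0.10)
        direct = evaluate_positives(screens, apply_threshold(screens, thr), window)
        curves = performance_curves(screens, window, max_points=10_000)
        row = curves[np.isclose(curves["threshold"], thr)].iloc[0]
        assert row["tpr"] == pytest.approx(direct["tpr"])
        assert row["fpr"] == pytest.approx(direct["fpr"])
        assert row["fpr"] == pytest.approx(achieved)

    def test_decile_risk_zero_for_controls(self):
        rng = np.random.default_rng(9)
        screens = random_screens(rng, n_cases=0, n_controls=15)
        out = decile_risk(screens, tau1=24.0)
        assert (out["risk"] == 0.0).all()
        assert out["n"].sum() == len(screens)


class TestFirstPositive:
    def test_hand_enumerated_six_cases(self):
        # window (24, 0); all cases d = 30, screens at 10, 20, 28
        rows = []
        for i in range(6):
            for t in (10.0, 20.0, 28.0):
                rows.append({"patient_id": f"c{i}", "delta": 1, "d": 30.0, "t": t})
        screens = pd.DataFrame(rows)
        a = np.zeros(18, bool)
        b = np.zeros(18, bool)
        # case 0: both at same visit (t=10)
        a[0] = b[0] = True
        # case 1: A earlier (t=10 vs t=20)
        a[3], b[4] = True, True
        # case 2: B earlier
        a[8], b[7] = True, True
        # case 3: A flags, B never (B assigned d = 30, A earlier)
        a[10] = True
        # case 4: B flags only
        b[14] = True
        # case 5: neither flags -> excluded from comparison
        window = DetectionWindow(24.0, 0.0)
        tab = first_positive_comparison(screens, {"A": a, "B": b}, window)
        row = tab.iloc[0]
        assert row["n_compared"] == 5
        assert row["first_by_a"] == pytest.approx(2 / 5)
        assert row["first_by_b"] == pytest.approx(2 / 5)
        assert row["same_visit"] == pytest.approx(1 / 5)

    def test_same_visit_for_identical_streams(self):
        rng = np.random.default_rng(1)
        screens = random_screens(rng, n_cases=5, n_controls=2)
        pos = screens["positive"].to_numpy()
        tab = first_positive_comparison(screens, {"A": pos, "B": pos.copy()}, DetectionWindow(24.0, 0.0))
        if tab.iloc[0]["n_compared"] > 0:
            assert tab.iloc[0]["same_visit"] == 1.0
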