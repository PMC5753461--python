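"""OR rule, threshold calibration and risk percentiles.

Every algorithm produces a per-screen score in (0, 1); a screen is positive
when AFP >= 400 ng/ml (clinical auto-referral) OR the score strictly exceeds
the algorithm's threshold.  Thresholds are calibrated so that the
screening-level false positive rate — the positive fraction among control
screens and case screens earlier than tau1 months before diagnosis — does
not exceed a target.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["OR_RULE_AFP", "or_rule_positive", "calibrate_threshold", "CalibrationError", "to_risk_percentile"]

OR_RULE_AFP = 400.0


class CalibrationError(ValueError):
    """The target FPR is unreachable (AFP >= 400 positives alone exceed it)."""

    def __init__(self, floor_fpr: float):
        super().__init__(
            f"AFP >= {OR_RULE_AFP:g} screens alone give FPR {floor_fpr:.4f}, above the target"
        )
        self.floor_fpr = floor_fpr


def or_rule_positive(afp, algo_positive) -> np.ndarray:
    """Positive iff AFP >= 400 ng/ml (inclusive) or the algorithm flags it."""
    return (np.asarray(afp, dtype=float) >= OR_RULE_AFP) | np.asarray(algo_positive, dtype=bool)


def apply_threshold(scores: pd.DataFrame, threshold: float) -> np.ndarray:
    """OR-rule positivity of each scored screen at a threshold (strict >)."""
    return or_rule_positive(scores["afp"].to_numpy(), scores["score"].to_numpy() > threshold)


def calibrate_threshold(scores: pd.DataFrame, fp_eligible, target_fpr: float) -> tuple[float, float]:
    """Smallest threshold whose achieved screening-level FPR is <= target.

    Parameters
    ----------
    scores : DataFrame with ``afp`` and ``score`` columns.
    fp_eligible : boolean mask of screens that count toward the FPR
        (controls' screens plus case screens with t < d - tau1).
    target_fpr : the target rate f in [0, 1).

    Returns ``(threshold, achieved_fpr)``.  Achieved FPR can fall strictly
    below the target when scores are tied.  Raises :class:`CalibrationError`
    when AFP >= 400 auto-positives alone exceed the target.
    """
    mask = np.asarray(fp_eligible, dtype=bool)
    s = scores.loc[mask, "score"].to_numpy(dtype=float)
    afp = scores.loc[mask, "afp"].to_numpy(dtype=float)
    n = len(s)
    if n == 0:
        raise ValueError("no FP-eligible screens to calibrate on")
    forced = afp >= OR_RULE_AFP
    floor_fpr = forced.mean()
    if floor_fpr > target_fpr:
        raise CalibrationError(floor_fpr)

    # FPR(c) = [#(score > c) + #(forced & score <= c)] / n is non-increasing
    # in c; scan unique scores ascending for the smallest feasible one.
    order = np.argsort(s, kind="mergesort")
    s_sorted = s[order]
    forced_sorted = forced[order]
    uniq, first_idx = np.unique(s_sorted, return_index=True)
    # counts at threshold c = uniq[k]: scores > c are those past the last tie
    last_idx = np.r_[first_idx[1:], n]              # one past the tie block
    n_above = n - last_idx
    forced_cum = np.cumsum(forced_sorted)
    n_forced_le = forced_cum[last_idx - 1]
    fpr_at = (n_above + n_forced_le) / n
    feasible = fpr_at <= target_fpr
    if not feasible.any():
        # strict '>' guarantees the max score is feasible given the floor check
        raise CalibrationError(floor_fpr)
    k = int(np.argmax(feasible))                    # smallest feasible threshold
    return float(uniq[k]), float(fpr_at[k])


def to_risk_percentile(scores) -> np.ndarray:
    """Mid-rank percentile of each score among all scores.

    Fraction of screens strictly below, plus half the ties (including the
    screen itself); keeps the control-only FPR-vs-percentile relationship
    linear with slope -1 in expectation.
    """
    s = np.asarray(scores, dtype=float)
    if len(s) == 0:
        raise ValueError("need at least one score")
    order = np.argsort(s, kind="mergesort")
    sorted_s = s[order]
    below = np.searchsorted(sorted_s, s, side="left")
    le = np.searchsorted(sorted_s, s, side="right")
    return (below + 0.5 * (le - below)) / len(s)
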