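"""Longitudinal performance framework for screening algorithms.

Because the time of disease onset in cases is unknown, a detection window
``(tau1, tau2)`` declares case screens within ``[d - tau1, d - tau2]`` of
the diagnosis time ``d`` to be true-positive-eligible, screens earlier than
``d - tau1`` false-positive-eligible, and screens inside the final ``tau2``
months excluded (a positive there is too late to change prognosis).  All
control screens are false-positive-eligible.

Measures
--------
- patient-level TPR: fraction of cases with >= 1 positive TP-eligible
  screen, among cases with >= 1 TP-eligible screen;
- screening-level FPR: positive fraction among FP-eligible screens;
- PPV: fraction of positive screens that are TP-eligible case screens;
- NPV: fraction of negative screens that are FP-eligible.

The eight standard windows: A1 (6, 0), B1 (12, 0), C1 (24, 0), D1 (full
follow-up, 0) and the A2-D2 variants with tau2 = 3 months.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline

from .policy import apply_threshold, to_risk_percentile

__all__ = [
    "DetectionWindow",
    "standard_windows",
    "classify_screens",
    "patient_tpr",
    "screening_fpr",
    "ppv_npv",
    "evaluate_positives",
    "performance_curves",
    "decile_risk",
    "first_positive_comparison",
    "false_positive_burden",
]

TP, FP, EXCLUDED = "TP-eligible", "FP-eligible", "excluded"


@dataclasses.dataclass(frozen=True)
class DetectionWindow:
    """Pre-clinical detection window: positives in ``[d - tau1, d - tau2]``
    count as true positives; ``tau1 = inf`` means the whole follow-up."""

    tau1: float
    tau2: float = 0.0
    label: str = ""

    def __post_init__(self) -> None:
        if not (self.tau1 > self.tau2 >= 0):
            raise ValueError("require tau1 > tau2 >= 0")


def standard_windows(max_followup: float = np.inf) -> dict[str, DetectionWindow]:
    """The eight windows A1-D1 (tau2 = 0) and A2-D2 (tau2 = 3 months)."""
    spec = {"A": 6.0, "B": 12.0, "C": 24.0, "D": float(max_followup)}
    out = {}
    for letter, tau1 in spec.items():
        for suffix, tau2 in (("1", 0.0), ("2", 3.0)):
            label = letter + suffix
            out[label] = DetectionWindow(tau1, tau2, label)
    return out


def classify_screens(screens: pd.DataFrame, window: DetectionWindow) -> pd.Series:
    """Partition screens into TP-eligible / FP-eligible / excluded.

    ``screens`` needs ``delta``, ``d`` and ``t`` columns.  For cases the TP
    region is closed on both ends; anything earlier is FP-eligible and
    anything later excluded.  Controls are always FP-eligible.
    """
    delta = screens["delta"].to_numpy()
    d = screens["d"].to_numpy(dtype=float)
    t = screens["t"].to_numpy(dtype=float)
    cls = np.full(len(screens), FP, dtype=object)
    is_case = delta == 1
    in_window = is_case & (t >= d - window.tau1) & (t <= d - window.tau2)
    late = is_case & (t > d - window.tau2)
    cls[in_window] = TP
    cls[late] = EXCLUDED
    return pd.Series(cls, index=screens.index, name="screen_class")


def patient_tpr(screens: pd.DataFrame, positive, window: DetectionWindow) -> tuple[float, int]:
    """Patient-level TPR and the number of evaluable cases.

    Numerator: cases with at least one positive TP-eligible screen.
    Denominator: cases with at least one TP-eligible screen (cases with no
    screen inside the window are not evaluable and drop out).
    """
    cls = classify_screens(screens, window)
    pos = np.asarray(positive, dtype=bool)
    tp_rows = (cls == TP).to_numpy()
    pid = screens["patient_id"]
    eligible_cases = pid[tp_rows].unique()
    if len(eligible_cases) == 0:
        return np.nan, 0
    detected = pid[tp_rows & pos].unique()
    return len(detected) / len(eligible_cases), len(eligible_cases)


def screening_fpr(screens: pd.DataFrame, positive, window: DetectionWindow) -> tuple[float, int]:
    """Screening-level FPR: positive fraction among FP-eligible screens."""
    cls = classify_screens(screens, window)
    pos = np.asarray(positive, dtype=bool)
    fp_rows = (cls == FP).to_numpy()
    n = int(fp_rows.sum())
    if n == 0:
        return np.nan, 0
    return float(pos[fp_rows].mean()), n


def ppv_npv(
    screens: pd.DataFrame,
    positive,
    window: DetectionWindow,
    include_excluded: bool = True,
) -> tuple[float, float]:
    """Screening-level PPV and NPV.

    PPV conditions on a positive screen; NPV on a negative one.  By default
    excluded-region screens of cases stay in the conditioning sets (the
    probability statements condition only on the screen result); pass
    ``include_excluded=False`` to drop them entirely.
    """
    cls = classify_screens(screens, window).to_numpy()
    pos = np.asarray(positive, dtype=bool)
    keep = np.ones(len(pos), dtype=bool) if include_excluded else cls != EXCLUDED
    pos_k, cls_k = pos[keep], cls[keep]
    n_pos = int(pos_k.sum())
    n_neg = int((~pos_k).sum())
    ppv = float((pos_k & (cls_k == TP)).sum() / n_pos) if n_pos else np.nan
    npv = float((~pos_k & (cls_k == FP)).sum() / n_neg) if n_neg else np.nan
    return ppv, npv


def evaluate_positives(
    screens: pd.DataFrame,
    positive,
    window: DetectionWindow,
    include_excluded: bool = True,
) -> dict[str, float]:
    """All four measures for one positivity stream under one window."""
    tpr, n_cases = patient_tpr(screens, positive, window)
    fpr, n_fp = screening_fpr(screens, positive, window)
    ppv, npv = ppv_npv(screens, positive, window, include_excluded)
    return {
        "tpr": tpr,
        "fpr": fpr,
        "ppv": ppv,
        "npv": npv,
        "n_cases": n_cases,
        "n_fp_eligible_screens": n_fp,
    }


def performance_curves(
    scores: pd.DataFrame,
    window: DetectionWindow,
    max_points: int = 512,
    include_excluded: bool = True,
) -> pd.DataFrame:
    """TPR/FPR/PPV/NPV as functions of the risk percentile.

    Each row evaluates the OR-rule positivity stream at one candidate
    threshold (a unique score value, thinned to ``max_points``); the
    ``percentile`` column is the fraction of screens at or below that
    threshold, the common x-axis across algorithms.
    """
    s = scores["score"].to_numpy(dtype=float)
    uniq = np.unique(s)
    if len(uniq) > max_points:
        idx = np.unique(np.linspace(0, len(uniq) - 1, max_points).astype(int))
        uniq = uniq[idx]
    sorted_s = np.sort(s)
    rows = []
    for c in uniq:
        pos = apply_threshold(scores, float(c))
        m = evaluate_positives(scores, pos, window, include_excluded)
        pct = np.searchsorted(sorted_s, c, side="right") / len(s)
        rows.append({"threshold": float(c), "percentile": float(pct), **m})
    return pd.DataFrame(rows)


def decile_risk(scores: pd.DataFrame, tau1: float) -> pd.DataFrame:
    """HCC risk within ``tau1`` months by decile of the screening score.

    For each equal-count decile of the score the empirical fraction of
    screens followed by diagnosis within ``tau1`` months is reported, with a
    natural cubic spline through the decile midpoints (``spline`` column
    evaluated at midpoints; use :func:`scipy.interpolate.CubicSpline` on the
    returned frame for a dense curve).  Empty deciles are omitted.
    """
    s = scores["score"].to_numpy(dtype=float)
    event = ((scores["delta"] == 1) & (scores["d"] - scores["t"] <= tau1)).to_numpy()
    pct = to_risk_percentile(s)
    dec = np.minimum((pct * 10).astype(int), 9)
    rows = []
    for k in range(10):
        mask = dec == k
        if not mask.any():
            continue
        rows.append({"decile": k + 1, "midpoint": (k + 0.5) / 10, "n": int(mask.sum()), "risk": float(event[mask].mean())})
    out = pd.DataFrame(rows)
    if len(out) >= 2:
        cs = CubicSpline(out["midpoint"], out["risk"], bc_type="natural")
        out["spline"] = cs(out["midpoint"])
    else:
        out["spline"] = out["risk"]
    return out


def _first_positive_times(screens: pd.DataFrame, positive, window: DetectionWindow) -> pd.Series:
    """Per evaluable case: time of first positive TP-eligible screen, or the
    diagnosis time when the algorithm never flags inside the window."""
    cls = classify_screens(screens, window)
    pos = np.asarray(positive, dtype=bool)
    case_d = screens[screens["delta"] == 1].groupby("patient_id")["d"].first()
    tp_rows = screens[(cls == TP).to_numpy()]
    evaluable = tp_rows["patient_id"].unique()
    flagged = screens[(cls == TP).to_numpy() & pos].groupby("patient_id")["t"].min()
    out = pd.Series(case_d.loc[evaluable].to_numpy(), index=pd.Index(evaluable, name="patient_id"))
    out.loc[flagged.index] = flagged
    return out


def first_positive_comparison(
    screens: pd.DataFrame,
    positives_by_algorithm: dict[str, np.ndarray],
    window: DetectionWindow,
) -> pd.DataFrame:
    """Pairwise comparison of first-positive timing between algorithms.

    Only cases flagged inside the window by at least one algorithm enter the
    comparison; an algorithm that never flags such a case is assigned the
    clinical diagnosis time.  Returns one row per ordered pair with the
    fractions flagged earlier by each algorithm and at the same visit.
    """
    times = {name: _first_positive_times(screens, pos, window) for name, pos in positives_by_algorithm.items()}
    cls = classify_screens(screens, window)
    any_flag = set()
    for pos in positives_by_algorithm.values():
        flagged = screens.loc[(cls == TP).to_numpy() & np.asarray(pos, dtype=bool), "patient_id"].unique()
        any_flag.update(flagged)
    names = list(positives_by_algorithm)
    rows = []
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            common = sorted(any_flag & set(times[a].index) & set(times[b].index))
            ta = times[a].loc[common]
            tb = times[b].loc[common]
            n = len(common)
            rows.append({
                "algorithm_a": a,
                "algorithm_b": b,
                "n_compared": n,
                "first_by_a": float((ta < tb).mean()) if n else np.nan,
                "first_by_b": float((tb < ta).mean()) if n else np.nan,
                "same_visit": float((ta == tb).mean()) if n else np.nan,
            })
    return pd.DataFrame(rows)


def false_positive_burden(
    screens: pd.DataFrame,
    positive,
    window: DetectionWindow,
    more_than: int = 2,
) -> float:
    """Fraction of patients with more than ``more_than`` false-positive
    screens, among patients with at least one FP-eligible screen."""
    cls = classify_screens(screens, window)
    pos = np.asarray(positive, dtype=bool)
    fp_rows = (cls == FP).to_numpy()
    pid = screens["patient_id"]
    eligible = pid[fp_rows].unique()
    if len(eligible) == 0:
        return np.nan
    counts = pid[fp_rows & pos].value_counts()
    return float((counts > more_than).sum() / len(eligible))
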