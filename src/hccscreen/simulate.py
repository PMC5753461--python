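"""Synthetic HCV-cirrhosis screening cohorts.

Generates cohorts with the statistical structure the screening algorithms
assume, so the whole pipeline can be exercised and validated without access
to registry data.  Control log2(AFP) follows the random-intercept hierarchy

    Y_ij | theta_i ~ N(theta_i, sigma2),    theta_i ~ N(theta_bar, tau2)

with defaults matching the variance components reported for the VA
HCV-cirrhosis population (theta_bar = 2.92, tau2 = 1.90, sigma2 = 0.71;
intra-class correlation 0.73).  Cases follow the control model until a
latent onset time ``d - lead`` and thereafter drift upward linearly on the
log2 scale.  Visit schedules, ALT/PLT margins and ages emulate the reported
cohort description (mean inter-visit gap ~11.67 months, log2 ALT ~6.14,
PLT ~148).
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import Cohort, write_cohort

__all__ = ["SimConfig", "generate_cohort", "simulate_control_afp", "simulate_case_afp", "save_cohort"]


@dataclasses.dataclass
class SimConfig:
    """Parameters of the synthetic cohort generator.

    Visit counts are drawn from ``visit_count_probs`` over the categories
    ``{1, 2, 3-4, >4}``; gaps between visits are gamma with the given mean
    and SD in months.  Case AFP rises at ``case_slope`` log2 units per month
    starting ``lead`` months before diagnosis, with lead uniform on
    ``[case_lead_min, case_lead_max]``.
    """

    n_controls: int = 1000
    n_cases: int = 0
    theta_bar: float = 2.92
    tau2: float = 1.90
    sigma2: float = 0.71
    visit_count_probs: tuple[float, float, float, float] = (0.2848, 0.2312, 0.2638, 0.2203)
    gap_mean: float = 11.67
    gap_sd: float = 11.00
    case_slope: float = 0.15
    case_slope_sd: float = 0.05
    case_lead_min: float = 0.0
    case_lead_max: float = 24.0
    alt_log2_mean: float = 6.14
    alt_log2_between_sd: float = 0.80
    alt_log2_within_sd: float = 0.65
    plt_mean: float = 147.97
    plt_between_sd: float = 75.0
    plt_within_sd: float = 25.0
    age_mean: float = 52.87
    age_sd: float = 7.28
    lab_missing_prob: float = 0.05
    horizon: float = 110.0
    case_min_d: float = 12.0
    afp_floor: float = 0.25
    seed: int = 0

    def validate(self) -> None:
        if self.n_controls < 0 or self.n_cases < 0:
            raise ValueError("counts must be non-negative")
        if self.sigma2 <= 0 or self.tau2 < 0:
            raise ValueError("sigma2 > 0 and tau2 >= 0 required")
        if abs(sum(self.visit_count_probs) - 1.0) > 1e-3 or min(self.visit_count_probs) < 0:
            raise ValueError("visit_count_probs must be a probability vector")
        if self.gap_mean <= 0 or self.gap_sd <= 0 or self.horizon <= 0:
            raise ValueError("gap moments and horizon must be positive")
        if self.case_lead_min < 0 or self.case_lead_max < self.case_lead_min:
            raise ValueError("invalid onset lead range")
        if self.case_slope < 0:
            raise ValueError("case_slope must be non-negative")


def simulate_control_afp(theta_i: float, times: np.ndarray, sigma2: float, rng: np.random.Generator, floor: float = 0.5) -> np.ndarray:
    """AFP (ng/ml) series for a control: ``2**Y`` with ``Y ~ N(theta_i, sigma2)`` i.i.d."""
    y = theta_i + np.sqrt(sigma2) * rng.standard_normal(len(times))
    return np.maximum(np.exp2(y), floor)


def simulate_case_afp(
    theta_i: float,
    times: np.ndarray,
    d: float,
    lead: float,
    slope: float,
    sigma2: float,
    rng: np.random.Generator,
    floor: float = 0.5,
) -> np.ndarray:
    """AFP series for a case: control model before onset ``d - lead``, then a
    linear upward drift in the log2 mean of ``slope`` per month; noise unchanged."""
    times = np.asarray(times, dtype=float)
    onset = d - lead
    mean = theta_i + slope * np.maximum(times - onset, 0.0)
    y = mean + np.sqrt(sigma2) * rng.standard_normal(len(times))
    return np.maximum(np.exp2(y), floor)


def _draw_visit_count(rng: np.random.Generator, probs) -> int:
    p = np.asarray(probs, dtype=float)
    cat = rng.choice(4, p=p / p.sum())
    if cat == 0:
        return 1
    if cat == 1:
        return 2
    if cat == 2:
        return int(rng.integers(3, 5))
    return int(rng.integers(5, 11))


def _draw_visit_times(rng: np.random.Generator, n: int, end: float, gap_mean: float, gap_sd: float) -> np.ndarray:
    """Sequential visit times in (0, end): uniform start then gamma gaps,
    truncated at the follow-up end (at least the first visit survives)."""
    shape = (gap_mean / gap_sd) ** 2
    scale = gap_mean / shape
    t0 = rng.uniform(0.0, min(gap_mean, 0.8 * end))
    times = [t0]
    for _ in range(n - 1):
        gap = max(rng.gamma(shape, scale), 0.25)
        times.append(times[-1] + gap)
    times = np.array(times)
    return times[times < end]


def generate_cohort(config: SimConfig) -> tuple[Cohort, pd.DataFrame]:
    """Generate a synthetic cohort and its truth sidecar.

    Returns ``(cohort, truth)`` where ``truth`` has one row per patient with
    the latent mean ``theta_i`` and, for cases, the onset time ``d - lead``
    and slope — sufficient to compute oracle labels downstream.  Fully
    reproducible from ``config.seed``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    pat_rows, visit_rows, lab_rows, truth_rows = [], [], [], []
    n_total = config.n_controls + config.n_cases
    is_case = np.r_[np.zeros(config.n_controls, int), np.ones(config.n_cases, int)]
    sqrt_tau = np.sqrt(config.tau2)

    for k in range(n_total):
        pid = f"P{k:06d}"
        delta = int(is_case[k])
        theta_i = config.theta_bar + sqrt_tau * rng.standard_normal()
        age0 = float(np.clip(config.age_mean + config.age_sd * rng.standard_normal(), 25.0, 90.0))
        n_visits = _draw_visit_count(rng, config.visit_count_probs)
        if delta:
            d = rng.uniform(config.case_min_d, config.horizon)
            lead = rng.uniform(config.case_lead_min, config.case_lead_max)
            slope = max(rng.normal(config.case_slope, config.case_slope_sd), 0.0)
            # case schedules stop at diagnosis; truncation shortens observed
            # gaps slightly, as in real cohorts
            times = _draw_visit_times(rng, n_visits, d, config.gap_mean, config.gap_sd)
        else:
            lead, slope = np.nan, np.nan
            # controls' follow-up ends shortly after their last test, so the
            # gap distribution is not length-biased by end-of-study truncation
            times = _draw_visit_times(rng, n_visits, np.inf, config.gap_mean, config.gap_sd)
            d = float(times[-1] + rng.uniform(0.5, 12.0))
        if delta:
            afp = simulate_case_afp(theta_i, times, d, lead, slope, config.sigma2, rng, config.afp_floor)
        else:
            afp = simulate_control_afp(theta_i, times, config.sigma2, rng, config.afp_floor)

        sex = "M" if rng.random() < 0.98 else "F"
        race = rng.choice(["White", "Black", "Other"], p=[0.3482, 0.1110, 0.5408])
        pat_rows.append((pid, delta, d, age0, sex, race))
        truth_rows.append((pid, theta_i, d - lead if delta else np.nan, slope))
        for t, a in zip(times, afp):
            visit_rows.append((pid, round(float(t), 3), float(a)))

        # per-patient lab levels; per-visit draws within the prior 6 months
        alt_level = config.alt_log2_mean + config.alt_log2_between_sd * rng.standard_normal()
        plt_level = config.plt_mean + config.plt_between_sd * rng.standard_normal()
        for t in times:
            if rng.random() > config.lab_missing_prob:
                alt = np.exp2(alt_level + config.alt_log2_within_sd * rng.standard_normal())
                lab_rows.append((pid, "ALT", max(float(alt), 1.0), round(float(t - rng.uniform(0.0, 5.9)), 3)))
            if rng.random() > config.lab_missing_prob:
                pv = plt_level + config.plt_within_sd * rng.standard_normal()
                lab_rows.append((pid, "PLT", max(float(pv), 10.0), round(float(t - rng.uniform(0.0, 5.9)), 3)))

    patients = pd.DataFrame(pat_rows, columns=["id", "delta", "d", "baseline_age", "sex", "race"])
    visits = pd.DataFrame(visit_rows, columns=["patient_id", "t", "afp"])
    labs = pd.DataFrame(lab_rows, columns=["patient_id", "analyte", "value", "t"])
    truth = pd.DataFrame(truth_rows, columns=["patient_id", "theta_i", "onset_time", "slope"])
    visits = visits.sort_values(["patient_id", "t"], kind="mergesort").reset_index(drop=True)
    return Cohort(patients, visits, labs), truth


def save_cohort(config: SimConfig, outdir: str | Path) -> dict[str, Path]:
    """Generate and write a cohort plus its truth sidecar and config record."""
    outdir = Path(outdir)
    cohort, truth = generate_cohort(config)
    paths = write_cohort(cohort, outdir)
    paths["truth"] = outdir / "truth.csv"
    truth.to_csv(paths["truth"], index=False)
    paths["config"] = outdir / "sim_config.json"
    with open(paths["config"], "w") as fh:
        json.dump(dataclasses.asdict(config), fh, indent=2)
    return paths
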