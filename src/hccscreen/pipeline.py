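"""End-to-end experiments: split-sample and out-of-bag bootstrap validation.

An experiment fits the requested screening algorithms on a training cohort,
calibrates each algorithm's threshold to a target screening-level FPR,
scores the validation cohort under the OR rule and evaluates the
longitudinal performance measures for each detection window.  All
randomness flows from a single root seed through named child streams
(split / resample-fit / bootstrap / synthetic), so a run is reproducible
from its manifest.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import __version__
from .cohort import Cohort, load_cohort, preprocess
from .evaluate import (
    DetectionWindow,
    classify_screens,
    evaluate_positives,
    false_positive_burden,
    first_positive_comparison,
    standard_windows,
)
from .peb import PEBScreen, fixed_threshold_scores
from .policy import CalibrationError, apply_threshold, calibrate_threshold
from .risk_model import SixMonthRiskModel
from .simulate import SimConfig, generate_cohort

__all__ = ["ExperimentConfig", "split_sample", "oob_bootstrap", "run_experiment", "fit_algorithms", "score_cohort", "evaluate_scores"]

ALGORITHMS = ("afp_only", "afp_lab_dafp", "peb", "afp_fixed")

_STREAMS = {"split": 1, "fit": 2, "bootstrap": 3, "synthetic": 4}


def _substream(seed: int, name: str) -> int:
    """Deterministic named child seed below 2**31."""
    h = hashlib.sha256(f"{seed}:{name}".encode()).digest()
    return int.from_bytes(h[:4], "little") % (2**31)


@dataclasses.dataclass
class ExperimentConfig:
    """Configuration of an end-to-end run.

    ``cohort`` is either a :class:`~hccscreen.simulate.SimConfig` (synthetic)
    or a mapping of CSV paths (``patients``/``visits``/``labs``).
    ``calibration`` selects the split on which thresholds are chosen.
    """

    cohort: SimConfig | dict[str, str]
    algorithms: tuple[str, ...] = ("afp_only", "afp_lab_dafp", "peb")
    windows: tuple[str, ...] = ("C1", "D1")
    fpr_target: float = 0.10
    calibration: str = "training"
    f0: float = 0.10
    n_resamples: int = 100
    seed: int = 0
    include_excluded: bool = True

    def validate(self) -> None:
        unknown = set(self.algorithms) - set(ALGORITHMS)
        if unknown:
            raise ValueError(f"unknown algorithm tags: {sorted(unknown)}")
        bad = set(self.windows) - set(standard_windows())
        if bad:
            raise ValueError(f"unknown window labels: {sorted(bad)}")
        if not 0 <= self.fpr_target < 1:
            raise ValueError("fpr_target must lie in [0, 1)")
        if self.calibration not in ("training", "validation"):
            raise ValueError("calibration must be 'training' or 'validation'")

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "ExperimentConfig":
        d = dict(d)
        cohort = d.pop("cohort")
        if isinstance(cohort, dict) and cohort.get("type", "synthetic") == "synthetic":
            sim = {k: v for k, v in cohort.items() if k != "type"}
            sim["visit_count_probs"] = tuple(sim.get("visit_count_probs", SimConfig.visit_count_probs))
            cohort = SimConfig(**sim)
        for key in ("algorithms", "windows"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(cohort=cohort, **d)


def split_sample(patients: pd.DataFrame, seed: int) -> tuple[pd.Index, pd.Index]:
    """Stratified random halves of the cohort (cases and controls each split
    in two); with odd counts the extra patient goes to training."""
    rng = np.random.default_rng(seed)
    train_ids, valid_ids = [], []
    for _, grp in patients.groupby("delta"):
        if len(grp) < 2:
            raise ValueError("each stratum needs at least 2 patients to split")
        ids = grp["id"].to_numpy().copy()
        rng.shuffle(ids)
        half = (len(ids) + 1) // 2          # extra patient to training
        train_ids.extend(ids[:half])
        valid_ids.extend(ids[half:])
    return pd.Index(sorted(train_ids)), pd.Index(sorted(valid_ids))


def fit_algorithms(train_screens: pd.DataFrame, algorithms, seed: int, n_resamples: int = 100) -> dict[str, Any]:
    """Fit every requested algorithm on preprocessed training screens."""
    fitted: dict[str, Any] = {}
    if {"peb", "afp_fixed"} & set(algorithms):
        peb_res = PEBScreen(train_screens).fit()
        fitted["_peb_params"] = peb_res.params
        if "peb" in algorithms:
            fitted["peb"] = peb_res
        if "afp_fixed" in algorithms:
            fitted["afp_fixed"] = peb_res.params
    fit_seed = _substream(seed, "fit")
    if "afp_only" in algorithms:
        fitted["afp_only"] = SixMonthRiskModel(train_screens, "afp_only", n_resamples).fit(fit_seed)
    if "afp_lab_dafp" in algorithms:
        fitted["afp_lab_dafp"] = SixMonthRiskModel(train_screens, "full", n_resamples).fit(_substream(seed, "fit_full"))
    return fitted


def score_cohort(fitted: dict[str, Any], screens: pd.DataFrame, f0: float = 0.10) -> dict[str, pd.DataFrame]:
    """Score screens with each fitted algorithm; the full-lab model only
    scores lab-eligible screens."""
    scores: dict[str, pd.DataFrame] = {}
    for name, obj in fitted.items():
        if name.startswith("_"):
            continue
        if name == "peb":
            scores[name] = obj.score_visits(screens, f0=f0)
        elif name == "afp_fixed":
            scores[name] = fixed_threshold_scores(screens, obj, f0=f0)
        elif name == "afp_only":
            scores[name] = obj.score_visits(screens)
        elif name == "afp_lab_dafp":
            eligible = screens[screens["lab_eligible"]] if "lab_eligible" in screens.columns else screens
            scores[name] = obj.score_visits(eligible)
    return scores


def evaluate_scores(
    valid_scores: dict[str, pd.DataFrame],
    cal_scores: dict[str, pd.DataFrame],
    windows: dict[str, DetectionWindow],
    fpr_target: float,
    include_excluded: bool = True,
) -> tuple[pd.DataFrame, dict[str, dict[str, float]], dict[str, dict[str, np.ndarray]]]:
    """Calibrate per (algorithm, window) and evaluate on the validation split.

    Returns the tidy measures table, the calibrated thresholds and the
    validation positivity streams.
    """
    rows, thresholds, positives = [], {}, {}
    for wlabel, window in windows.items():
        thresholds[wlabel] = {}
        positives[wlabel] = {}
        for name, vsc in valid_scores.items():
            csc = cal_scores[name]
            fp_mask = (classify_screens(csc, window) == "FP-eligible").to_numpy()
            try:
                thr, achieved = calibrate_threshold(csc, fp_mask, fpr_target)
            except CalibrationError as err:
                rows.append({"algorithm": name, "window": wlabel, "error": str(err)})
                continue
            pos = apply_threshold(vsc, thr)
            m = evaluate_positives(vsc, pos, window, include_excluded)
            burden = false_positive_burden(vsc, pos, window)
            thresholds[wlabel][name] = thr
            positives[wlabel][name] = pos
            rows.append({
                "algorithm": name,
                "window": wlabel,
                "threshold": thr,
                "calibration_fpr": achieved,
                "fp_burden_gt2": burden,
                **m,
            })
    return pd.DataFrame(rows), thresholds, positives


def _get_cohort(config: ExperimentConfig) -> Cohort:
    if isinstance(config.cohort, SimConfig):
        sim = dataclasses.replace(config.cohort, seed=_substream(config.seed, "synthetic"))
        cohort, _ = generate_cohort(sim)
        return cohort
    paths = config.cohort
    return load_cohort(paths["patients"], paths["visits"], paths.get("labs"))


def run_experiment(config: ExperimentConfig, outdir: str | Path | None = None) -> dict[str, Any]:
    """Full split-sample experiment: simulate/load, split, fit, calibrate,
    score, evaluate; optionally write tables and a run manifest."""
    config.validate()
    cohort = _get_cohort(config)
    screens = preprocess(cohort)
    train_ids, valid_ids = split_sample(cohort.patients, _substream(config.seed, "split"))
    train_screens = screens[screens["patient_id"].isin(train_ids)].reset_index(drop=True)
    valid_screens = screens[screens["patient_id"].isin(valid_ids)].reset_index(drop=True)

    max_fu = float(screens["d"].max())
    windows = {w: standard_windows(max_fu)[w] for w in config.windows}

    fitted = fit_algorithms(train_screens, config.algorithms, config.seed, config.n_resamples)
    valid_scores = score_cohort(fitted, valid_screens, config.f0)
    if config.calibration == "training":
        cal_scores = score_cohort(fitted, train_screens, config.f0)
    else:
        cal_scores = valid_scores

    table, thresholds, positives = evaluate_scores(
        valid_scores, cal_scores, windows, config.fpr_target, config.include_excluded
    )

    timing = {}
    for wlabel, window in windows.items():
        streams = {}
        base = None
        for name, pos in positives[wlabel].items():
            idx = valid_scores[name].index
            if base is None:
                base = valid_scores[name]
            aligned = pd.Series(False, index=valid_screens.index)
            aligned.loc[idx] = pos
            streams[name] = aligned.to_numpy()
        if len(streams) >= 2:
            timing[wlabel] = first_positive_comparison(valid_screens, streams, window)

    result = {
        "config": config,
        "cohort": cohort,
        "train_ids": train_ids,
        "valid_ids": valid_ids,
        "fitted": fitted,
        "valid_scores": valid_scores,
        "measures": table,
        "thresholds": thresholds,
        "first_positive": timing,
    }
    if outdir is not None:
        result["manifest"] = _write_outputs(result, Path(outdir))
    return result


def _jsonable(obj):
    if isinstance(obj, SimConfig):
        return dataclasses.asdict(obj)
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def _write_outputs(result: dict[str, Any], outdir: Path) -> dict[str, Any]:
    outdir.mkdir(parents=True, exist_ok=True)
    config = result["config"]
    result["measures"].to_csv(outdir / "measures.csv", index=False)
    for wlabel, tab in result["first_positive"].items():
        tab.to_csv(outdir / f"first_positive_{wlabel}.csv", index=False)
    for name, sc in result["valid_scores"].items():
        cols = [c for c in ("patient_id", "t", "j", "z", "mu_hat", "score", "positive") if c in sc.columns]
        sc[cols].to_csv(outdir / f"scores_{name}.csv", index=False)
    manifest = {
        "version": __version__,
        "seed": config.seed,
        "config": {k: _jsonable(v) for k, v in dataclasses.asdict(config).items()},
        "n_train": len(result["train_ids"]),
        "n_valid": len(result["valid_ids"]),
        "train_ids_sha256": hashlib.sha256(",".join(map(str, result["train_ids"])).encode()).hexdigest(),
        "thresholds": {w: {a: float(t) for a, t in d.items()} for w, d in result["thresholds"].items()},
        "outputs": sorted(p.name for p in outdir.glob("*.csv")),
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=_jsonable)
    return manifest


def _bootstrap_training(cohort: Cohort, screens: pd.DataFrame, rng: np.random.Generator) -> tuple[pd.DataFrame, pd.Index]:
    """One bootstrap draw: training screens for patients sampled with
    replacement (duplicates relabelled) and the out-of-bag patient ids."""
    ids = cohort.patients["id"].to_numpy()
    sampled = rng.choice(ids, size=len(ids), replace=True)
    oob = pd.Index(sorted(set(ids) - set(sampled)))
    by_patient = dict(tuple(screens.groupby("patient_id", sort=False)))
    parts = []
    for rep, pid in enumerate(sampled):
        part = by_patient[pid].copy()
        part["patient_id"] = f"{pid}#{rep}"
        parts.append(part)
    return pd.concat(parts, ignore_index=True), oob


def oob_bootstrap(
    cohort: Cohort,
    algorithms=("afp_only", "afp_lab_dafp", "peb"),
    windows=("C1",),
    fpr_target: float = 0.10,
    n_boot: int = 300,
    seed: int = 0,
    f0: float = 0.10,
    n_resamples: int = 100,
    calibration: str = "training",
) -> pd.DataFrame:
    """Out-of-bag bootstrap validation.

    Each replicate trains on n patients drawn with replacement and evaluates
    on the out-of-bag patients (on average a fraction 1 - 1/e of the
    cohort); measures are averaged over replicates.  Replicates whose
    out-of-bag set has no evaluable case are skipped and counted.
    """
    screens = preprocess(cohort)
    max_fu = float(screens["d"].max())
    win = {w: standard_windows(max_fu)[w] for w in windows}
    rng = np.random.default_rng(_substream(seed, "bootstrap"))
    all_rows, skipped = [], 0
    for b in range(n_boot):
        train_screens, oob_ids = _bootstrap_training(cohort, screens, rng)
        oob_screens = screens[screens["patient_id"].isin(oob_ids)].reset_index(drop=True)
        if not ((oob_screens["delta"] == 1).any() and (oob_screens["delta"] == 0).any()):
            skipped += 1
            continue
        fitted = fit_algorithms(train_screens, algorithms, _substream(seed, f"boot{b}"), n_resamples)
        oob_scores = score_cohort(fitted, oob_screens, f0)
        cal_scores = score_cohort(fitted, train_screens, f0) if calibration == "training" else oob_scores
        table, _, _ = evaluate_scores(oob_scores, cal_scores, win, fpr_target)
        table["replicate"] = b
        all_rows.append(table)
    if not all_rows:
        raise RuntimeError("all bootstrap replicates skipped")
    full = pd.concat(all_rows, ignore_index=True)
    avg = (
        full.groupby(["algorithm", "window"], as_index=False)[["tpr", "fpr", "ppv", "npv", "fp_burden_gt2"]]
        .mean()
        .assign(n_replicates=len(all_rows), n_skipped=skipped)
    )
    return avg
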