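"""Six-month HCC risk prediction models on screening-visit covariates.

Two covariate sets are supported:

``"afp_only"``
    A logistic model of the six-month outcome on a 4-term linear-spline
    basis of log2(AFP) (hinge knots at 2, 7, 9 on the log2 scale).

``"full"`` (AFP + Lab + dAFP)
    Adds linear-spline bases for log2(ALT) (knots at log2 of 20, 50, 100,
    200), PLT (knot 35), age (knot 50), AFP x ALT and AFP x PLT interaction
    blocks, an indicator that the AFP rate of change is unobserved, and a
    5-term basis of the annualised log2-AFP rate of change (knots -8, 0, 2,
    9), zeroed when unobserved.

Because visits within a patient are correlated, the model is fit by
cross-sectional resampling: in each of K = 100 iterations one visit per
training patient is drawn at random and an independent-observation logistic
regression is fit; predicted risk for a new visit is the average of the K
per-iteration logistic predictions, eta in (0, 1).

All hinge terms use strict indicators, ``(x - k) * I(x > k)``, so every
basis is a continuous piecewise-linear function of its input.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import expit
from sklearn.linear_model import LogisticRegression

__all__ = [
    "AFP_KNOTS",
    "ALT_KNOTS",
    "PLT_KNOTS",
    "AGE_KNOTS",
    "DAFP_KNOTS",
    "afp_basis",
    "alt_basis",
    "plt_basis",
    "age_basis",
    "dafp_basis",
    "design_matrix",
    "design_columns",
    "SixMonthRiskModel",
    "SixMonthRiskResults",
]

AFP_KNOTS = (2.0, 7.0, 9.0)                       # log2(AFP) scale
ALT_KNOTS = tuple(np.log2([20.0, 50.0, 100.0, 200.0]))  # log2(ALT) scale
PLT_KNOTS = (35.0,)                               # raw 1000's
AGE_KNOTS = (50.0,)                               # years
DAFP_KNOTS = (-8.0, 0.0, 2.0, 9.0)                # log2 per year

AFP_TRAINING_CAP = 400.0


def _hinge(x: np.ndarray, k: float) -> np.ndarray:
    return (x - k) * (x > k)


def _spline_basis(x, knots, log2_input: bool) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    v = np.log2(np.maximum(x, 1.0)) if log2_input else x
    cols = [v] + [_hinge(v, k) for k in knots]
    return np.column_stack(cols)


def afp_basis(afp) -> np.ndarray:
    """[y, (y-2)+, (y-7)+, (y-9)+] with y = log2(max(AFP, 1))."""
    return _spline_basis(afp, AFP_KNOTS, log2_input=True)


def alt_basis(alt) -> np.ndarray:
    return _spline_basis(alt, ALT_KNOTS, log2_input=True)


def plt_basis(plt) -> np.ndarray:
    return _spline_basis(plt, PLT_KNOTS, log2_input=False)


def age_basis(age) -> np.ndarray:
    return _spline_basis(age, AGE_KNOTS, log2_input=False)


def dafp_basis(rate, obs) -> np.ndarray:
    """5-term basis of the annualised rate of change, zeroed when the rate is
    unobserved (previous AFP more than 12 months old or absent)."""
    rate = np.where(np.asarray(obs, dtype=bool), np.asarray(rate, dtype=float), 0.0)
    base = np.column_stack([rate] + [_hinge(rate, k) for k in DAFP_KNOTS])
    return base * np.asarray(obs, dtype=float)[:, None]


def _interaction(a: np.ndarray, b: np.ndarray, mode: str) -> np.ndarray:
    if mode == "outer":
        return np.einsum("ni,nj->nij", a, b).reshape(len(a), -1)
    if mode == "linear":
        return (a[:, 0] * b[:, 0])[:, None]
    raise ValueError(f"unknown interaction mode {mode!r}")


def design_columns(covariate_set: str = "full", interaction: str = "outer") -> list[str]:
    afp = [f"afp_{i}" for i in range(4)]
    if covariate_set == "afp_only":
        return afp
    alt = [f"alt_{i}" for i in range(5)]
    plt_ = [f"plt_{i}" for i in range(2)]
    age = [f"age_{i}" for i in range(2)]
    if interaction == "outer":
        ia = [f"afp{i}_x_alt{j}" for i in range(4) for j in range(5)]
        ip = [f"afp{i}_x_plt{j}" for i in range(4) for j in range(2)]
    else:
        ia, ip = ["afp0_x_alt0"], ["afp0_x_plt0"]
    return afp + alt + plt_ + age + ia + ip + ["dafp_unobs"] + [f"dafp_{i}" for i in range(5)]


def design_matrix(visits: pd.DataFrame, covariate_set: str = "full", interaction: str = "outer") -> np.ndarray:
    """Build the covariate matrix X for a block of screening visits.

    The full set requires ``alt`` and ``plt`` on every row (visits without
    both concurrent labs are ineligible and must be filtered beforehand).
    """
    a = afp_basis(visits["afp"].to_numpy())
    if covariate_set == "afp_only":
        return a
    if covariate_set != "full":
        raise ValueError(f"unknown covariate set {covariate_set!r}")
    alt_vals = visits["alt"].to_numpy(dtype=float)
    plt_vals = visits["plt"].to_numpy(dtype=float)
    if np.isnan(alt_vals).any() or np.isnan(plt_vals).any():
        raise ValueError("full covariate set requires concurrent ALT and PLT on every visit")
    al = alt_basis(alt_vals)
    pl = plt_basis(plt_vals)
    ag = age_basis(visits["age"].to_numpy(dtype=float))
    obs = visits["dafp_obs"].to_numpy()
    da = dafp_basis(visits["dafp_rate"].to_numpy(dtype=float), obs)
    unobs = (1.0 - np.asarray(obs, dtype=float))[:, None]
    return np.column_stack([
        a, al, pl, ag,
        _interaction(a, al, interaction),
        _interaction(a, pl, interaction),
        unobs, da,
    ])


def _fit_one(X: np.ndarray, y: np.ndarray, ridge_alpha: float) -> tuple[np.ndarray, str]:
    """Fit one logistic regression with intercept; returns (params, status).

    params = [intercept, coefs...].  Falls back to a small ridge penalty on
    separation or non-convergence; a single-class draw gets an
    intercept-only fit at the smoothed empirical log-odds.
    """
    n = len(y)
    if y.min() == y.max():
        p = (y.sum() + 0.5) / (n + 1.0)
        return np.r_[np.log(p / (1 - p)), np.zeros(X.shape[1])], "single_class"
    Xc = sm.add_constant(X, has_constant="add")
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.Logit(y, Xc).fit(disp=0, maxiter=200)
        params = np.asarray(res.params)
        if res.mle_retvals.get("converged", False) and np.all(np.isfinite(params)) and np.max(np.abs(params)) < 1e3:
            return params, "ok"
    except Exception:
        pass
    clf = LogisticRegression(C=1.0 / ridge_alpha, solver="lbfgs", max_iter=500)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        clf.fit(X, y)
    return np.r_[clf.intercept_, clf.coef_.ravel()], "ridge"


class SixMonthRiskModel:
    """Cross-sectional resampling logistic model of six-month HCC risk.

    Parameters
    ----------
    train_visits : pandas.DataFrame
        Preprocessed training visits carrying ``patient_id``, ``afp``,
        ``D`` (six-month outcome) and, for the full set, ``alt``, ``plt``,
        ``age``, ``dafp_obs``, ``dafp_rate``.  Visits with AFP >= 400 ng/ml
        are excluded (the OR rule handles them); for the full set visits
        without concurrent labs are excluded.
    covariate_set : {"full", "afp_only"}
    n_resamples : int
        Number K of cross-sectional draws/fits (default 100).
    interaction : {"outer", "linear"}
        Expansion of the AFP x ALT and AFP x PLT blocks.
    """

    def __init__(
        self,
        train_visits: pd.DataFrame,
        covariate_set: str = "full",
        n_resamples: int = 100,
        interaction: str = "outer",
        ridge_alpha: float = 1e-2,
    ):
        if covariate_set not in ("full", "afp_only"):
            raise ValueError(f"unknown covariate set {covariate_set!r}")
        v = train_visits[train_visits["afp"] < AFP_TRAINING_CAP]
        if covariate_set == "full" and "lab_eligible" in v.columns:
            v = v[v["lab_eligible"]]
        if not len(v):
            raise ValueError("no eligible training visits")
        self.visits = v.reset_index(drop=True)
        self.covariate_set = covariate_set
        self.interaction = interaction
        self.n_resamples = int(n_resamples)
        self.ridge_alpha = float(ridge_alpha)
        self.X = design_matrix(self.visits, covariate_set, interaction)
        self.y = self.visits["D"].to_numpy(dtype=float)
        self._groups = self.visits.groupby("patient_id", sort=True).indices

    def fit(self, seed: int = 0) -> "SixMonthRiskResults":
        """Run the K resampled fits.  Iteration k draws its visit indices from
        an independent child stream of ``seed``, so results for the first k
        iterations are unchanged when K grows."""
        seeds = np.random.SeedSequence(seed).spawn(self.n_resamples)
        group_idx = list(self._groups.values())
        coefs = np.empty((self.n_resamples, self.X.shape[1] + 1))
        statuses = []
        for k in range(self.n_resamples):
            rng = np.random.default_rng(seeds[k])
            rows = np.array([idx[rng.integers(len(idx))] for idx in group_idx])
            params, status = _fit_one(self.X[rows], self.y[rows], self.ridge_alpha)
            coefs[k] = params
            statuses.append(status)
        return SixMonthRiskResults(
            coefs=coefs,
            covariate_set=self.covariate_set,
            interaction=self.interaction,
            seed=seed,
            statuses=statuses,
        )


class SixMonthRiskResults:
    """The K fitted coefficient vectors and prediction averaging."""

    def __init__(self, coefs: np.ndarray, covariate_set: str, interaction: str, seed: int, statuses: list[str]):
        if not np.all(np.isfinite(coefs)):
            raise ValueError("non-finite coefficients")
        self.coefs = coefs
        self.covariate_set = covariate_set
        self.interaction = interaction
        self.seed = seed
        self.statuses = statuses

    @property
    def n_resamples(self) -> int:
        return self.coefs.shape[0]

    @property
    def diagnostics(self) -> dict[str, int]:
        return {s: self.statuses.count(s) for s in sorted(set(self.statuses))}

    def predict(self, visits: pd.DataFrame) -> np.ndarray:
        """Average predicted six-month risk eta over the K fits; in (0, 1)."""
        X = design_matrix(visits, self.covariate_set, self.interaction)
        Xc = np.column_stack([np.ones(len(X)), X])
        logits = Xc @ self.coefs.T                       # (n, K)
        eta = np.mean(expit(logits), axis=1)
        return np.clip(eta, 1e-15, 1 - 1e-15)

    def score_visits(self, visits: pd.DataFrame) -> pd.DataFrame:
        out = visits.copy()
        out["score"] = self.predict(visits)
        return out

    def coef_table(self) -> pd.DataFrame:
        cols = ["intercept"] + design_columns(self.covariate_set, self.interaction)
        return pd.DataFrame(
            {"mean": self.coefs.mean(axis=0), "sd": self.coefs.std(axis=0, ddof=1)},
            index=cols,
        )

    def summary(self) -> str:
        diag = ", ".join(f"{k}={v}" for k, v in self.diagnostics.items())
        tab = self.coef_table()
        lines = [
            f"Six-month risk model ({self.covariate_set}, {self.interaction} interactions)",
            "=" * 68,
            f"resampled fits: K={self.n_resamples}  [{diag}]",
            "coefficients (mean and SD over resampled fits):",
            tab.to_string(float_format=lambda x: f"{x:10.4f}"),
        ]
        return "\n".join(lines)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "covariate_set": self.covariate_set,
                    "interaction": self.interaction,
                    "seed": self.seed,
                    "statuses": self.statuses,
                    "knots": {
                        "afp": list(AFP_KNOTS),
                        "alt": list(ALT_KNOTS),
                        "plt": list(PLT_KNOTS),
                        "age": list(AGE_KNOTS),
                        "dafp": list(DAFP_KNOTS),
                    },
                    "coefs": self.coefs.tolist(),
                },
                fh,
            )

    @classmethod
    def from_json(cls, path: str | Path) -> "SixMonthRiskResults":
        with open(path) as fh:
            d = json.load(fh)
        return cls(np.asarray(d["coefs"]), d["covariate_set"], d["interaction"], d["seed"], d["statuses"])
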