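"""Parametric empirical Bayes (PEB) sequential screening on log2(AFP).

The control population is modelled hierarchically,

    Y_ij | theta_i ~ N(theta_i, sigma2),   theta_i ~ N(theta_bar, tau2),

with Y = log2(AFP).  Standardising Z = (Y - theta_bar) / sqrt(sigma2 + tau2)
makes the marginal of Z standard normal.  At a patient's j-th screen the PEB
estimate of their own standardised mean shrinks the running mean of prior
screens toward the population mean:

    mu_hat_j = B_j * Zbar_j,   B_j = tau2 / (sigma2 / (j - 1) + tau2),

and the screen is positive when

    Z_j > mu_hat_j + z_{1 - f0} * sqrt(1 - B1 * B_j),   B1 = tau2 / (sigma2 + tau2).

B1 is the intra-class correlation of the biomarker; it is also the shrinkage
weight at the second screen.  At j = 1 the rule reduces exactly to the fixed
population-threshold rule Z > z_{1 - f0}.  The continuous score
Phi((Z - mu_hat) / sqrt(1 - B1 * B_j)) is uniform on (0, 1) per screen under
the null model, so the boolean rule is score > 1 - f0.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm

__all__ = ["PEBParams", "PEBScreen", "PEBScreenResults", "standardize", "peb_scores", "fixed_threshold_scores"]

#: Training visits at or above this AFP (ng/ml) are excluded from estimation;
#: they trigger the OR rule rather than the model.
AFP_TRAINING_CAP = 400.0


class IdentifiabilityError(ValueError):
    """Variance components cannot be separated from the given data."""


@dataclasses.dataclass(frozen=True)
class PEBParams:
    """Hierarchical-model parameters for the control population.

    ``b1 = tau2 / (sigma2 + tau2)`` is both the intra-class correlation of
    log2(AFP) and the shrinkage weight applied at the second screen.
    """

    theta_bar: float
    sigma2: float
    tau2: float

    def __post_init__(self) -> None:
        if self.sigma2 <= 0:
            raise ValueError("sigma2 must be positive")
        if self.tau2 < 0:
            raise ValueError("tau2 must be non-negative")

    @property
    def b1(self) -> float:
        return self.tau2 / (self.sigma2 + self.tau2)

    icc = b1

    @property
    def total_sd(self) -> float:
        return float(np.sqrt(self.sigma2 + self.tau2))

    def b_j(self, j) -> np.ndarray:
        """Shrinkage weight before the j-th screen (1-based); B_1 = 0."""
        j = np.asarray(j, dtype=float)
        with np.errstate(divide="ignore"):
            out = np.where(j > 1, self.tau2 / (self.sigma2 / np.maximum(j - 1, 1) + self.tau2), 0.0)
        return out

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump({"theta_bar": self.theta_bar, "sigma2": self.sigma2, "tau2": self.tau2}, fh, indent=2)

    @classmethod
    def from_json(cls, path: str | Path) -> "PEBParams":
        with open(path) as fh:
            d = json.load(fh)
        return cls(d["theta_bar"], d["sigma2"], d["tau2"])


def standardize(afp, params: PEBParams) -> np.ndarray:
    """Z = (log2(AFP) - theta_bar) / sqrt(sigma2 + tau2).

    AFP must be positive (cohort inclusion guarantees it).  No flooring is
    applied here: censoring the lower tail of log2(AFP) would bias the
    variance components the rule depends on.
    """
    afp = np.asarray(afp, dtype=float)
    if (afp <= 0).any():
        raise ValueError("AFP must be positive")
    return (np.log2(afp) - params.theta_bar) / params.total_sd


class PEBScreen:
    """Model for the PEB screening rule, fit to training-cohort controls.

    Parameters
    ----------
    train_visits : pandas.DataFrame
        Preprocessed visits (``patient_id``, ``afp``, ``delta``).  Only
        control visits with AFP below 400 ng/ml enter estimation.
    """

    def __init__(self, train_visits: pd.DataFrame):
        v = train_visits
        if "delta" in v.columns:
            v = v[v["delta"] == 0]
        v = v[v["afp"] < AFP_TRAINING_CAP]
        if not len(v):
            raise ValueError("no eligible control training visits")
        self.endog = np.log2(v["afp"].to_numpy(dtype=float))
        self.groups = v["patient_id"].to_numpy()

    def fit(self, reml: bool = True) -> "PEBScreenResults":
        """Estimate (theta_bar, sigma2, tau2) by a random-intercept linear
        mixed model (REML by default) on log2(AFP)."""
        counts = pd.Series(self.groups).value_counts()
        if (counts >= 2).sum() < 2:
            raise IdentifiabilityError(
                "variance components need at least two control patients with two or more visits"
            )
        exog = np.ones((len(self.endog), 1))
        model = sm.MixedLM(self.endog, exog, groups=self.groups)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = model.fit(reml=reml)
        tau2 = float(np.asarray(res.cov_re)[0, 0])
        sigma2 = float(res.scale)
        if sigma2 < 1e-8:
            warnings.warn("within-subject variance estimated near zero", stacklevel=2)
        if tau2 <= 1e-10:
            warnings.warn("between-subject variance estimated at the zero boundary; B1 = 0", stacklevel=2)
            tau2 = 0.0
        params = PEBParams(theta_bar=float(res.params[0]), sigma2=sigma2, tau2=tau2)
        return PEBScreenResults(params, mixedlm_result=res, n_patients=len(counts), n_visits=len(self.endog))


class PEBScreenResults:
    """Fitted PEB parameters plus scoring of new screening streams."""

    def __init__(self, params: PEBParams, mixedlm_result=None, n_patients: int | None = None, n_visits: int | None = None):
        self.params = params
        self.mixedlm_result = mixedlm_result
        self.n_patients = n_patients
        self.n_visits = n_visits

    def score_visits(self, visits: pd.DataFrame, f0: float = 0.10, include_or_history: bool = True) -> pd.DataFrame:
        """Apply the PEB rule to every visit; see :func:`peb_scores`."""
        return peb_scores(visits, self.params, f0=f0, include_or_history=include_or_history)

    def summary(self) -> str:
        p = self.params
        lines = [
            "PEB screening rule — random-intercept model for log2(AFP) in controls",
            "=" * 68,
            f"n patients: {self.n_patients}    n visits: {self.n_visits}",
            f"theta_bar (population mean)     {p.theta_bar:10.4f}",
            f"sigma2 (within-subject var)     {p.sigma2:10.4f}",
            f"tau2 (between-subject var)      {p.tau2:10.4f}",
            f"B1 = ICC = tau2/(sigma2+tau2)   {p.b1:10.4f}",
        ]
        if self.mixedlm_result is not None:
            se = self.mixedlm_result.bse_fe
            lines.append(f"SE(theta_bar)                   {float(se[0]):10.4f}")
        return "\n".join(lines)


def peb_scores(
    visits: pd.DataFrame,
    params: PEBParams,
    f0: float = 0.10,
    include_or_history: bool = True,
) -> pd.DataFrame:
    """Sequential PEB screening over each patient's ordered visits.

    Returns a frame aligned with ``visits`` carrying the screen index ``j``,
    ``z``, the shrinkage estimate ``mu_hat``, the continuous ``score``
    (null-uniform on (0,1)) and the boolean ``positive`` at level ``f0``.

    When ``include_or_history`` is False, screens with AFP >= 400 ng/ml (OR
    rule auto-positives) are dropped from the running history Zbar of later
    screens; by default they are retained.
    """
    if not 0 < f0 < 1:
        raise ValueError("f0 must lie in (0, 1)")
    v = visits.sort_values(["patient_id", "t"], kind="mergesort") if "t" in visits.columns else visits
    z_all = standardize(v["afp"].to_numpy(), params)
    afp = v["afp"].to_numpy(dtype=float)
    pid = v["patient_id"].to_numpy()
    b1 = params.b1
    zq = stats.norm.ppf(1 - f0)

    j_out = np.empty(len(v), dtype=int)
    mu_out = np.empty(len(v))
    score_out = np.empty(len(v))
    start = 0
    while start < len(v):
        end = start
        while end < len(v) and pid[end] == pid[start]:
            end += 1
        hist_sum, hist_n = 0.0, 0
        for i in range(start, end):
            j = hist_n + 1
            bj = params.tau2 / (params.sigma2 / hist_n + params.tau2) if hist_n > 0 else 0.0
            mu_hat = bj * (hist_sum / hist_n) if hist_n > 0 else 0.0
            denom = np.sqrt(1.0 - b1 * bj)
            assert denom > 0.0
            j_out[i] = j
            mu_out[i] = mu_hat
            score_out[i] = stats.norm.cdf((z_all[i] - mu_hat) / denom)
            if include_or_history or afp[i] < AFP_TRAINING_CAP:
                hist_sum += z_all[i]
                hist_n += 1
        start = end

    out = v.copy()
    out["j"] = j_out
    out["z"] = z_all
    out["mu_hat"] = mu_out
    out["score"] = score_out
    out["positive"] = score_out > 1 - f0
    # equivalent threshold form: Z > mu_hat + z_{1-f0} sqrt(1 - B1 B_j)
    out.attrs["f0"] = f0
    out.attrs["z_quantile"] = float(zq)
    return out


def fixed_threshold_scores(visits: pd.DataFrame, params: PEBParams, f0: float = 0.10) -> pd.DataFrame:
    """The standard population-threshold rule Z > z_{1-f0}, as a score stream.

    The score Phi(Z) is the marginal percentile of the screen under the
    control model, so ``score > 1 - f0`` is exactly the fixed-threshold rule;
    ranking by score is ranking by AFP.
    """
    if not 0 < f0 < 1:
        raise ValueError("f0 must lie in (0, 1)")
    out = visits.copy()
    z = standardize(out["afp"].to_numpy(), params)
    out["z"] = z
    out["score"] = stats.norm.cdf(z)
    out["positive"] = out["score"] > 1 - f0
    out.attrs["f0"] = f0
    return out
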