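"""Evaluation metrics for deconvolution and multi-method comparison.

Besides the RMSE between predicted and true proportions, two R-squared
flavours are provided.  The *diagonal* R² measures fit to the identity line
true = pred and therefore penalizes systematic bias; the *fitted* (adjusted)
R² of the regression true ~ pred absorbs any affine bias into slope and
intercept, so a method that over-estimates every proportion by a constant
still scores R²(fit) = 1 while its RMSE is large — the reason diagonal R² or
RMSE should be preferred when judging deconvolution.  Method comparison
across datasets uses the Friedman rank test with the Nemenyi post-hoc
critical difference.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "DeconvoMetrics",
    "RankResult",
    "rmse",
    "r2_diagonal",
    "r2_fit",
    "linear_fit",
    "deconvolution_metrics",
    "friedman_nemenyi",
    "NEMENYI_Q05",
]


def _as_pair(true, pred) -> tuple[np.ndarray, np.ndarray]:
    t = np.asarray(true, dtype=float).ravel()
    p = np.asarray(pred, dtype=float).ravel()
    if t.shape != p.shape:
        raise ValueError(f"length mismatch: {t.shape} vs {p.shape}")
    if t.size < 1:
        raise ValueError("empty vectors")
    return t, p


def rmse(true, pred) -> float:
    """Root mean squared error sqrt(mean((true - pred)^2))."""
    t, p = _as_pair(true, pred)
    return float(np.sqrt(np.mean((t - p) ** 2)))


def r2_diagonal(true, pred) -> float:
    """R² of the fit to the identity line: 1 - SS(true-pred)/SS(true-mean).

    May be negative; undefined (error) when the truth is constant.
    """
    t, p = _as_pair(true, pred)
    if t.size < 2:
        raise ValueError("need at least 2 points")
    ss_tot = float(np.sum((t - t.mean()) ** 2))
    if ss_tot == 0:
        raise ValueError("true values are constant; diagonal R² undefined")
    return 1.0 - float(np.sum((t - p) ** 2)) / ss_tot


@dataclass
class LinearFit:
    slope: float
    intercept: float
    residuals: np.ndarray
    r2: float
    r2_adj: float
    n: int
    fit_df: int = 1  # predictors in the fit


def linear_fit(true, pred, denominator: str = "conventional") -> LinearFit:
    """OLS of true on pred with plain and sample-size-adjusted R².

    ``denominator="conventional"`` uses the total sum of squares of the
    response, matching the standard regression-summary R² (R's lm/summary);
    ``"printed"`` uses the sum of squares of the predictor instead, kept for
    fidelity with one published variant of the formula.
    """
    t, p = _as_pair(true, pred)
    n = t.size
    if n < 3:
        raise ValueError("adjusted R² needs at least 3 points")
    var_p = np.sum((p - p.mean()) ** 2)
    if var_p == 0:
        raise ValueError("predictions are constant; fit undefined")
    slope = float(np.sum((p - p.mean()) * (t - t.mean())) / var_p)
    intercept = float(t.mean() - slope * p.mean())
    res = t - (slope * p + intercept)
    if denominator == "conventional":
        denom = float(np.sum((t - t.mean()) ** 2))
    elif denominator == "printed":
        denom = float(var_p)
    else:
        raise ValueError(f"unknown denominator {denominator!r}")
    if denom == 0:
        raise ValueError("zero denominator in R² computation")
    r2 = 1.0 - float(np.sum(res**2)) / denom
    fit_df = 1
    r2_adj = 1.0 - (1.0 - r2) * (n - 1) / (n - fit_df - 1)
    return LinearFit(slope, intercept, res, r2, r2_adj, n, fit_df)


def r2_fit(true, pred, denominator: str = "conventional") -> float:
    """Adjusted R² of the linear model true = a*pred + b."""
    return linear_fit(true, pred, denominator).r2_adj


@dataclass
class DeconvoMetrics:
    """Bundle of deconvolution-accuracy metrics over paired proportions."""

    rmse: float
    r2_diagonal: float
    r2_fit: float
    fit_slope: float
    fit_intercept: float
    residuals: np.ndarray
    n: int
    fit_df: int = 1


def deconvolution_metrics(true, pred) -> DeconvoMetrics:
    fit = linear_fit(true, pred)
    return DeconvoMetrics(
        rmse=rmse(true, pred),
        r2_diagonal=r2_diagonal(true, pred),
        r2_fit=fit.r2_adj,
        fit_slope=fit.slope,
        fit_intercept=fit.intercept,
        residuals=fit.residuals,
        n=fit.n,
        fit_df=fit.fit_df,
    )


#: Nemenyi critical values q_0.05(k) = studentized-range ppf / sqrt(2),
#: infinite degrees of freedom, for k = 2..20 compared methods.
NEMENYI_Q05 = {
    2: 1.959964,
    3: 2.343701,
    4: 2.569032,
    5: 2.727774,
    6: 2.849705,
    7: 2.948320,
    8: 3.030879,
    9: 3.101730,
    10: 3.163684,
    11: 3.218654,
    12: 3.268004,
    13: 3.312739,
    14: 3.353618,
    15: 3.391230,
    16: 3.426041,
    17: 3.458425,
    18: 3.488685,
    19: 3.517073,
    20: 3.543799,
}


@dataclass
class RankResult:
    mean_ranks: pd.Series  # per method, 1 = best
    friedman_statistic: float
    friedman_pvalue: float
    critical_difference: float
    significant: pd.DataFrame  # boolean method x method matrix

    def ranking(self) -> list[str]:
        return list(self.mean_ranks.sort_values().index)


def friedman_nemenyi(
    table: pd.DataFrame, lower_is_better: bool = False, alpha: float = 0.05
) -> RankResult:
    """Friedman rank test with Nemenyi post-hoc over a methods x blocks table.

    Each column (block: a dataset or scenario) is ranked with midranks, rank
    1 going to the best method (largest value, or smallest when
    ``lower_is_better``, e.g. for RMSE).  The chi-squared Friedman statistic
    is 12 n / (k (k+1)) * sum_j (Rbar_j - (k+1)/2)^2 with k methods and n
    blocks, df = k - 1; pairs of methods whose mean ranks differ by more than
    CD = q_alpha(k) * sqrt(k (k+1) / (6 n)) are flagged significant.
    """
    if alpha != 0.05:
        raise NotImplementedError("critical values embedded for alpha = 0.05 only")
    k, n = table.shape
    if k < 2:
        raise ValueError("need at least 2 methods")
    if n < 2:
        raise ValueError("need at least 2 blocks")
    if k not in NEMENYI_Q05:
        raise ValueError(f"no critical value embedded for k={k} methods")
    vals = table.to_numpy(dtype=float)
    signed = vals if lower_is_better else -vals
    ranks = np.apply_along_axis(sps.rankdata, 0, signed)  # midranks, 1 = best
    mean_ranks = pd.Series(ranks.mean(axis=1), index=table.index, name="mean_rank")
    stat = float(
        12.0 * n / (k * (k + 1)) * np.sum((mean_ranks.to_numpy() - (k + 1) / 2) ** 2)
    )
    pval = float(sps.chi2.sf(stat, df=k - 1))
    cd = float(NEMENYI_Q05[k] * np.sqrt(k * (k + 1) / (6.0 * n)))
    diff = np.abs(mean_ranks.to_numpy()[:, None] - mean_ranks.to_numpy()[None, :])
    sig = pd.DataFrame(diff > cd, index=table.index, columns=table.index)
    np.fill_diagonal(sig.values, False)
    return RankResult(mean_ranks, stat, pval, cd, sig)
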