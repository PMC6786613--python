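"""Sensitivity analysis: standardized-coefficient multiple regression and
Pearson correlation of sweep output.

Standardized betas follow the usual convention (SPSS-style "Beta"): the OLS
coefficient after z-scoring the variables, i.e. b_j * s_xj / s_y, giving
direction and relative strength on a common scale.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

__all__ = ["RegressionResult", "standardized_ols", "pearson_r"]


@dataclass(frozen=True)
class RegressionResult:
    """Summary of one standardized multiple regression."""

    response: str
    R: float
    R2: float
    beta: dict[str, float]
    t: dict[str, float]
    p: dict[str, float]
    n: int


def standardized_ols(
    table: pd.DataFrame, response: str, predictors: Sequence[str]
) -> RegressionResult:
    """OLS of ``response`` on z-scored ``predictors`` with standardized
    coefficients.

    Predictors are z-scored (sample sd) and the fitted coefficients are
    rescaled by the response sd, which is equivalent to z-scoring everything.
    R^2 comes from the fit; each coefficient gets a two-sided t-test on
    n - k - 1 degrees of freedom.

    Raises ``ValueError`` when a predictor or the response is constant.
    """
    predictors = list(predictors)
    if len(predictors) < 1:
        raise ValueError("at least one predictor is required")
    df = table[[response, *predictors]].dropna()
    n = len(df)
    if n < len(predictors) + 2:
        raise ValueError("too few rows for the requested regression")
    y = df[response].to_numpy(dtype=float)
    X = df[predictors].to_numpy(dtype=float)
    sx = X.std(axis=0, ddof=1)
    sy = y.std(ddof=1)
    if np.any(sx == 0):
        bad = predictors[int(np.flatnonzero(sx == 0)[0])]
        raise ValueError(f"predictor {bad!r} is constant (singular design)")
    if sy == 0:
        raise ValueError(f"response {response!r} is constant")
    Z = (X - X.mean(axis=0)) / sx
    fit = sm.OLS(y, sm.add_constant(Z)).fit()
    coefs = np.asarray(fit.params)[1:]
    return RegressionResult(
        response=response,
        R=float(np.sqrt(fit.rsquared)),
        R2=float(fit.rsquared),
        beta={name: float(c / sy) for name, c in zip(predictors, coefs)},
        t={name: float(t) for name, t in zip(predictors, np.asarray(fit.tvalues)[1:])},
        p={name: float(p) for name, p in zip(predictors, np.asarray(fit.pvalues)[1:])},
        n=n,
    )


def pearson_r(x, y) -> float:
    """Product-moment correlation coefficient in [-1, 1].

    Raises ``ValueError`` on unequal lengths, fewer than 3 points, or a
    constant input (where the coefficient is undefined).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D sequences of equal length")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("pearson r is undefined for a constant input")
    return float(sps.pearsonr(x, y).statistic)
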