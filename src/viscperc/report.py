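"""Regression fit reports used across the pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm

__all__ = ["FitReport", "ols_report"]


@dataclass
class FitReport:
    """Summary of an OLS fit: R², F(df1, df2), sample size, residuals."""

    r2: float
    fstat: float
    df1: int
    df2: int
    n: int
    pvalue: float
    params: np.ndarray = field(repr=False, default=None)
    residuals: np.ndarray = field(repr=False, default=None)

    def to_dict(self) -> dict:
        return {"r2": self.r2, "fstat": self.fstat, "df1": self.df1,
                "df2": self.df2, "n": self.n, "pvalue": self.pvalue,
                "params": None if self.params is None else list(map(float, self.params))}


def ols_report(X, y) -> tuple[FitReport, sm.regression.linear_model.RegressionResults]:
    """OLS of y on X (intercept added); returns the report and the raw fit."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if X.ndim == 1:
        X = X[:, None]
    res = sm.OLS(y, sm.add_constant(X, has_constant="add")).fit()
    rep = FitReport(
        r2=float(res.rsquared), fstat=float(res.fvalue),
        df1=int(res.df_model), df2=int(res.df_resid), n=int(res.nobs),
        pvalue=float(res.f_pvalue), params=np.asarray(res.params),
        residuals=np.asarray(res.resid))
    return rep, res
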