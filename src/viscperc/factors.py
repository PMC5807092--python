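"""Factor-analytic core: Horn retention, ML factor analysis, Harman scores,
viscosity regression, frozen-model transfer, and a random-predictor baseline.

The statistical chain is: determine the number of latent factors behind the
20 feature ratings with Horn's parallel analysis; fit a maximum-likelihood
factor model on the feature correlation matrix; compute per-stimulus factor
scores with Harman's idealized-variable weights W = Λ(ΛᵀΛ)⁻¹ (applying the
loadings to the actual, standardized data); regress the viscosity ratings
on the four scores; and finally apply the frozen loadings + regression
weights to feature ratings from unseen scene contexts.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from sklearn.decomposition import FactorAnalysis

from .report import FitReport, ols_report
from .synth import RatingsTable, child_seed

__all__ = [
    "FactorModel",
    "ViscosityModel",
    "horn_parallel_analysis",
    "fit_factor_model",
    "factor_scores",
    "fit_viscosity_regression",
    "predict_transfer",
    "bootstrap_random_predictor_baseline",
    "tucker_congruence",
    "procrustes_align",
    "build_viscosity_model",
]


def _feature_matrix(table) -> pd.DataFrame:
    """Accept a RatingsTable (repetition-averaged) or a plain DataFrame."""
    if isinstance(table, RatingsTable):
        return table.average_repetitions().values
    return pd.DataFrame(table)


# ---------------------------------------------------------------------------
# Horn's parallel analysis
# ---------------------------------------------------------------------------


def horn_parallel_analysis(table, n_random: int = 100, quantile: float = 0.95,
                           seed: int = 0) -> int:
    """Number of factors to retain by Horn's parallel analysis.

    Eigenvalues of the observed feature correlation matrix are compared,
    position by position, against the ``quantile`` of eigenvalues from
    ``n_random`` same-shape standard-normal datasets; counting stops at the
    first observed eigenvalue that fails to exceed its threshold.
    """
    X = _feature_matrix(table).to_numpy(dtype=float)
    n, p = X.shape
    if p < 2:
        raise ValueError("parallel analysis needs at least 2 features")
    if X.std(axis=0).min() < 1e-14:
        raise ValueError("constant feature column: correlation undefined")
    obs = np.sort(np.linalg.eigvalsh(np.corrcoef(X, rowvar=False)))[::-1]
    rng = np.random.default_rng(child_seed(seed, "horn"))
    rand = np.empty((n_random, p))
    for i in range(n_random):
        R = np.corrcoef(rng.standard_normal((n, p)), rowvar=False)
        rand[i] = np.sort(np.linalg.eigvalsh(R))[::-1]
    thresh = np.quantile(rand, quantile, axis=0)
    exceeds = obs > thresh
    k = 0
    for flag in exceeds:
        if not flag:
            break
        k += 1
    return k


# ---------------------------------------------------------------------------
# ML factor analysis
# ---------------------------------------------------------------------------


@dataclass
class FactorModel:
    """A fitted factor model frozen for reuse on new data.

    Holds loadings Λ (features × factors), per-feature uniquenesses, the
    training standardization (mean/sd per feature, population convention)
    and the Harman score weights W = Λ(ΛᵀΛ)⁻¹.
    """

    loadings: np.ndarray
    uniquenesses: np.ndarray
    feature_names: list[str]
    factor_names: list[str]
    train_mean: np.ndarray
    train_sd: np.ndarray
    rotation: str | None = None
    score_weights: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        self.loadings = np.asarray(self.loadings, dtype=float)
        self.uniquenesses = np.asarray(self.uniquenesses, dtype=float)
        if self.score_weights is None:
            lam = self.loadings
            self.score_weights = lam @ np.linalg.inv(lam.T @ lam)
        comm = 1.0 - self.uniquenesses
        if (comm < -1e-8).any() or (comm > 1 + 1e-8).any():
            raise ValueError("communalities must lie in [0, 1]")

    @property
    def n_factors(self) -> int:
        return self.loadings.shape[1]

    def implied_correlation(self) -> np.ndarray:
        """Model-implied correlation matrix ΛΛᵀ + diag(ψ)."""
        return self.loadings @ self.loadings.T + np.diag(self.uniquenesses)

    def standardize(self, values: pd.DataFrame,
                    stats: Literal["train", "self"] = "train") -> np.ndarray:
        X = values.to_numpy(dtype=float)
        if stats == "train":
            return (X - self.train_mean) / self.train_sd
        return (X - X.mean(axis=0)) / X.std(axis=0)

    def to_json_dict(self) -> dict:
        return {
            "loadings": self.loadings.tolist(),
            "uniquenesses": self.uniquenesses.tolist(),
            "feature_names": self.feature_names,
            "factor_names": self.factor_names,
            "train_mean": self.train_mean.tolist(),
            "train_sd": self.train_sd.tolist(),
            "rotation": self.rotation,
        }

    @classmethod
    def from_json_dict(cls, d: dict) -> "FactorModel":
        return cls(np.array(d["loadings"]), np.array(d["uniquenesses"]),
                   list(d["feature_names"]), list(d["factor_names"]),
                   np.array(d["train_mean"]), np.array(d["train_sd"]),
                   d.get("rotation"))


@dataclass
class ViscosityModel:
    """Frozen factor model plus regression weights β (intercept first)."""

    factor_model: FactorModel
    beta: np.ndarray

    def __post_init__(self) -> None:
        self.beta = np.asarray(self.beta, dtype=float)
        if len(self.beta) != self.factor_model.n_factors + 1:
            raise ValueError("beta must have length n_factors + 1")

    def predict_from_scores(self, scores: np.ndarray) -> np.ndarray:
        return self.beta[0] + np.asarray(scores) @ self.beta[1:]

    def to_json_dict(self) -> dict:
        return {"factor_model": self.factor_model.to_json_dict(),
                "beta": self.beta.tolist()}

    @classmethod
    def from_json_dict(cls, d: dict) -> "ViscosityModel":
        return cls(FactorModel.from_json_dict(d["factor_model"]), np.array(d["beta"]))


def fit_factor_model(table, n_factors: int,
                     rotation: Literal[None, "varimax"] = None,
                     max_iter: int = 5000,
                     heywood_warn: float = 0.005,
                     uniqueness_floor: float = 1e-8) -> FactorModel:
    """Maximum-likelihood factor analysis on the feature correlation matrix.

    Ratings are standardized (population sd) so the analysed covariance is
    the correlation matrix; the ML solution is unrotated by default, with
    varimax selectable.  Column signs follow the majority-non-negative
    convention.  A Heywood case (uniqueness below ``heywood_warn``) raises a
    warning; uniquenesses are floored at ``uniqueness_floor`` only for
    numerical safety, so a near-perfect low-rank fit is reported as such.
    """
    values = _feature_matrix(table)
    X = values.to_numpy(dtype=float)
    n, p = X.shape
    if n_factors < 1:
        raise ValueError("n_factors must be >= 1")
    if n_factors >= p:
        raise ValueError("need more features than factors")
    mean = X.mean(axis=0)
    sd = X.std(axis=0)
    if sd.min() < 1e-14:
        raise ValueError("constant feature column")
    Z = (X - mean) / sd
    fa = FactorAnalysis(n_components=n_factors, rotation=rotation,
                        max_iter=max_iter, tol=1e-6, svd_method="lapack")
    fa.fit(Z)
    lam = fa.components_.T.copy()
    uniq = fa.noise_variance_.copy()
    if (uniq < heywood_warn).any():
        warnings.warn("Heywood case: uniqueness near zero for "
                      f"{int((uniq < heywood_warn).sum())} feature(s)",
                      RuntimeWarning)
    uniq = np.clip(uniq, uniqueness_floor, 1.0)
    # majority of loadings non-negative per factor
    flip = (lam > 0).sum(axis=0) < (lam < 0).sum(axis=0)
    lam[:, flip] *= -1.0
    return FactorModel(lam, uniq, list(values.columns),
                       [f"factor_{j+1}" for j in range(n_factors)],
                       mean, sd, rotation)


def factor_scores(model: FactorModel, table,
                  standardize_with: Literal["train", "self"] = "train") -> pd.DataFrame:
    """Harman factor scores: standardized data · Λ(ΛᵀΛ)⁻¹.

    By default the model's stored training mean/sd standardize the data, so
    scoring the training table reproduces the training scores exactly.
    """
    values = _feature_matrix(table)
    missing = [c for c in model.feature_names if c not in values.columns]
    extra = [c for c in values.columns if c not in model.feature_names]
    if missing or extra:
        raise ValueError(f"feature mismatch: missing={missing}, extra={extra}")
    Z = model.standardize(values[model.feature_names], standardize_with)
    S = Z @ model.score_weights
    return pd.DataFrame(S, columns=model.factor_names, index=values.index)


def fit_viscosity_regression(scores: pd.DataFrame, viscosity_ratings
                             ) -> tuple[ViscosityModel, FitReport]:
    """OLS of mean viscosity ratings on the factor scores.

    ``viscosity_ratings`` may be a RatingsTable (repetitions averaged
    first) or an aligned 1-D array.  The factor model is attached by the
    caller through ``build_viscosity_model``; here only β and the fit
    report are produced — see that helper for the packaged model.
    """
    y = _ratings_vector(viscosity_ratings)
    X = np.asarray(scores, dtype=float)
    if len(y) != len(X):
        raise ValueError("scores and ratings are not aligned")
    if len(y) <= X.shape[1] + 1:
        raise ValueError("need n > n_factors + 1 observations")
    rep, _ = ols_report(X, y)
    return rep.params, rep


def build_viscosity_model(factor_model: FactorModel, scores: pd.DataFrame,
                          viscosity_ratings) -> tuple[ViscosityModel, FitReport]:
    beta, rep = fit_viscosity_regression(scores, viscosity_ratings)
    return ViscosityModel(factor_model, beta), rep


def _ratings_vector(ratings) -> np.ndarray:
    if isinstance(ratings, RatingsTable):
        return ratings.average_repetitions().values.to_numpy(dtype=float).ravel()
    return np.asarray(ratings, dtype=float).ravel()


def predict_transfer(model: ViscosityModel, new_table, new_viscosity_ratings,
                     standardize_with: Literal["self", "train"] = "self"
                     ) -> tuple[np.ndarray, FitReport]:
    """Apply a frozen model to a new context; no parameters are refit.

    The new feature table is standardized within itself by default (slider
    settings are scale-free per experiment), scored with the stored Harman
    weights, and pushed through the stored β.  The report regresses the
    observed ratings on the predictions (df1 = 1, df2 = n − 2).
    """
    scores = factor_scores(model.factor_model, new_table, standardize_with)
    pred = model.predict_from_scores(scores.to_numpy())
    y = _ratings_vector(new_viscosity_ratings)
    rep, _ = ols_report(pred, y)
    return pred, rep


# ---------------------------------------------------------------------------
# baselines and diagnostics
# ---------------------------------------------------------------------------


def bootstrap_random_predictor_baseline(viscosity_ratings, n_predictors: int,
                                        n_boot: int = 1000, seed: int = 0) -> dict:
    """R² distribution of OLS on iid standard-normal random regressors.

    Under this null, E[R²] = k/(n−1); the distribution quantifies how many
    arbitrary predictors would be needed to match a given fit quality by
    chance alone.
    """
    if n_boot < 100:
        raise ValueError("n_boot must be at least 100")
    y = _ratings_vector(viscosity_ratings)
    n = len(y)
    if not 1 <= n_predictors <= n - 1:
        raise ValueError("n_predictors must lie in [1, n-1]")
    rng = np.random.default_rng(child_seed(seed, "bootstrap"))
    yc = y - y.mean()
    tss = float(yc @ yc)
    r2 = np.empty(n_boot)
    for b in range(n_boot):
        X = rng.standard_normal((n, n_predictors))
        Xc = np.column_stack([np.ones(n), X])
        coef, *_ = np.linalg.lstsq(Xc, y, rcond=None)
        resid = y - Xc @ coef
        r2[b] = 1.0 - float(resid @ resid) / tss
    return {"r2": r2, "mean": float(r2.mean()),
            "ci95": (float(np.quantile(r2, 0.025)), float(np.quantile(r2, 0.975))),
            "n_predictors": n_predictors, "n": n}


def tucker_congruence(A: np.ndarray, B: np.ndarray, match: bool = True) -> float:
    """Mean |Tucker congruence| between matched loading columns.

    Columns are matched by maximising total |congruence| (Hungarian
    assignment), which makes recovery checks agnostic to column order,
    sign, and — combined with a prior orthogonal Procrustes alignment when
    needed — rotation.
    """
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    num = A.T @ B
    den = np.sqrt(np.outer((A**2).sum(axis=0), (B**2).sum(axis=0)))
    phi = np.abs(num / den)
    if match:
        r, c = linear_sum_assignment(-phi)
        return float(phi[r, c].mean())
    return float(np.diag(phi).mean())


def procrustes_align(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Orthogonal rotation of B's columns best aligning it with A."""
    U, _, Vt = np.linalg.svd(np.asarray(B).T @ np.asarray(A))
    return np.asarray(B) @ (U @ Vt)
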