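"""NIPALS partial least squares calibration with leave-one-out cross-validation.

PLS regresses a response (nitrate content, mg/kg) on collinear spectra by
extracting latent factors that maximize covariance between spectra and
response.  :class:`NIPALSPLS` implements the classical NIPALS algorithm as a
scikit-learn regressor: X and y are mean-centered (not variance-scaled),
factors are extracted by iterated weight/score/loading updates with
deflation, and prediction runs new spectra through the stored weights and
loadings.  Because factors are extracted greedily, a model fitted with K
factors contains every smaller model as a prefix; ``predict_per_factor``
exposes this, and leave-one-out cross-validation exploits it to score all
factor counts with one fit per fold.

Factor selection follows the lowest-RMSECV rule: the smallest factor count
attaining the minimum root mean squared error of cross-validation. The
cross-validated r² is the squared Pearson correlation between reference
values and held-out predictions (with 1 − SSE/SST also reported).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin

from .preprocess import PreprocessRecipe, SpectrumMatrix

__all__ = [
    "NIPALSPLS",
    "CalibrationTable",
    "CVResult",
    "ConvergenceError",
    "fit_pls",
    "predict",
    "loocv",
    "select_factors",
    "regression_metrics",
    "summarize_references",
]


class ConvergenceError(RuntimeError):
    """NIPALS score iteration failed to converge for some factor."""


@dataclass
class CalibrationTable:
    """Paired mean spectra and reference nitrate contents.

    One spectrum row per sample; reference values are positive mg/kg (the
    wet-chemistry reflectometer role); ids are unique. ``metadata`` may carry
    fertilizer condition, sampling day, or generator truth.
    """

    sample_ids: list[str]
    nitrate_mg_per_kg: np.ndarray
    spectra: SpectrumMatrix
    metadata: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.nitrate_mg_per_kg = np.asarray(self.nitrate_mg_per_kg, dtype=float)
        n = len(self.sample_ids)
        if len(set(self.sample_ids)) != n:
            raise ValueError("duplicate sample ids")
        if self.nitrate_mg_per_kg.shape != (n,):
            raise ValueError("one nitrate value per sample required")
        if np.any(self.nitrate_mg_per_kg <= 0):
            raise ValueError("nitrate reference values must be positive")
        if self.spectra.n_samples != n:
            raise ValueError("one spectrum per sample required")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_csv(self, path) -> None:
        df = pd.DataFrame(self.spectra.values,
                          columns=[f"{w:.4f}" for w in self.spectra.wavelengths])
        df.insert(0, "nitrate_mg_kg", self.nitrate_mg_per_kg)
        df.insert(0, "sample_id", self.sample_ids)
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "CalibrationTable":
        df = pd.read_csv(path)
        wl = np.array([float(c) for c in df.columns[2:]])
        return cls(
            sample_ids=[str(s) for s in df["sample_id"]],
            nitrate_mg_per_kg=df["nitrate_mg_kg"].to_numpy(),
            spectra=SpectrumMatrix(df.iloc[:, 2:].to_numpy(), wl),
        )


class NIPALSPLS(RegressorMixin, BaseEstimator):
    """Univariate-response PLS regression by the NIPALS algorithm.

    Parameters
    ----------
    n_factors : int
        Number of latent factors to extract.
    tol : float
        Relative score-change convergence threshold per factor.
    max_iter : int
        Iteration cap per factor before :class:`ConvergenceError`.

    Attributes (after ``fit``)
    --------------------------
    x_mean_, y_mean_ : centering vectors.
    x_weights_ : (n_bands, K) NIPALS weights, unit norm per column.
    x_loadings_ : (n_bands, K) X loadings.
    y_loadings_ : (K,) regression of y on each score.
    x_scores_ : (n_samples, K) training scores (mutually orthogonal).
    coef_ : (n_bands,) equivalent regression vector on centered X.
    """

    def __init__(self, n_factors: int = 10, tol: float = 1e-10, max_iter: int = 500):
        self.n_factors = n_factors
        self.tol = tol
        self.max_iter = max_iter

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        n, p = X.shape
        if y.shape[0] != n:
            raise ValueError("X and y disagree on n_samples")
        if n < 2:
            raise ValueError("need at least 2 samples")
        if not 1 <= self.n_factors <= min(n - 1, p):
            raise ValueError(
                f"n_factors must lie in [1, min(n-1, n_bands)] = "
                f"[1, {min(n - 1, p)}], got {self.n_factors}"
            )
        self.x_mean_ = X.mean(axis=0)
        self.y_mean_ = float(y.mean())
        Xc = X - self.x_mean_
        yc = y - self.y_mean_

        K = self.n_factors
        W = np.zeros((p, K))
        P = np.zeros((p, K))
        q = np.zeros(K)
        T = np.zeros((n, K))
        self.n_iter_ = []
        if not np.any(yc != 0):
            # constant response: nothing to regress; predict the mean
            self.x_weights_, self.x_loadings_ = W[:, :0], P[:, :0]
            self.y_loadings_, self.x_scores_ = q[:0], T[:, :0]
            self.n_factors_ = 0
            self.coef_ = np.zeros(p)
            self._rotation_ = np.zeros((p, 0))
            return self
        for k in range(K):
            # u initialized from y (the single response column); for a
            # univariate response the loop converges in one pass but is kept
            # iterative for uniformity with the multivariate algorithm.
            u = yc if np.any(yc != 0) else Xc[:, int(np.argmax(Xc.var(axis=0)))]
            t = np.zeros(n)
            t_old = None
            for it in range(self.max_iter):
                w = Xc.T @ u
                nw = np.linalg.norm(w)
                if nw == 0:
                    break
                w /= nw
                t = Xc @ w
                tt = t @ t
                if tt == 0:
                    break
                qk = (yc @ t) / tt
                if t_old is not None:
                    denom = np.linalg.norm(t)
                    if denom == 0 or np.linalg.norm(t - t_old) <= self.tol * denom:
                        break
                t_old = t
                u = yc * qk
            else:
                raise ConvergenceError(f"NIPALS did not converge for factor {k + 1}")
            self.n_iter_.append(it + 1)
            tt = t @ t
            if tt == 0:
                # X fully deflated: remaining factors carry nothing
                K = k
                W, P, q, T = W[:, :K], P[:, :K], q[:K], T[:, :K]
                break
            pk = (Xc.T @ t) / tt
            qk = (yc @ t) / tt
            W[:, k], P[:, k], q[k], T[:, k] = w, pk, qk, t
            Xc = Xc - np.outer(t, pk)
            yc = yc - t * qk
        self.x_weights_, self.x_loadings_, self.y_loadings_, self.x_scores_ = W, P, q, T
        self.n_factors_ = K
        # W (P'W)^-1 q : regression vector on centered X
        R = W @ np.linalg.inv(np.triu(P.T @ W)) if K else np.zeros((p, 0))
        self.coef_ = R @ q
        self._rotation_ = R
        return self

    def predict(self, X) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.x_mean_.size:
            raise ValueError(
                f"X has {X.shape[1]} bands, model was trained on {self.x_mean_.size}"
            )
        return self.y_mean_ + (X - self.x_mean_) @ self.coef_

    def predict_per_factor(self, X) -> np.ndarray:
        """(n_samples, K) predictions using 1..K factors (greedy prefixes)."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        T_new = (X - self.x_mean_) @ self._rotation_  # scores for new samples
        return self.y_mean_ + np.cumsum(T_new * self.y_loadings_, axis=1)


@dataclass
class CVResult:
    """Leave-one-out cross-validation summary over factor counts 1..K."""

    rmsecv_by_factor: np.ndarray
    r2_by_factor: np.ndarray
    r2_sse_by_factor: np.ndarray
    chosen_factors: int
    predictions: np.ndarray  # held-out predictions at chosen_factors
    predictions_by_factor: np.ndarray = field(repr=False, default=None)

    @property
    def rmsecv(self) -> float:
        return float(self.rmsecv_by_factor[self.chosen_factors - 1])

    @property
    def r2(self) -> float:
        return float(self.r2_by_factor[self.chosen_factors - 1])


def fit_pls(X: SpectrumMatrix | np.ndarray, y, n_factors: int) -> NIPALSPLS:
    values = X.values if isinstance(X, SpectrumMatrix) else X
    return NIPALSPLS(n_factors=n_factors).fit(values, y)


def predict(model: NIPALSPLS, X: SpectrumMatrix | np.ndarray) -> np.ndarray:
    values = X.values if isinstance(X, SpectrumMatrix) else X
    return model.predict(values)


def regression_metrics(y_true, y_pred) -> dict[str, float]:
    """r² (squared Pearson correlation) and RMSE between reference and prediction.

    Also reports ``r2_sse`` = 1 − SSE/SST. With zero variance in either
    vector the correlation is undefined and r² is NaN.
    """
    y_true = np.asarray(y_true, dtype=float).ravel()
    y_pred = np.asarray(y_pred, dtype=float).ravel()
    if y_true.size != y_pred.size or y_true.size < 2:
        raise ValueError("need two equal-length vectors of length >= 2")
    rmse = float(np.sqrt(np.mean((y_true - y_pred) ** 2)))
    st, sp = y_true.std(), y_pred.std()
    if st == 0 or sp == 0:
        r2 = float("nan")
    else:
        r2 = float(np.corrcoef(y_true, y_pred)[0, 1] ** 2)
    sst = float(np.sum((y_true - y_true.mean()) ** 2))
    r2_sse = float("nan") if sst == 0 else 1.0 - float(np.sum((y_true - y_pred) ** 2)) / sst
    return {"r2": r2, "rmse": rmse, "r2_sse": r2_sse}


def loocv(X: SpectrumMatrix | np.ndarray, y, max_factors: int = 20) -> CVResult:
    """Leave-one-out cross-validation of NIPALS PLS over 1..max_factors.

    Each sample is held out in turn and a model fitted on the remainder at
    ``max_factors``; held-out predictions at every smaller factor count are
    read off the greedy factor sequence. RMSECV_k is the root mean squared
    held-out error at k factors; the chosen factor count is the smallest k
    attaining the minimum RMSECV.
    """
    values = X.values if isinstance(X, SpectrumMatrix) else np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n = values.shape[0]
    if n < 3:
        raise ValueError("LOOCV needs at least 3 samples")
    if max_factors > n - 2:
        raise ValueError(f"max_factors must be <= n - 2 = {n - 2}")
    preds = np.empty((n, max_factors))
    for i in range(n):
        keep = np.arange(n) != i
        model = NIPALSPLS(n_factors=max_factors).fit(values[keep], y[keep])
        pk = model.predict_per_factor(values[i : i + 1])[0]
        if pk.size < max_factors:  # rank-deficient fold: extend with last value
            tail = pk[-1] if pk.size else model.y_mean_
            pk = np.concatenate([pk, np.full(max_factors - pk.size, tail)])
        preds[i] = pk
    rmsecv = np.sqrt(np.mean((preds - y[:, None]) ** 2, axis=0))
    r2 = np.empty(max_factors)
    r2_sse = np.empty(max_factors)
    for k in range(max_factors):
        m = regression_metrics(y, preds[:, k])
        r2[k], r2_sse[k] = m["r2"], m["r2_sse"]
    chosen = int(np.argmin(rmsecv)) + 1  # argmin returns the first minimum
    return CVResult(
        rmsecv_by_factor=rmsecv,
        r2_by_factor=r2,
        r2_sse_by_factor=r2_sse,
        chosen_factors=chosen,
        predictions=preds[:, chosen - 1],
        predictions_by_factor=preds,
    )


def select_factors(cv: CVResult) -> int:
    """Smallest factor count attaining the minimum RMSECV."""
    return int(np.argmin(cv.rmsecv_by_factor)) + 1


def summarize_references(table: CalibrationTable | np.ndarray) -> dict[str, float]:
    """n / min / max / mean / median / sample-sd summary of reference values."""
    y = table.nitrate_mg_per_kg if isinstance(table, CalibrationTable) else np.asarray(table, float)
    if y.size == 0:
        raise ValueError("empty reference table")
    sd = float(np.std(y, ddof=1)) if y.size > 1 else 0.0
    return {
        "n": int(y.size),
        "min": float(y.min()),
        "max": float(y.max()),
        "mean": float(y.mean()),
        "median": float(np.median(y)),
        "sd": sd,
    }
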