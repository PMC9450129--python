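"""Partial least squares regression (PLS1) with cross-validated model size.

The fit is the classical NIPALS sequence on mean-centered data: each
latent variable (LV) maximises covariance between a spectral score and
the response, the matrices are deflated, and the per-component weights
``W``, x-loadings ``P`` and y-loadings ``q`` are kept so that the model
collapses to a single affine map ``y_hat = intercept + X @ coef``.

Model size is chosen by k-fold cross-validation: the number of LVs is
the (first) minimiser of RMSECV, i.e. ties break toward the more
parsimonious model.  Evaluation follows the chemometrics conventions
used for fruit-quality calibrations:

* ``r2 = 1 - SSE/SST`` (can be negative for a worse-than-mean predictor),
* ``bias = mean(predicted - reference)``,
* ``rpd = sd_ref / rmse`` with the population SD (divisor n), so a
  constant-mean predictor scores RPD = 1 exactly.  RPD > 2 indicates a
  good calibration, RPD < 1 no predictive power.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .errors import FitError, ParameterError, ValidationError

__all__ = [
    "PLSRModel",
    "CVResult",
    "EvaluationReport",
    "CVSpec",
    "fit_plsr",
    "predict",
    "cross_validate",
    "evaluate",
]


@dataclass
class PLSRModel:
    """Fitted PLS1 model: component matrices plus the collapsed affine map."""

    x_mean: np.ndarray
    y_mean: float
    W: np.ndarray  # (p, n_lv) weights
    P: np.ndarray  # (p, n_lv) x-loadings
    q: np.ndarray  # (n_lv,) y-loadings
    coef: np.ndarray  # (p,)
    intercept: float
    n_lv: int

    @property
    def n_wavelengths(self) -> int:
        return self.coef.shape[0]

    def predict(self, X: np.ndarray) -> np.ndarray:
        return predict(self, X)


@dataclass
class CVSpec:
    """Cross-validation settings threaded through the workflow."""

    k: int = 5
    seed: int = 0
    grouping: Optional[str] = None  # None | "fruit"
    max_lv: int = 12


@dataclass
class CVResult:
    rmsecv: np.ndarray  # indexed by LV count - 1
    n_lv: int
    folds: np.ndarray  # fold id per sample
    seed: int
    y_cv: np.ndarray = field(default=None, repr=False)  # held-out predictions at n_lv


@dataclass
class EvaluationReport:
    r2: float
    rmse: float
    bias: float
    rpd: float
    sd_ref: float
    n: int


def _nipals(Xc: np.ndarray, yc: np.ndarray, n_lv: int):
    """NIPALS PLS1 on centered data; returns (W, P, q)."""
    n, p = Xc.shape
    X = Xc.copy()
    y = yc.copy()
    W = np.zeros((p, n_lv))
    P = np.zeros((p, n_lv))
    q = np.zeros(n_lv)
    for a in range(n_lv):
        w = X.T @ y
        nw = np.linalg.norm(w)
        if nw < 1e-14:
            # residual covariance exhausted; truncate
            return W[:, :a], P[:, :a], q[:a]
        w /= nw
        t = X @ w
        tt = float(t @ t)
        if tt < 1e-14:
            return W[:, :a], P[:, :a], q[:a]
        p_a = (X.T @ t) / tt
        q_a = float(y @ t) / tt
        X -= np.outer(t, p_a)
        y = y - q_a * t
        W[:, a], P[:, a], q[a] = w, p_a, q_a
    return W, P, q


def _coef_from_components(W: np.ndarray, P: np.ndarray, q: np.ndarray, n_lv: int) -> np.ndarray:
    """Regression vector using the first ``n_lv`` components: B = W (PᵀW)⁻¹ q."""
    Wl, Pl, ql = W[:, :n_lv], P[:, :n_lv], q[:n_lv]
    return Wl @ np.linalg.solve(Pl.T @ Wl, ql)


def fit_plsr(X: np.ndarray, y: np.ndarray, n_lv: int) -> PLSRModel:
    """Fit a PLS1 model with ``n_lv`` latent variables.

    Deterministic (no random initialisation).  Raises
    :class:`ParameterError` if ``n_lv`` exceeds ``min(n-1, p)`` and
    :class:`FitError` on a zero-variance response.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValidationError("X and y shapes are incompatible")
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
        raise ValidationError("X and y must be finite")
    n, p = X.shape
    if n_lv < 1 or n_lv > min(n - 1, p):
        raise ParameterError(f"n_lv={n_lv} not in [1, min(n-1, p)={min(n - 1, p)}]")
    if np.std(y) == 0:
        raise FitError("response has zero variance")
    x_mean = X.mean(axis=0)
    y_mean = float(y.mean())
    W, P, q = _nipals(X - x_mean, y - y_mean, n_lv)
    if W.shape[1] == 0:
        raise FitError("no PLS component could be extracted")
    a = W.shape[1]
    coef = _coef_from_components(W, P, q, a)
    intercept = y_mean - float(x_mean @ coef)
    return PLSRModel(x_mean, y_mean, W, P, q, coef, intercept, a)


def predict(model: PLSRModel, X: np.ndarray) -> np.ndarray:
    """Affine prediction ``intercept + X @ coef`` vectorised over rows."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != model.n_wavelengths:
        raise ValidationError(
            f"X has {X.shape[1]} columns, model expects {model.n_wavelengths}"
        )
    return model.intercept + X @ model.coef


def _prediction_path(model_like, X: np.ndarray) -> np.ndarray:
    """Predictions for every LV count 1..a in one pass; shape (n, a)."""
    x_mean, y_mean, W, P, q = model_like
    a = W.shape[1]
    Xc = X - x_mean
    out = np.empty((X.shape[0], a))
    for l in range(1, a + 1):
        coef = _coef_from_components(W, P, q, l)
        out[:, l - 1] = y_mean + Xc @ coef
    return out


def make_folds(n: int, k: int, seed: int, groups=None) -> np.ndarray:
    """Random fold assignment; with ``groups``, a group never spans folds."""
    if k < 2 or k > n:
        raise ParameterError(f"k={k} not in [2, n={n}]")
    rng = np.random.default_rng(seed)
    folds = np.empty(n, dtype=int)
    if groups is None:
        perm = rng.permutation(n)
        for i, idx in enumerate(np.array_split(perm, k)):
            folds[idx] = i
    else:
        groups = np.asarray(groups)
        uniq = np.unique(groups)
        if len(uniq) < k:
            raise ParameterError("fewer groups than folds")
        perm = rng.permutation(len(uniq))
        for i, gidx in enumerate(np.array_split(perm, k)):
            folds[np.isin(groups, uniq[gidx])] = i
    return folds


def cross_validate(
    X: np.ndarray,
    y: np.ndarray,
    max_lv: int,
    k: int = 5,
    seed: int = 0,
    groups=None,
) -> CVResult:
    """k-fold CV over LV counts 1..max_lv; chooses the first RMSECV minimum.

    RMSECV is computed over the concatenated held-out predictions.
    ``groups`` (e.g. fruit ids) keeps all of a group's spectra in one
    fold.  ``k = n`` gives leave-one-out, which is deterministic
    regardless of the seed.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    folds = make_folds(n, k, seed, groups=groups)
    max_lv = min(max_lv, p)
    # every training split must support max_lv components
    for i in range(k):
        n_train = int(np.sum(folds != i))
        max_lv = min(max_lv, n_train - 1)
    if max_lv < 1:
        raise ParameterError("not enough samples per fold for one LV")
    preds = np.full((n, max_lv), np.nan)
    for i in range(k):
        tr = folds != i
        te = ~tr
        Xtr, ytr = X[tr], y[tr]
        x_mean = Xtr.mean(axis=0)
        y_mean = float(ytr.mean())
        W, P, q = _nipals(Xtr - x_mean, ytr - y_mean, max_lv)
        path = _prediction_path((x_mean, y_mean, W, P, q), X[te])
        a = path.shape[1]
        preds[te, :a] = path
        if a < max_lv:  # rank-deficient fold: pad with last available model
            preds[te, a:] = path[:, [a - 1]]
    rmsecv = np.sqrt(np.mean((preds - y[:, None]) ** 2, axis=0))
    n_lv = int(np.argmin(rmsecv)) + 1  # argmin takes the first minimum
    return CVResult(rmsecv=rmsecv, n_lv=n_lv, folds=folds, seed=seed,
                    y_cv=preds[:, n_lv - 1])


def evaluate(y_hat: np.ndarray, y_ref: np.ndarray) -> EvaluationReport:
    """Chemometrics summary of predictions against reference values."""
    y_hat = np.asarray(y_hat, dtype=float).ravel()
    y_ref = np.asarray(y_ref, dtype=float).ravel()
    if y_hat.shape != y_ref.shape or y_ref.size < 2:
        raise ValidationError("y_hat and y_ref must be equal-length vectors of size >= 2")
    sd_ref = float(np.std(y_ref))  # population convention (divisor n)
    if sd_ref == 0:
        raise ValidationError("reference values have zero variance")
    resid = y_hat - y_ref
    rmse = float(np.sqrt(np.mean(resid**2)))
    bias = float(np.mean(resid))
    sse = float(np.sum(resid**2))
    sst = float(np.sum((y_ref - y_ref.mean()) ** 2))
    r2 = 1.0 - sse / sst
    rpd = float(np.inf) if rmse == 0 else sd_ref / rmse
    return EvaluationReport(r2=r2, rmse=rmse, bias=bias, rpd=rpd,
                            sd_ref=sd_ref, n=y_ref.size)
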