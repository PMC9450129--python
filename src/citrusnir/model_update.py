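"""Batch-to-batch model maintenance for PLSR calibrations.

Four maintenance strategies for a calibration confronted with a new
fruit batch (new variety, season or population):

* **MU** — model update: merge labeled standard samples from the new
  batch into the calibration set and refit everything;
* **SBC** — slope/bias correction: fit ``reference = a + b·prediction``
  on the standards and correct predictions post hoc, leaving the model
  (and its calibration statistics) untouched;
* **OSC** — orthogonal signal correction: deflate from the calibration
  spectra the components whose scores are orthogonal to the response,
  then refit;
* **DOP** — EPO-style dynamic orthogonal projection: estimate the
  between-batch difference subspace from the standards, project it out
  of calibration and all future spectra, then refit.

A PCA score plot plus :func:`coverage_index` quantify whether the
standards cover the prediction batch — the practical determinant of
update success.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.spatial import Delaunay, QhullError
from sklearn.decomposition import PCA

from .errors import CitrusNIRError, FitError, ParameterError, ValidationError
from .plsr_core import CVSpec, PLSRModel, cross_validate, fit_plsr, predict
from .preprocessing import PreprocessState, apply_chain, fit_chain
from .spectra_io import AnalysisSet, SpectraSet

logger = logging.getLogger(__name__)


@dataclass
class UpdateCorrection:
    """Fitted maintenance artifact; fields depend on ``kind``."""

    kind: str  # "MU" | "SBC" | "OSC" | "DOP"
    # SBC
    slope: Optional[float] = None
    bias: Optional[float] = None
    # OSC
    x_mean: Optional[np.ndarray] = None
    osc_weights: Optional[np.ndarray] = None  # (p, n_osc)
    osc_loadings: Optional[np.ndarray] = None  # (p, n_osc)
    osc_scores: Optional[np.ndarray] = None  # (n_cal, n_osc) removed scores
    # DOP
    basis: Optional[np.ndarray] = None  # (p, K) orthonormal
    K: Optional[int] = None
    update_ids: Optional[list] = None

    def __post_init__(self):
        if self.kind == "SBC" and self.slope is not None and self.slope == 0:
            raise ValidationError("SBC slope must be nonzero")
        if self.kind == "DOP" and self.basis is not None:
            V = np.asarray(self.basis, dtype=float)
            if not np.allclose(V.T @ V, np.eye(V.shape[1]), atol=1e-10):
                raise ValidationError("DOP basis must be orthonormal")
            self.basis = V


# ---------------------------------------------------------------------------
# MU


def model_update_mu(calibration: AnalysisSet, update_set: AnalysisSet,
                    chain_spec: str, n_lv: int, attribute: str = "ssc",
                    cv_spec: CVSpec | None = None,
                    reselect_lv: bool = False) -> Tuple[PLSRModel, PreprocessState]:
    """Recalibrate on calibration ∪ standards; returns (model, chain state).

    Preprocessing is refit on the union; the LV count stays fixed unless
    ``reselect_lv``.
    """
    cal_ids = set(calibration.spectra.spectrum_ids)
    upd_ids = set(update_set.spectra.spectrum_ids) if update_set.n else set()
    if cal_ids & upd_ids:
        raise ValidationError(f"update set overlaps calibration: {sorted(cal_ids & upd_ids)[:5]}")
    if update_set.n:
        union = concat_analysis_sets([calibration, update_set])
    else:
        union = calibration
    state = fit_chain(chain_spec, union, cv_spec=cv_spec, attribute=attribute)
    Xu = apply_chain(state, union.spectra).absorbance
    yu = union.y(attribute)
    if reselect_lv:
        cv = cv_spec or CVSpec()
        n_lv = cross_validate(Xu, yu, max_lv=cv.max_lv, k=cv.k, seed=cv.seed).n_lv
    model = fit_plsr(Xu, yu, n_lv)
    return model, state


def concat_analysis_sets(sets: Sequence[AnalysisSet]) -> AnalysisSet:
    """Row-wise concatenation on a shared grid."""
    from .spectra_io import ReferenceTable

    grid = sets[0].spectra.grid
    for s in sets[1:]:
        if s.spectra.grid != grid:
            raise ValidationError("cannot concatenate sets on different grids")
    A = np.vstack([s.X for s in sets])
    meta = pd.concat([s.spectra.meta for s in sets], ignore_index=True)
    ref = pd.concat([s.reference.table for s in sets], ignore_index=True)
    return AnalysisSet(SpectraSet(grid, A, meta), ReferenceTable(ref))


# ---------------------------------------------------------------------------
# SBC


def sbc_fit(model: PLSRModel, update_set: AnalysisSet,
            chain_state: PreprocessState, attribute: str = "ssc") -> UpdateCorrection:
    """Least-squares line ``reference = bias + slope·prediction`` on standards."""
    if update_set.n < 3:
        raise ParameterError("SBC needs at least 3 update samples")
    Xu = apply_chain(chain_state, update_set.spectra).absorbance
    y_hat = predict(model, Xu)
    y_ref = update_set.y(attribute)
    if np.std(y_hat) < 1e-10:
        raise FitError("predictions on the update set have (near-)zero variance")
    slope, bias = np.polyfit(y_hat, y_ref, 1)
    return UpdateCorrection(kind="SBC", slope=float(slope), bias=float(bias),
                            update_ids=update_set.spectra.spectrum_ids.tolist())


def sbc_apply(correction: UpdateCorrection, y_hat: np.ndarray) -> np.ndarray:
    if correction.kind != "SBC":
        raise ParameterError("correction is not an SBC artifact")
    return correction.bias + correction.slope * np.asarray(y_hat, dtype=float)


# ---------------------------------------------------------------------------
# OSC


def osc_fit(X: np.ndarray, y: np.ndarray, n_osc: int = 1,
            max_iter: int = 100, tol: float = 1e-10) -> UpdateCorrection:
    """Extract ``n_osc`` response-orthogonal components from centered X.

    Each component starts from the leading principal direction, its score
    is orthogonalised against the centered response, weights are the
    least-squares preimage of that score, and the loop iterates to
    convergence before X is deflated.  Removed calibration scores are
    exactly orthogonal to centered y by construction.
    """
    if n_osc < 1:
        raise ParameterError("n_osc must be >= 1")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    x_mean = X.mean(axis=0)
    Xc = X - x_mean
    yc = y - y.mean()
    yy = float(yc @ yc)
    if yy == 0:
        raise FitError("response has zero variance")
    n, p = X.shape
    Ws = np.zeros((p, n_osc))
    Ps = np.zeros((p, n_osc))
    Ts = np.zeros((n, n_osc))
    for comp in range(n_osc):
        # seed from the first principal score not aligned with the response
        U, s, _ = np.linalg.svd(Xc, full_matrices=False)
        t = None
        for j in range(min(5, s.size)):
            cand = U[:, j] * s[j]
            resid = cand - yc * (float(yc @ cand) / yy)
            if np.linalg.norm(resid) > 1e-8 * max(1.0, np.linalg.norm(cand)):
                t = cand
                break
        if t is None:
            raise FitError("OSC found no response-orthogonal structure to remove")
        converged = False
        w = None
        for _ in range(max_iter):
            t_orth = t - yc * (float(yc @ t) / yy)
            nt = np.linalg.norm(t_orth)
            if nt < 1e-14:
                break
            t_orth *= np.linalg.norm(t) / nt  # keep the score scale stable
            w, *_ = np.linalg.lstsq(Xc, t_orth, rcond=None)
            t_new = Xc @ w
            if np.linalg.norm(t_new - t_orth) <= tol * np.linalg.norm(t_orth):
                t = t_new
                converged = True
                break
            t = t_new
        if not converged:
            logger.warning("OSC component %d did not fully converge; using last iterate",
                           comp + 1)
        # enforce exact orthogonality of the removed calibration score
        t = t - yc * (float(yc @ t) / yy)
        tt = float(t @ t)
        if tt < 1e-14:
            raise FitError("OSC found no response-orthogonal structure to remove")
        p_load = Xc.T @ t / tt
        Xc = Xc - np.outer(t, p_load)
        Ws[:, comp], Ps[:, comp], Ts[:, comp] = w, p_load, t
    return UpdateCorrection(kind="OSC", x_mean=x_mean, osc_weights=Ws,
                            osc_loadings=Ps, osc_scores=Ts)


def osc_apply(correction: UpdateCorrection, X: np.ndarray) -> np.ndarray:
    """Deflate new spectra with the stored weight/loading pairs."""
    if correction.kind != "OSC":
        raise ParameterError("correction is not an OSC artifact")
    X = np.atleast_2d(np.asarray(X, dtype=float)).copy()
    Xc = X - correction.x_mean
    for comp in range(correction.osc_weights.shape[1]):
        w = correction.osc_weights[:, comp]
        pl = correction.osc_loadings[:, comp]
        t = Xc @ w
        X = X - np.outer(t, pl)
        Xc = Xc - np.outer(t, pl)
    return X


# ---------------------------------------------------------------------------
# DOP


def _match_by_reference(cal_X: np.ndarray, cal_y: np.ndarray,
                        upd_y: np.ndarray) -> np.ndarray:
    """For each update sample, the mean calibration spectrum at the nearest
    reference value (ties averaged)."""
    out = np.empty((upd_y.size, cal_X.shape[1]))
    for i, yv in enumerate(upd_y):
        d = np.abs(cal_y - yv)
        ties = np.flatnonzero(d == d.min())
        out[i] = cal_X[ties].mean(axis=0)
    return out


def dop_fit(calibration: AnalysisSet, update_set: AnalysisSet,
            chain_state: PreprocessState, n_lv: int,
            K_range: Sequence[int] = range(1, 21),
            attribute: str = "ssc") -> Tuple[UpdateCorrection, PLSRModel]:
    """EPO-framework projection removing the between-batch difference subspace.

    The difference matrix pairs each standard with the calibration
    spectra of matched reference value; its right eigenvectors give the
    interference basis V, and P = I − VVᵀ is applied to calibration and
    every future spectrum.  K is chosen from ``K_range`` by minimal
    RMSEP on the standards.
    """
    if update_set.n < 3:
        raise ParameterError("DOP needs at least 3 update samples")
    X_cal = apply_chain(chain_state, calibration.spectra).absorbance
    y_cal = calibration.y(attribute)
    X_upd = apply_chain(chain_state, update_set.spectra).absorbance
    y_upd = update_set.y(attribute)
    p = X_cal.shape[1]
    K_range = [k for k in K_range]
    if max(K_range) >= p:
        raise ParameterError(f"K must be < p={p}")
    D = X_upd - _match_by_reference(X_cal, y_cal, y_upd)
    evals, evecs = np.linalg.eigh(D.T @ D)
    order = np.argsort(evals)[::-1]
    evecs = evecs[:, order]
    trials = []
    for K in K_range:
        V = evecs[:, :K]
        Xp = X_cal - (X_cal @ V) @ V.T
        model = fit_plsr(Xp, y_cal, min(n_lv, Xp.shape[0] - 1))
        Xu = X_upd - (X_upd @ V) @ V.T
        rmsep = float(np.sqrt(np.mean((predict(model, Xu) - y_upd) ** 2)))
        trials.append((K, rmsep, V, model))
    # smallest K within 2% of the best standards RMSEP (parsimonious choice;
    # a strict argmin always drifts to the largest K by overfitting the
    # standards)
    best_rmsep = min(t[1] for t in trials)
    K, _, V, model = next(t for t in trials if t[1] <= 1.02 * best_rmsep)
    corr = UpdateCorrection(kind="DOP", basis=V, K=K,
                            update_ids=update_set.spectra.spectrum_ids.tolist())
    return corr, model


def dop_apply(correction: UpdateCorrection, X: np.ndarray) -> np.ndarray:
    """Project spectra onto the complement of the interference basis."""
    if correction.kind != "DOP":
        raise ParameterError("correction is not a DOP artifact")
    X = np.atleast_2d(np.asarray(X, dtype=float))
    V = correction.basis
    return X - (X @ V) @ V.T


# ---------------------------------------------------------------------------
# coverage diagnostics


def pca_scores(spectra, n_components: int = 2,
               fit_on: Optional[np.ndarray] = None) -> np.ndarray:
    """Mean-centered PCA scores for coverage diagnostics.

    ``fit_on`` lets the rotation be estimated on a pooled matrix while
    scoring ``spectra`` in that shared space.
    """
    A = spectra.absorbance if isinstance(spectra, SpectraSet) else np.asarray(spectra, float)
    ref = A if fit_on is None else np.asarray(fit_on, float)
    if n_components > min(ref.shape[0] - 1, ref.shape[1]):
        raise ParameterError(f"n_components={n_components} too large for shape {ref.shape}")
    pca = PCA(n_components=n_components, svd_solver="full")
    pca.fit(ref)
    return pca.transform(A)


def coverage_index(update_scores: np.ndarray, prediction_scores: np.ndarray) -> float:
    """Fraction of prediction points inside the convex hull of update points
    in PC1-2 space.  A pure diagnostic: no thresholding is applied."""
    U = np.asarray(update_scores, dtype=float)[:, :2]
    P = np.asarray(prediction_scores, dtype=float)[:, :2]
    if U.shape[0] < 3:
        raise ParameterError("coverage_index needs at least 3 update points")
    try:
        tri = Delaunay(U)
    except QhullError as exc:
        raise CitrusNIRError(f"degenerate update-point geometry: {exc}") from exc
    return float(np.mean(tri.find_simplex(P) >= 0))
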