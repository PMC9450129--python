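"""Spectral pretreatments: SG second derivative, SNV, MSC, VSN, NSR.

All transforms are row-wise (per spectrum) and composable into a fitted
chain, declared left-to-right as e.g. ``"2D+VSN"`` — derivative first,
then scatter correction.  States are fitted on the calibration set only
and frozen for every later set.

Note: the Savitzky-Golay derivative is taken with respect to variable
*index* (unit step), not nm.  A uniform grid makes the two differ only
by the constant factor spacing², which a downstream regression absorbs.
Edges are handled by asymmetric-window polynomial fits so the output
keeps all variables; the derivative is therefore exact everywhere for
spectra that are polynomials of degree ≤ 2 in index.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import List, Optional, Tuple, Union

import numpy as np
from scipy.signal import savgol_filter

from .errors import ParameterError, StateError, TransformError
from .plsr_core import CVSpec, cross_validate
from .spectra_io import AnalysisSet, SpectraSet

logger = logging.getLogger(__name__)

Matrix = np.ndarray
SpectraLike = Union[SpectraSet, Matrix]


def _as_matrix(x: SpectraLike) -> Tuple[Matrix, SpectraSet | None]:
    if isinstance(x, SpectraSet):
        return x.absorbance, x
    return np.atleast_2d(np.asarray(x, dtype=float)), None


def _rewrap(A: Matrix, template: SpectraSet | None) -> SpectraLike:
    if template is None:
        return A
    return template.with_absorbance(A)


def _ids(template: SpectraSet | None, idx) -> list:
    if template is None:
        return list(np.atleast_1d(idx))
    return template.meta["spectrum_id"].iloc[np.atleast_1d(idx)].tolist()


# ---------------------------------------------------------------------------
# transform states


@dataclass
class SGParams:
    window: int = 13
    polyorder: int = 2
    deriv: int = 2


@dataclass
class SNVState:
    pass  # stateless; present so chains serialize uniformly


@dataclass
class MSCState:
    reference: np.ndarray  # mean calibration spectrum, frozen at fit


@dataclass
class VSNState:
    weights: np.ndarray  # per-wavelength, in [0, 1]
    converged: bool = True
    n_iter: int = 0


@dataclass
class NSRState:
    lambda1: float  # nm mapped to 1
    lambda2: float  # nm mapped to 0


@dataclass
class PreprocessState:
    """Ordered, fitted pretreatment chain."""

    chain: list  # of the state dataclasses above
    spec: str = ""


# ---------------------------------------------------------------------------
# Savitzky-Golay second derivative


def sg_second_derivative(x: SpectraLike, window: int = 13, polyorder: int = 2) -> SpectraLike:
    """Second SG derivative per spectrum (w.r.t. index position)."""
    A, tmpl = _as_matrix(x)
    if window % 2 == 0:
        raise ParameterError(f"window must be odd, got {window}")
    if window < polyorder + 1:
        raise ParameterError(f"window {window} too small for polyorder {polyorder}")
    if polyorder < 2:
        raise ParameterError("second derivative needs polyorder >= 2")
    if A.shape[1] < window:
        raise ParameterError(f"{A.shape[1]} variables < window {window}")
    # mode="interp" fits an asymmetric polynomial over the edge windows,
    # so degree-<=polyorder inputs differentiate exactly at every index
    D = savgol_filter(A, window_length=window, polyorder=polyorder,
                      deriv=2, delta=1.0, axis=1, mode="interp")
    return _rewrap(D, tmpl)


# ---------------------------------------------------------------------------
# SNV


def snv(x: SpectraLike) -> SpectraLike:
    """Standard normal variate: each spectrum to mean 0, SD 1 (divisor p)."""
    A, tmpl = _as_matrix(x)
    mu = A.mean(axis=1, keepdims=True)
    sd = A.std(axis=1, keepdims=True)
    flat = np.flatnonzero(sd.ravel() == 0)
    if flat.size:
        raise TransformError(f"constant spectra cannot be SNV-scaled: {_ids(tmpl, flat)}")
    return _rewrap((A - mu) / sd, tmpl)


# ---------------------------------------------------------------------------
# MSC


def msc_fit(calibration: SpectraLike) -> MSCState:
    """Freeze the MSC reference (mean calibration spectrum)."""
    A, _ = _as_matrix(calibration)
    if A.shape[0] == 0:
        raise ParameterError("MSC needs a nonempty calibration set")
    return MSCState(reference=A.mean(axis=0))


def msc_apply(state: MSCState, x: SpectraLike) -> SpectraLike:
    """Regress each spectrum on the reference; corrected = (x - b0)/b1."""
    A, tmpl = _as_matrix(x)
    r = state.reference
    rc = r - r.mean()
    denom = float(rc @ rc)
    b1 = (A - A.mean(axis=1, keepdims=True)) @ rc / denom
    b0 = A.mean(axis=1) - b1 * r.mean()
    bad = np.flatnonzero(b1 == 0)
    if bad.size:
        raise TransformError(f"zero MSC slope for spectra: {_ids(tmpl, bad)}")
    return _rewrap((A - b0[:, None]) / b1[:, None], tmpl)


# ---------------------------------------------------------------------------
# VSN


def _weighted_normalize(A: Matrix, w: np.ndarray) -> Matrix:
    ws = w.sum()
    mu = (A * w).sum(axis=1, keepdims=True) / ws
    var = ((A - mu) ** 2 * w).sum(axis=1, keepdims=True) / ws
    sd = np.sqrt(var)
    if np.any(sd == 0):
        raise TransformError("constant spectrum under VSN weighting")
    return (A - mu) / sd


def vsn_fit(calibration: SpectraLike, max_iter: int = 50, tol: float = 1e-6) -> VSNState:
    """Estimate per-wavelength normalisation weights.

    Iterative reweighting: wavelengths whose (normalised) values sit far
    from the pointwise median reference — typically the analyte-informative
    bands — receive low weight, so the normalisation parameters are
    estimated from the scatter-dominated part of the spectrum.  With
    uniform weights the transform reduces exactly to SNV.
    """
    A, _ = _as_matrix(calibration)
    if A.shape[0] < 3:
        raise ParameterError("VSN needs at least 3 calibration spectra")
    p = A.shape[1]
    w = np.ones(p)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        Z = _weighted_normalize(A, w)
        ref = np.median(Z, axis=0)
        m = np.median(np.abs(Z - ref), axis=0)
        s = float(np.median(m))
        w_new = np.ones(p) if s <= 0 else 1.0 / (1.0 + (m / s) ** 2)
        if np.max(np.abs(w_new - w)) < tol:
            w = w_new
            converged = True
            break
        w = w_new
    if not converged:
        logger.warning("VSN did not converge in %d iterations; using last iterate", max_iter)
    return VSNState(weights=w, converged=converged, n_iter=it)


def vsn_apply(state: VSNState, x: SpectraLike) -> SpectraLike:
    A, tmpl = _as_matrix(x)
    w = np.asarray(state.weights, dtype=float)
    if w.shape[0] != A.shape[1]:
        raise TransformError("VSN weights do not match spectrum length")
    return _rewrap(_weighted_normalize(A, w), tmpl)


# ---------------------------------------------------------------------------
# NSR


def nsr_apply(state: NSRState | Tuple[float, float], x: SpectraSet) -> SpectraSet:
    """Anchor each spectrum to 1 at λ1 and 0 at λ2."""
    if not isinstance(x, SpectraSet):
        raise TransformError("NSR needs a SpectraSet (anchors are wavelengths in nm)")
    lam1, lam2 = (state.lambda1, state.lambda2) if isinstance(state, NSRState) else state
    if lam1 == lam2:
        raise ParameterError("NSR anchors must be distinct")
    i1, i2 = x.grid.index_of(lam1), x.grid.index_of(lam2)
    A = x.absorbance
    denom = A[:, i1] - A[:, i2]
    bad = np.flatnonzero(denom == 0)
    if bad.size:
        raise TransformError(
            f"x(λ1) == x(λ2) for spectra: {x.meta['spectrum_id'].iloc[bad].tolist()}"
        )
    return x.with_absorbance((A - A[:, [i2]]) / denom[:, None])


def _nsr_criterion(A, y, i1, i2, cv: CVSpec) -> float:
    denom = A[:, i1] - A[:, i2]
    if np.any(denom == 0):
        return np.inf
    corrected = (A - A[:, [i2]]) / denom[:, None]
    res = cross_validate(corrected, y, max_lv=cv.max_lv, k=cv.k, seed=cv.seed)
    return float(res.rmsecv[res.n_lv - 1])


def nsr_select(calibration: AnalysisSet, cv_spec: CVSpec | None = None,
               attribute: str = "ssc", coarse_step: int = 4) -> NSRState:
    """Search anchor pairs minimising downstream PLSR RMSECV.

    Coarse grid over every ``coarse_step``-th wavelength, then a one-step
    refinement around the best pair.  The criterion is purely data-driven.
    """
    cv = cv_spec or CVSpec()
    A = calibration.X
    y = calibration.y(attribute)
    grid = calibration.spectra.grid
    p = A.shape[1]
    coarse = list(range(0, p, coarse_step))
    best = (np.inf, None)
    for ai, i1 in enumerate(coarse):
        for i2 in coarse[ai + 1:]:
            c = _nsr_criterion(A, y, i1, i2, cv)
            if c < best[0]:
                best = (c, (i1, i2))
    if best[1] is None:
        raise TransformError("no valid NSR anchor pair found")
    i1, i2 = best[1]
    for j1 in range(max(0, i1 - coarse_step + 1), min(p, i1 + coarse_step)):
        for j2 in range(max(0, i2 - coarse_step + 1), min(p, i2 + coarse_step)):
            if j1 == j2:
                continue
            c = _nsr_criterion(A, y, j1, j2, cv)
            if c < best[0]:
                best = (c, (j1, j2))
    i1, i2 = best[1]
    return NSRState(lambda1=float(grid.values[i1]), lambda2=float(grid.values[i2]))


# ---------------------------------------------------------------------------
# chains


CHAIN_ALIASES = {"2d": "2D", "snv": "SNV", "msc": "MSC", "vsn": "VSN",
                 "nsr": "NSR", "none": "", "": ""}


def parse_chain(spec: str) -> List[str]:
    """Parse a chain string like ``"2D+VSN"`` into ordered step names."""
    steps = []
    for tok in str(spec).split("+"):
        key = tok.strip().lower()
        if key not in CHAIN_ALIASES:
            raise ParameterError(f"unknown pretreatment {tok!r}")
        name = CHAIN_ALIASES[key]
        if name:
            steps.append(name)
    return steps


def fit_chain(spec: str, calibration: AnalysisSet, cv_spec: CVSpec | None = None,
              sg_params: SGParams | None = None, attribute: str = "ssc") -> PreprocessState:
    """Fit every step of a chain, in order, on calibration data only.

    Each step is fitted on the output of the preceding steps, then its
    transform is applied before the next is fitted.
    """
    steps = parse_chain(spec)
    sg = sg_params or SGParams()
    current = calibration
    chain = []
    for name in steps:
        if name == "2D":
            state = sg
            out = sg_second_derivative(current.spectra, sg.window, sg.polyorder)
        elif name == "SNV":
            state = SNVState()
            out = snv(current.spectra)
        elif name == "MSC":
            state = msc_fit(current.spectra)
            out = msc_apply(state, current.spectra)
        elif name == "VSN":
            state = vsn_fit(current.spectra)
            out = vsn_apply(state, current.spectra)
        elif name == "NSR":
            state = nsr_select(current, cv_spec=cv_spec, attribute=attribute)
            out = nsr_apply(state, current.spectra)
        chain.append(state)
        current = AnalysisSet(out, current.reference)
    return PreprocessState(chain=chain, spec="+".join(steps))


def apply_chain(state: PreprocessState, x: SpectraLike) -> SpectraLike:
    """Apply a fitted chain left to right."""
    if state is None or not isinstance(state, PreprocessState):
        raise StateError("apply_chain needs a fitted PreprocessState")
    out = x
    for step in state.chain:
        if isinstance(step, SGParams):
            out = sg_second_derivative(out, step.window, step.polyorder)
        elif isinstance(step, SNVState):
            out = snv(out)
        elif isinstance(step, MSCState):
            out = msc_apply(step, out)
        elif isinstance(step, VSNState):
            out = vsn_apply(step, out)
        elif isinstance(step, NSRState):
            out = nsr_apply(step, out)
        else:
            raise StateError(f"unknown chain step {type(step).__name__}")
    return out
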