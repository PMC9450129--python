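"""Wavelength selection for PLSR calibrations.

Five procedures commonly compared in short-wave NIR fruit-quality work:

* :func:`window_search` — exhaustive contiguous-interval search on a
  (start, width) grid, each window scored by its own CV-selected model;
* :func:`mc_uve` — Monte-Carlo uninformative variable elimination via
  the stability (mean/SD) of PLSR coefficients over random subsamples;
* :func:`spa` — successive projections algorithm, growing minimally
  collinear variable chains;
* :func:`vcpa` — variable combination population analysis: binary-matrix
  subset sampling with an exponentially decreasing retention schedule,
  finished by exhaustive search over the small survivor pool;
* :func:`iriv` — iteratively retaining informative variables: variables
  whose inclusion raises the ensemble RMSECV are dropped round by round,
  then backward elimination.

Every stochastic method takes an explicit seed and records it in its
:class:`SelectionResult`; the reported ``rmsecv`` is always that of a
final cross-validated refit on the selected variables.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu

from .errors import FitError, ParameterError
from .plsr_core import CVSpec, _nipals, _prediction_path, cross_validate, make_folds

logger = logging.getLogger(__name__)


@dataclass
class SelectionResult:
    method: str
    indices: np.ndarray  # sorted, unique, within grid
    rmsecv: float
    n_lv: int
    seed: Optional[int] = None
    window_nm: Optional[Tuple[float, float]] = None
    scores: Optional[np.ndarray] = None  # method-specific per-variable diagnostic
    surface: Optional[pd.DataFrame] = None  # window search RMSECV surface
    final_pool: Optional[np.ndarray] = None  # VCPA survivors before exhaustion

    def __post_init__(self):
        idx = np.unique(np.asarray(self.indices, dtype=int))
        if idx.size == 0:
            raise ParameterError("selection produced an empty variable set")
        self.indices = idx


def _final_cv(X, y, cols, cv: CVSpec) -> Tuple[float, int]:
    res = cross_validate(X[:, cols], y, max_lv=min(cv.max_lv, len(cols)),
                         k=cv.k, seed=cv.seed)
    return float(res.rmsecv[res.n_lv - 1]), res.n_lv


def _subset_rmsecv(X, y, cols, folds, n_lv: int) -> float:
    """RMSECV of a column subset at (up to) a fixed LV count, on fixed folds."""
    cols = np.asarray(cols)
    n = X.shape[0]
    preds = np.empty(n)
    for f in np.unique(folds):
        tr = folds != f
        Xtr = X[np.ix_(tr, cols)]
        ytr = y[tr]
        a = min(n_lv, len(cols), Xtr.shape[0] - 1)
        x_mean = Xtr.mean(axis=0)
        y_mean = float(ytr.mean())
        W, P, q = _nipals(Xtr - x_mean, ytr - y_mean, a)
        path = _prediction_path((x_mean, y_mean, W, P, q), X[np.ix_(~tr, cols)])
        preds[~tr] = path[:, -1]
    return float(np.sqrt(np.mean((preds - y) ** 2)))


# ---------------------------------------------------------------------------
# window search


def window_search(X, y, wavelengths=None, min_width: int = 20, width_step: int = 10,
                  start_step: int = 2, cv_spec: CVSpec | None = None) -> SelectionResult:
    """Exhaustive contiguous-window search minimising RMSECV.

    Every window on the (start, width) grid gets its own CV-chosen LV
    count; the full RMSECV surface is returned for plotting.  The
    full-spectrum window is always a candidate.
    """
    cv = cv_spec or CVSpec()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if min_width < 10:
        raise ParameterError("min_width must be >= 10 variables")
    widths = list(range(min_width, p, width_step))
    if not widths or widths[-1] != p:
        widths.append(p)
    rows = []
    best = (np.inf, None, None)
    for width in widths:
        for start in range(0, p - width + 1, start_step):
            cols = np.arange(start, start + width)
            res = cross_validate(X[:, cols], y, max_lv=min(cv.max_lv, width),
                                 k=cv.k, seed=cv.seed)
            rmsecv = float(res.rmsecv[res.n_lv - 1])
            rows.append({"start": start, "width": width, "rmsecv": rmsecv,
                         "n_lv": res.n_lv})
            if rmsecv < best[0]:
                best = (rmsecv, cols, res.n_lv)
    if best[1] is None:
        raise ParameterError("window grid produced zero candidate windows")
    rmsecv, cols, n_lv = best
    surface = pd.DataFrame(rows)
    window_nm = None
    if wavelengths is not None:
        wavelengths = np.asarray(wavelengths)
        window_nm = (float(wavelengths[cols[0]]), float(wavelengths[cols[-1]]))
    return SelectionResult(method="window_search", indices=cols, rmsecv=rmsecv,
                           n_lv=n_lv, seed=cv.seed, window_nm=window_nm,
                           surface=surface)


# ---------------------------------------------------------------------------
# MC-UVE


def mc_uve(X, y, n_runs: int = 500, sample_fraction: float = 0.8,
           n_lv: int = 5, n_keep: Optional[int] = None,
           cv_spec: CVSpec | None = None, seed: int = 0) -> SelectionResult:
    """Coefficient-stability screening over random calibration subsets.

    ``stability_j = mean_j / std_j`` of the PLSR coefficient of variable
    j over ``n_runs`` subsample fits; the ``n_keep`` variables with the
    largest |stability| are kept (``n_keep`` chosen by CV over a
    candidate list when unset).
    """
    if n_runs < 50:
        raise ParameterError("n_runs must be >= 50")
    cv = cv_spec or CVSpec()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    m = max(2, int(round(sample_fraction * n)))
    rng = np.random.default_rng(seed)
    coefs = np.empty((n_runs, p))
    run = 0
    degenerate = 0
    while run < n_runs:
        idx = rng.choice(n, size=m, replace=False)
        ys = y[idx]
        if np.std(ys) == 0:
            degenerate += 1
            continue
        Xs = X[idx]
        a = min(n_lv, m - 1, p)
        x_mean = Xs.mean(axis=0)
        W, P, q = _nipals(Xs - x_mean, ys - ys.mean(), a)
        from .plsr_core import _coef_from_components

        coefs[run] = _coef_from_components(W, P, q, W.shape[1])
        run += 1
    if degenerate:
        logger.info("mc_uve: resampled %d degenerate subsets", degenerate)
    std = coefs.std(axis=0)
    std[std == 0] = np.inf
    stability = coefs.mean(axis=0) / std
    order = np.argsort(-np.abs(stability))
    if n_keep is None:
        candidates = sorted({c for c in (5, 10, 15, 20, 30, 45, 60, p) if c <= p})
        best = (np.inf, None)
        for c in candidates:
            cols = np.sort(order[:c])
            r, _ = _final_cv(X, y, cols, cv)
            if r < best[0]:
                best = (r, c)
        n_keep = best[1]
    if not (1 <= n_keep <= p):
        raise ParameterError(f"n_keep={n_keep} outside [1, {p}]")
    cols = np.sort(order[:n_keep])
    rmsecv, chosen_lv = _final_cv(X, y, cols, cv)
    return SelectionResult(method="mc_uve", indices=cols, rmsecv=rmsecv,
                           n_lv=chosen_lv, seed=seed, scores=stability)


# ---------------------------------------------------------------------------
# SPA


def _spa_chain(Xn: np.ndarray, start: int, k_max: int) -> List[int]:
    """Grow a chain of maximally y-free, minimally collinear columns."""
    n, p = Xn.shape
    R = Xn.copy()
    chain = [start]
    u = R[:, start] / np.linalg.norm(R[:, start])
    for _ in range(k_max - 1):
        R = R - np.outer(u, u @ R)  # project out the last chosen direction
        norms = np.linalg.norm(R, axis=0)
        norms[chain] = -1.0
        j = int(np.argmax(norms))
        if norms[j] < 1e-10:  # rank exhausted mid-chain
            logger.info("spa: chain from %d stopped early at length %d", start, len(chain))
            break
        chain.append(j)
        u = R[:, j] / norms[j]
    return chain


def spa(X, y, k_min: int = 2, k_max: int = 15, cv_spec: CVSpec | None = None,
        starts: Optional[Sequence[int]] = None) -> SelectionResult:
    """Successive projections algorithm.

    For every candidate start variable a chain is grown by repeatedly
    adding the column with the largest norm after orthogonal projection
    onto the complement of the chosen span; every (start, k) prefix is
    scored by PLSR RMSECV and the best is returned.
    """
    cv = cv_spec or CVSpec()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if k_max > min(n - 1, p):
        raise ParameterError(f"k_max={k_max} exceeds min(n-1, p)={min(n - 1, p)}")
    if k_min < 1 or k_min > k_max:
        raise ParameterError("need 1 <= k_min <= k_max")
    Xc = X - X.mean(axis=0)
    if starts is None:
        starts = range(p)
    folds = make_folds(n, cv.k, cv.seed)
    best = (np.inf, None)
    for s in starts:
        if np.linalg.norm(Xc[:, s]) < 1e-12:
            continue
        chain = _spa_chain(Xc, s, k_max)
        for k in range(k_min, min(k_max, len(chain)) + 1):
            cols = np.sort(chain[:k])
            r = _subset_rmsecv(X, y, cols, folds, n_lv=min(cv.max_lv, k))
            if r < best[0]:
                best = (r, cols)
    if best[1] is None:
        raise FitError("SPA found no usable chain")
    cols = best[1]
    rmsecv, n_lv = _final_cv(X, y, cols, cv)
    return SelectionResult(method="spa", indices=cols, rmsecv=rmsecv, n_lv=n_lv,
                           seed=cv.seed)


# ---------------------------------------------------------------------------
# VCPA


def _edf_schedule(p: int, final_max: int, rounds: int) -> np.ndarray:
    """Exponentially decreasing retention counts: p at round 0, final_max last."""
    i = np.arange(rounds + 1)
    r = p * (final_max / p) ** (i / rounds)
    return np.maximum(final_max, np.round(r).astype(int))


def vcpa(X, y, n_bms: int = 1000, edf_rounds: int = 50, top_fraction: float = 0.1,
         final_max: int = 14, cv_spec: CVSpec | None = None, seed: int = 0,
         n_lv: Optional[int] = None) -> SelectionResult:
    """Variable combination population analysis.

    Each round draws ``n_bms`` random binary inclusion vectors over the
    surviving variables, scores every subset by RMSECV, and keeps the
    variables most frequent among the best ``top_fraction`` of subsets,
    shrinking the pool along an exponential schedule down to
    ``final_max``.  The final stage evaluates every combination of the
    survivors exhaustively.
    """
    cv = cv_spec or CVSpec()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if p < 20:
        raise ParameterError("VCPA expects p >= 20")
    if final_max > 20:
        raise ParameterError("final_max > 20 would make the exhaustive stage combinatorial")
    rng = np.random.default_rng(seed)
    if n_lv is None:
        n_lv = cross_validate(X, y, max_lv=cv.max_lv, k=cv.k, seed=cv.seed).n_lv
    schedule = _edf_schedule(p, final_max, edf_rounds)
    survivors = np.arange(p)
    for rnd in range(1, edf_rounds + 1):
        target = int(schedule[rnd])
        if len(survivors) <= target:
            continue
        folds = make_folds(n, cv.k, int(rng.integers(2**31)))
        masks = rng.random((n_bms, len(survivors))) < 0.5
        empty = ~masks.any(axis=1)
        masks[empty, rng.integers(0, len(survivors), size=int(empty.sum()))] = True
        errs = np.empty(n_bms)
        for b in range(n_bms):
            cols = survivors[masks[b]]
            errs[b] = _subset_rmsecv(X, y, cols, folds, n_lv)
        n_top = max(1, int(round(top_fraction * n_bms)))
        top = np.argsort(errs)[:n_top]
        freq = masks[top].sum(axis=0)
        keep = np.argsort(-freq)[:target]
        survivors = np.sort(survivors[keep])
    # exhaustive final stage over the small survivor pool
    folds = make_folds(n, cv.k, cv.seed)
    best = (np.inf, None)
    for r in range(1, len(survivors) + 1):
        for combo in itertools.combinations(survivors, r):
            cols = np.asarray(combo)
            e = _subset_rmsecv(X, y, cols, folds, min(n_lv, len(cols)))
            if e < best[0]:
                best = (e, cols)
    cols = best[1]
    rmsecv, chosen_lv = _final_cv(X, y, cols, cv)
    return SelectionResult(method="vcpa", indices=cols, rmsecv=rmsecv,
                           n_lv=chosen_lv, seed=seed, final_pool=survivors)


# ---------------------------------------------------------------------------
# IRIV


def iriv(X, y, n_bms: int = 500, alpha: float = 0.05,
         cv_spec: CVSpec | None = None, seed: int = 0,
         n_lv: Optional[int] = None, max_rounds: int = 20) -> SelectionResult:
    """Iteratively retaining informative variables.

    Per round a binary inclusion matrix is sampled; for each variable
    the RMSECV of subsets that include it is compared with subsets that
    exclude it.  Variables whose inclusion raises the mean RMSECV
    (uninformative or interfering; a Mann-Whitney test at ``alpha``
    separates the two labels) are dropped.  Rounds repeat until stable,
    then backward elimination polishes the survivors.
    """
    cv = cv_spec or CVSpec()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if p < 10:
        raise ParameterError("IRIV expects p >= 10")
    rng = np.random.default_rng(seed)
    if n_lv is None:
        n_lv = cross_validate(X, y, max_lv=cv.max_lv, k=cv.k, seed=cv.seed).n_lv
    survivors = np.arange(p)
    for rnd in range(max_rounds):
        ps = len(survivors)
        if ps <= 2:
            break
        folds = make_folds(n, cv.k, int(rng.integers(2**31)))
        masks = rng.random((n_bms, ps)) < 0.5
        empty = ~masks.any(axis=1)
        masks[empty, rng.integers(0, ps, size=int(empty.sum()))] = True
        errs = np.empty(n_bms)
        for b in range(n_bms):
            errs[b] = _subset_rmsecv(X, y, survivors[masks[b]], folds, n_lv)
        keep = np.ones(ps, dtype=bool)
        n_strong = n_weak = 0
        for j in range(ps):
            incl = errs[masks[:, j]]
            excl = errs[~masks[:, j]]
            if incl.size == 0 or excl.size == 0:
                continue
            dmean = float(excl.mean() - incl.mean())  # > 0: inclusion helps
            pval = mannwhitneyu(incl, excl, alternative="two-sided").pvalue
            if dmean <= 0:  # uninformative (p >= alpha) or interfering (p < alpha)
                keep[j] = False
            elif pval < alpha:
                n_strong += 1
            else:
                n_weak += 1
        logger.debug("iriv round %d: %d strong, %d weak, dropping %d of %d",
                     rnd + 1, n_strong, n_weak, int((~keep).sum()), ps)
        if keep.all():
            break
        if not keep.any():
            raise FitError("IRIV dropped every variable; consider a larger alpha")
        survivors = survivors[keep]
    # backward elimination on survivors
    folds = make_folds(n, cv.k, cv.seed)
    current = list(survivors)
    best_err = _subset_rmsecv(X, y, np.asarray(current), folds,
                              min(n_lv, len(current)))
    improved = True
    while improved and len(current) > 1:
        improved = False
        for j in list(current):
            trial = [c for c in current if c != j]
            e = _subset_rmsecv(X, y, np.asarray(trial), folds, min(n_lv, len(trial)))
            if e < best_err:
                best_err, current, improved = e, trial, True
                break
    cols = np.sort(np.asarray(current))
    rmsecv, chosen_lv = _final_cv(X, y, cols, cv)
    return SelectionResult(method="iriv", indices=cols, rmsecv=rmsecv,
                           n_lv=chosen_lv, seed=seed)
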