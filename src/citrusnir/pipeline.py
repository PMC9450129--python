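"""Config-driven orchestration of the full calibration workflow.

The experimental design mirrors a two-variety portable-NIRS study:
populations are assigned roles (calibration, internal validation,
update, prediction), a grid of pretreatment chains × selection methods
× update methods is executed, and table-style reports are emitted.
Preprocessing and model states are always fitted on calibration-role
data only; the sole exception is MU, whose semantics are a refit on the
augmented calibration.

Role presets follow the study design: calibration P1-4, internal
validation P5 (update standards from P6), and three external splits —
update {7,8} → predict {9-12}, update {9,12} → predict {7,8,10,11},
and the deliberately non-covering "negative" split update {9,10} →
predict {7,8,11,12}.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml

from .errors import CitrusNIRError, ParameterError
from .model_update import (
    UpdateCorrection,
    coverage_index,
    dop_apply,
    dop_fit,
    model_update_mu,
    osc_apply,
    osc_fit,
    pca_scores,
    sbc_apply,
    sbc_fit,
)
from .plsr_core import CVSpec, cross_validate, evaluate, fit_plsr, predict
from .preprocessing import apply_chain, fit_chain
from .spectra_io import AnalysisSet, read_reference, read_spectra, join
from . import variable_selection as vs

logger = logging.getLogger(__name__)

# role presets for the two-variety design
INTERNAL_SPLIT = {"name": "internal", "update": ["6"], "prediction": ["5"], "n_standards": 40}
EXTERNAL_SPLITS = [
    {"name": "external_1", "update": ["7", "8"], "prediction": ["9", "10", "11", "12"],
     "n_standards": 30},
    {"name": "external_2", "update": ["9", "12"], "prediction": ["7", "8", "10", "11"],
     "n_standards": 30},
    {"name": "external_negative", "update": ["9", "10"], "prediction": ["7", "8", "11", "12"],
     "n_standards": 30},
]
DEFAULT_CALIBRATION = ["1", "2", "3", "4"]


@dataclass
class ExperimentConfig:
    spectra_path: Optional[str] = None
    reference_path: Optional[str] = None
    calibration: List[str] = field(default_factory=lambda: list(DEFAULT_CALIBRATION))
    internal_validation: List[str] = field(default_factory=lambda: ["5"])
    splits: List[dict] = field(default_factory=lambda: [INTERNAL_SPLIT] + EXTERNAL_SPLITS)
    chains: List[str] = field(default_factory=lambda: ["2D", "2D+SNV", "2D+MSC",
                                                       "2D+VSN", "2D+NSR"])
    selection_methods: List[str] = field(default_factory=list)
    update_methods: List[str] = field(default_factory=lambda: ["None", "MU", "SBC",
                                                               "OSC", "DOP"])
    update_chain: str = "2D"
    attributes: List[str] = field(default_factory=lambda: ["ssc"])
    cv: CVSpec = field(default_factory=CVSpec)
    seed: int = 0
    output_dir: str = "results"

    def __post_init__(self):
        roles = [set(self.calibration), set(self.internal_validation)]
        for a, b in zip(roles, roles[1:]):
            if a & b:
                raise ParameterError(f"roles overlap: {a & b}")
        if not self.calibration:
            raise ParameterError("calibration role must be nonempty")


def load_config(path) -> ExperimentConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    cv = CVSpec(**raw.pop("cv", {}))
    return ExperimentConfig(cv=cv, **raw)


def load_data(config: ExperimentConfig) -> AnalysisSet:
    spectra = read_spectra(config.spectra_path)
    ref = read_reference(config.reference_path)
    return join(spectra, ref, allow_partial=True)


# ---------------------------------------------------------------------------
# report helpers


def _metrics(prefix: str, rep) -> dict:
    return {f"{prefix}_r2": rep.r2, f"{prefix}_rmse": rep.rmse,
            f"{prefix}_bias": rep.bias, f"{prefix}_rpd": rep.rpd}


def render_report(df: pd.DataFrame) -> str:
    """Markdown rendering at table precision: 2 decimals, 4 for bias."""
    out = df.copy()
    for c in out.columns:
        if c.endswith("_bias"):
            out[c] = out[c].map(lambda v: f"{v:.4f}")
        elif out[c].dtype.kind == "f":
            out[c] = out[c].map(lambda v: f"{v:.2f}")
    return out.to_markdown(index=False)


# ---------------------------------------------------------------------------
# stage 1: pretreatment comparison


def pretreatment_experiment(data: AnalysisSet, calibration_pops: Sequence[str],
                            prediction_pops: Sequence[str], chains: Sequence[str],
                            attribute: str = "ssc",
                            cv: CVSpec | None = None) -> pd.DataFrame:
    """One report row per pretreatment chain: CV on calibration populations,
    external prediction on the held-out population."""
    cv = cv or CVSpec()
    cal = data.by_population(calibration_pops)
    prd = data.by_population(prediction_pops)
    if attribute == "ta":  # populations without TA reference are unusable
        cal = cal.subset(~np.isnan(cal.y("ta")))
        prd = prd.subset(~np.isnan(prd.y("ta")))
    rows = []
    for chain in chains or ["none"]:
        try:
            rows.append(_pretreatment_row(cal, prd, chain, attribute, cv))
        except CitrusNIRError as exc:
            logger.error("chain %s failed: %s", chain, exc)
            rows.append({"attribute": attribute, "pretreatment": chain,
                         "status": f"failed: {exc}"})
    return pd.DataFrame(rows)


def _pretreatment_row(cal: AnalysisSet, prd: AnalysisSet, chain: str,
                      attribute: str, cv: CVSpec) -> dict:
    state = fit_chain(chain, cal, cv_spec=cv, attribute=attribute)
    Xc = apply_chain(state, cal.spectra).absorbance
    yc = cal.y(attribute)
    res = cross_validate(Xc, yc, max_lv=cv.max_lv, k=cv.k, seed=cv.seed)
    model = fit_plsr(Xc, yc, res.n_lv)
    cal_rep = evaluate(res.y_cv, yc)
    Xp = apply_chain(state, prd.spectra).absorbance
    prd_rep = evaluate(predict(model, Xp), prd.y(attribute))
    return {"attribute": attribute, "pretreatment": chain or "none",
            "variables": Xc.shape[1], "n_lv": res.n_lv, "seed": cv.seed,
            "status": "ok", **_metrics("cal", cal_rep), **_metrics("pred", prd_rep)}


# ---------------------------------------------------------------------------
# stage 2: variable selection


def selection_experiment(data: AnalysisSet, calibration_pops: Sequence[str],
                         prediction_pops: Sequence[str], methods: Sequence[str],
                         chain: str = "2D", attribute: str = "ssc",
                         cv: CVSpec | None = None, seed: int = 0,
                         method_kwargs: Optional[dict] = None) -> pd.DataFrame:
    """One row per selection method applied after ``chain`` pretreatment."""
    cv = cv or CVSpec()
    kw = method_kwargs or {}
    cal = data.by_population(calibration_pops)
    prd = data.by_population(prediction_pops)
    state = fit_chain(chain, cal, cv_spec=cv, attribute=attribute)
    Xc = apply_chain(state, cal.spectra).absorbance
    yc = cal.y(attribute)
    Xp = apply_chain(state, prd.spectra).absorbance
    yp = prd.y(attribute)
    wavelengths = cal.spectra.grid.values
    rows = []
    for method in methods:
        try:
            sel = run_selection(method, Xc, yc, wavelengths=wavelengths, cv=cv,
                                seed=seed, **kw.get(method, {}))
            cols = sel.indices
            model = fit_plsr(Xc[:, cols], yc, sel.n_lv)
            res = cross_validate(Xc[:, cols], yc, max_lv=min(cv.max_lv, len(cols)),
                                 k=cv.k, seed=cv.seed)
            cal_rep = evaluate(res.y_cv, yc)
            prd_rep = evaluate(predict(model, Xp[:, cols]), yp)
            rows.append({"attribute": attribute, "pretreatment": chain,
                         "method": method, "variables": len(cols),
                         "n_lv": sel.n_lv, "seed": seed, "status": "ok",
                         **_metrics("cal", cal_rep), **_metrics("pred", prd_rep)})
        except CitrusNIRError as exc:
            logger.error("selection %s failed: %s", method, exc)
            rows.append({"attribute": attribute, "pretreatment": chain,
                         "method": method, "status": f"failed: {exc}"})
    return pd.DataFrame(rows)


def run_selection(method: str, X, y, wavelengths=None, cv: CVSpec | None = None,
                  seed: int = 0, **kwargs) -> vs.SelectionResult:
    cv = cv or CVSpec()
    m = method.lower().replace("-", "_").replace(" ", "_")
    if m == "window_search":
        return vs.window_search(X, y, wavelengths=wavelengths, cv_spec=cv, **kwargs)
    if m == "mc_uve":
        return vs.mc_uve(X, y, cv_spec=cv, seed=seed, **kwargs)
    if m == "spa":
        return vs.spa(X, y, cv_spec=cv, **kwargs)
    if m == "vcpa":
        return vs.vcpa(X, y, cv_spec=cv, seed=seed, **kwargs)
    if m == "iriv":
        return vs.iriv(X, y, cv_spec=cv, seed=seed, **kwargs)
    if m in ("previous_report", "window_700_930"):
        # convenience preset: the 700-930 nm interval recommended for this
        # instrument class in earlier pear work
        if wavelengths is None:
            raise ParameterError("preset window needs the wavelength axis")
        cols = np.flatnonzero((wavelengths >= 700) & (wavelengths <= 930))
        res = cross_validate(np.asarray(X)[:, cols], y,
                             max_lv=min(cv.max_lv, len(cols)), k=cv.k, seed=cv.seed)
        return vs.SelectionResult(method="previous_report", indices=cols,
                                  rmsecv=float(res.rmsecv[res.n_lv - 1]),
                                  n_lv=res.n_lv, seed=cv.seed)
    raise ParameterError(f"unknown selection method {method!r}")


# ---------------------------------------------------------------------------
# stage 3: model update


def select_standards(data: AnalysisSet, populations: Sequence[str],
                     n_fruit: int, seed: int = 0) -> AnalysisSet:
    """Random ``n_fruit`` standards (all replicates) from the given populations."""
    pool = data.by_population(populations)
    fruits = pool.spectra.meta["fruit_id"].unique()
    rng = np.random.default_rng(seed)
    if n_fruit >= len(fruits):
        chosen = set(fruits)
    else:
        chosen = set(rng.choice(fruits, size=n_fruit, replace=False))
    return pool.subset(pool.spectra.meta["fruit_id"].isin(chosen).to_numpy())


def run_update_method(method: str, calibration: AnalysisSet, update_set: AnalysisSet,
                      prediction_set: AnalysisSet, chain_spec: str = "2D",
                      n_lv: Optional[int] = None, cv: CVSpec | None = None,
                      attribute: str = "ssc", n_osc: int = 1,
                      K_range: Sequence[int] = range(1, 21)) -> dict:
    """Apply one maintenance method and evaluate on the prediction set.

    Returns calibration (cross-validation) and prediction metrics plus
    the fitted correction, in one dict.
    """
    cv = cv or CVSpec()
    state = fit_chain(chain_spec, calibration, cv_spec=cv, attribute=attribute)
    Xc = apply_chain(state, calibration.spectra).absorbance
    yc = calibration.y(attribute)
    base_cv = cross_validate(Xc, yc, max_lv=cv.max_lv, k=cv.k, seed=cv.seed)
    if n_lv is None:
        n_lv = base_cv.n_lv
    base_model = fit_plsr(Xc, yc, n_lv)
    Xp = apply_chain(state, prediction_set.spectra).absorbance
    yp = prediction_set.y(attribute)
    correction: Optional[UpdateCorrection] = None
    method_u = method.upper() if method else "NONE"

    if method_u in ("NONE", ""):
        cal_rep = evaluate(base_cv.y_cv, yc)
        y_hat = predict(base_model, Xp)
        params = f"LVs={n_lv}"
    elif method_u == "MU":
        model, state2 = model_update_mu(calibration, update_set, chain_spec,
                                        n_lv, attribute=attribute, cv_spec=cv)
        from .model_update import concat_analysis_sets
        union = concat_analysis_sets([calibration, update_set])
        Xu = apply_chain(state2, union.spectra).absorbance
        res = cross_validate(Xu, union.y(attribute), max_lv=cv.max_lv,
                             k=cv.k, seed=cv.seed)
        cal_rep = evaluate(res.y_cv, union.y(attribute))
        y_hat = predict(model, apply_chain(state2, prediction_set.spectra).absorbance)
        params = f"LVs={n_lv}"
    elif method_u == "SBC":
        correction = sbc_fit(base_model, update_set, state, attribute=attribute)
        cal_rep = evaluate(base_cv.y_cv, yc)  # SBC leaves calibration untouched
        y_hat = sbc_apply(correction, predict(base_model, Xp))
        params = f"LVs={n_lv}"
    elif method_u == "OSC":
        correction = osc_fit(Xc, yc, n_osc=n_osc)
        Xc_corr = osc_apply(correction, Xc)
        res = cross_validate(Xc_corr, yc, max_lv=cv.max_lv, k=cv.k, seed=cv.seed)
        model = fit_plsr(Xc_corr, yc, res.n_lv)  # OSC re-selects LVs by CV
        cal_rep = evaluate(res.y_cv, yc)
        y_hat = predict(model, osc_apply(correction, Xp))
        params = f"LVs={res.n_lv}, n_osc={n_osc}"
    elif method_u == "DOP":
        correction, model = dop_fit(calibration, update_set, state, n_lv,
                                    K_range=K_range, attribute=attribute)
        Xc_proj = dop_apply(correction, Xc)
        res = cross_validate(Xc_proj, yc, max_lv=cv.max_lv, k=cv.k, seed=cv.seed)
        cal_rep = evaluate(res.y_cv, yc)
        y_hat = predict(model, dop_apply(correction, Xp))
        params = f"LVs={n_lv}, K={correction.K}"
    else:
        raise ParameterError(f"unknown update method {method!r}")

    pred_rep = evaluate(y_hat, yp)
    return {"method": method_u, "params": params, "cal_report": cal_rep,
            "pred_report": pred_rep, "correction": correction,
            "n_lv": n_lv, "chain": chain_spec, "y_hat": y_hat}


def update_experiment(data: AnalysisSet, calibration_pops: Sequence[str] = None,
                      splits: Sequence[dict] = None, methods: Sequence[str] = None,
                      chain_spec: str = "2D", cv: CVSpec | None = None,
                      attribute: str = "ssc", seed: int = 0,
                      n_lv: Optional[int] = None) -> pd.DataFrame:
    """Maintenance-method grid over validation splits, with coverage diagnostics."""
    cv = cv or CVSpec()
    calibration_pops = calibration_pops or DEFAULT_CALIBRATION
    splits = splits if splits is not None else [INTERNAL_SPLIT] + EXTERNAL_SPLITS
    methods = methods or ["None", "MU", "SBC", "OSC", "DOP"]
    cal = data.by_population(calibration_pops)
    # shared 2D score space for coverage diagnostics (fitted on all spectra)
    state = fit_chain(chain_spec, cal, cv_spec=cv, attribute=attribute)
    X_all = apply_chain(state, data.spectra).absorbance
    rows = []
    for split in splits:
        upd = select_standards(data, split["update"], split.get("n_standards", 30),
                               seed=seed)
        prd = data.by_population(split["prediction"])
        upd_scores = pca_scores(apply_chain(state, upd.spectra).absorbance,
                                n_components=2, fit_on=X_all)
        prd_scores = pca_scores(apply_chain(state, prd.spectra).absorbance,
                                n_components=2, fit_on=X_all)
        cov = coverage_index(upd_scores, prd_scores)
        for method in methods:
            try:
                out = run_update_method(method, cal, upd, prd, chain_spec=chain_spec,
                                        n_lv=n_lv, cv=cv, attribute=attribute)
                row = {"split": split["name"], "method": out["method"],
                       "params": out["params"],
                       "update_pops": "+".join(split["update"]),
                       "prediction_pops": "+".join(split["prediction"]),
                       "coverage": cov, "seed": seed, "status": "ok",
                       **_metrics("cal", out["cal_report"]),
                       **_metrics("pred", out["pred_report"])}
            except CitrusNIRError as exc:
                logger.error("update %s on %s failed: %s", method, split["name"], exc)
                row = {"split": split["name"], "method": method,
                       "status": f"failed: {exc}"}
            rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# top-level driver + figures


def run_experiment(config: ExperimentConfig, data: AnalysisSet | None = None) -> Dict[str, pd.DataFrame]:
    """Execute the configured stages and write CSV + markdown reports."""
    if data is None:
        data = load_data(config)
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    reports: Dict[str, pd.DataFrame] = {}
    pred_pops = config.internal_validation
    if config.chains:
        frames = [pretreatment_experiment(data, config.calibration, pred_pops,
                                          config.chains, attribute=a, cv=config.cv)
                  for a in config.attributes]
        reports["pretreatment"] = pd.concat(frames, ignore_index=True)
    if config.selection_methods:
        reports["selection"] = selection_experiment(
            data, config.calibration, pred_pops, config.selection_methods,
            chain=config.update_chain, cv=config.cv, seed=config.seed)
    if config.update_methods:
        reports["update"] = update_experiment(
            data, config.calibration, config.splits, config.update_methods,
            chain_spec=config.update_chain, cv=config.cv, seed=config.seed)
    for name, df in reports.items():
        df.to_csv(outdir / f"report_{name}.csv", index=False)
        (outdir / f"report_{name}.md").write_text(render_report(df))
        logger.info("wrote %s report (%d rows)", name, len(df))
    return reports


def make_figures(outdir, surface: pd.DataFrame | None = None,
                 scores: pd.DataFrame | None = None,
                 predictions: pd.DataFrame | None = None) -> List[Path]:
    """Render the standard diagnostic figures from report tables.

    ``surface``: window-search RMSECV surface (start, width, rmsecv).
    ``scores``: PCA scores with a ``population`` column.
    ``predictions``: measured/predicted pairs with optional annotation.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    if surface is not None:
        for col in ("start", "width", "rmsecv"):
            if col not in surface.columns:
                raise ParameterError(f"surface table missing column {col!r}")
        fig, ax = plt.subplots(figsize=(7, 4))
        for width, grp in surface.groupby("width"):
            ax.plot(grp["start"], grp["rmsecv"], label=f"width {width}")
        ax.set_xlabel("window start (variable index)")
        ax.set_ylabel("RMSECV")
        ax.legend(fontsize=6, ncol=3)
        path = outdir / "window_search_surface.png"
        fig.savefig(path, dpi=120)
        plt.close(fig)
        written.append(path)
    if scores is not None:
        for col in ("pc1", "pc2", "population"):
            if col not in scores.columns:
                raise ParameterError(f"scores table missing column {col!r}")
        fig, ax = plt.subplots(figsize=(5, 5))
        for pop, grp in scores.groupby("population"):
            ax.scatter(grp["pc1"], grp["pc2"], s=8, label=f"P{pop}")
        ax.set_xlabel("PC1")
        ax.set_ylabel("PC2")
        ax.legend(fontsize=6, ncol=2)
        path = outdir / "pca_scores.png"
        fig.savefig(path, dpi=120)
        plt.close(fig)
        written.append(path)
    if predictions is not None:
        for col in ("measured", "predicted"):
            if col not in predictions.columns:
                raise ParameterError(f"predictions table missing column {col!r}")
        rep = evaluate(predictions["predicted"], predictions["measured"])
        fig, ax = plt.subplots(figsize=(5, 5))
        ax.scatter(predictions["measured"], predictions["predicted"], s=10)
        lims = [predictions["measured"].min(), predictions["measured"].max()]
        ax.plot(lims, lims, "k--", lw=1)
        ax.annotate(f"$R_p^2$={rep.r2:.2f}\nRMSEP={rep.rmse:.2f}\nRPD={rep.rpd:.2f}",
                    xy=(0.05, 0.8), xycoords="axes fraction")
        ax.set_xlabel("measured")
        ax.set_ylabel("predicted")
        path = outdir / "predicted_vs_measured.png"
        fig.savefig(path, dpi=120)
        plt.close(fig)
        written.append(path)
    return written
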