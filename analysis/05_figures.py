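"""Diagnostic figures: window-search RMSECV surface, PCA score plot of the
two varieties, and predicted-vs-measured for the SBC-updated model."""

from pathlib import Path

import pandas as pd

from citrusnir import pipeline as pl
from citrusnir.model_update import pca_scores
from citrusnir.plsr_core import CVSpec
from citrusnir.preprocessing import apply_chain, fit_chain
from citrusnir.spectra_io import join, read_reference, read_spectra

ROOT = Path(__file__).resolve().parent.parent / "results"


def main():
    data = join(read_spectra(ROOT / "data" / "spectra.csv"),
                read_reference(ROOT / "data" / "reference.csv"), allow_partial=True)
    figdir = ROOT / "figures"

    surface = None
    surface_path = ROOT / "window_search_surface.csv"
    if surface_path.exists():
        surface = pd.read_csv(surface_path)

    # PCA of 2D spectra, the space in which batch coverage is judged
    cal = data.by_population(["1", "2", "3", "4"])
    state = fit_chain("2D", cal, cv_spec=CVSpec())
    X2d = apply_chain(state, data.spectra).absorbance
    sc = pca_scores(X2d, n_components=2)
    scores = pd.DataFrame({"pc1": sc[:, 0], "pc2": sc[:, 1],
                           "population": data.spectra.meta["population_id"]})

    # predicted vs measured: SBC with covering standards (update P7-8)
    upd = pl.select_standards(data, ["7", "8"], n_fruit=30, seed=0)
    prd = data.by_population(["9", "10", "11", "12"])
    out = pl.run_update_method("SBC", cal, upd, prd, chain_spec="2D",
                               cv=CVSpec(k=5, seed=0, max_lv=12))
    preds = pd.DataFrame({"measured": prd.y("ssc"), "predicted": out["y_hat"]})

    written = pl.make_figures(figdir, surface=surface, scores=scores,
                              predictions=preds)
    rep = out["pred_report"]
    print(f"SBC on covering standards: RMSEP {rep.rmse:.2f} °Brix, "
          f"R2p {rep.r2:.2f}, RPD {rep.rpd:.2f}")
    for path in written:
        print(f"wrote {path}")


if __name__ == "__main__":
    main()
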