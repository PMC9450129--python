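"""Mechanism tests for the four maintenance methods and coverage diagnostics."""

import numpy as np
import pytest

from citrusnir import model_update as mu
from citrusnir import synthetic_data as sd
from citrusnir.errors import CitrusNIRError, ParameterError, ValidationError
from citrusnir.plsr_core import CVSpec, cross_validate, evaluate, fit_plsr, predict
from citrusnir.preprocessing import fit_chain
from citrusnir.spectra_io import AnalysisSet, ReferenceTable

from conftest import make_analysis


def _calibration(rng, n=50, p=40):
    X = rng.normal(size=(n, p)) + np.linspace(1, 2, p)
    beta = np.zeros(p)
    beta[5:10] = 0.5
    y = 12 + X @ beta + 0.1 * rng.normal(size=n)
    return make_analysis(X, y)


class TestMU:
    def test_empty_update_set_is_noop(self, rng):
        cal = _calibration(rng)
        empty = cal.subset(np.zeros(cal.n, dtype=bool))
        model, _ = mu.model_update_mu(cal, empty, "none", n_lv=4)
        base = fit_plsr(cal.X, cal.y("ssc"), 4)
        np.testing.assert_allclose(model.coef, base.coef, atol=1e-10)
        assert model.intercept == pytest.approx(base.intercept, abs=1e-10)

    def test_same_distribution_update_is_stable(self, rng):
        # augmenting a well-determined model with same-distribution samples
        # must not shift held-out RMSE appreciably
        rmses = {"base": [], "updated": []}
        for seed in range(10):
            r = np.random.default_rng(seed)
            cal = _calibration(r, n=150, p=20)
            extra = _calibration(r, n=30, p=20)
            extra = AnalysisSet(
                extra.spectra.with_absorbance(extra.X),
                extra.reference)
            extra.spectra.meta["spectrum_id"] = [f"U{i}" for i in range(extra.n)]
            extra.reference.table["spectrum_id"] = extra.spectra.meta["spectrum_id"]
            holdout = _calibration(r, n=50, p=20)
            base = fit_plsr(cal.X, cal.y("ssc"), 6)
            model, _ = mu.model_update_mu(cal, extra, "none", n_lv=6)
            rmses["base"].append(evaluate(predict(base, holdout.X),
                                          holdout.y("ssc")).rmse)
            rmses["updated"].append(evaluate(predict(model, holdout.X),
                                             holdout.y("ssc")).rmse)
        base_m, upd_m = np.mean(rmses["base"]), np.mean(rmses["updated"])
        assert abs(upd_m - base_m) / base_m < 0.10

    def test_overlapping_ids_rejected(self, rng):
        cal = _calibration(rng)
        with pytest.raises(ValidationError):
            mu.model_update_mu(cal, cal.subset(np.arange(3)), "none", n_lv=3)


class TestSBC:
    def test_exact_affine_inverse(self, rng):
        cal = _calibration(rng)
        model = fit_plsr(cal.X, cal.y("ssc"), 4)
        alpha, beta = 1.8, -2.5
        upd = _calibration(rng, n=20)
        # distort references so predictions satisfy y_hat = (y - beta)/alpha
        y_hat = predict(model, upd.X)
        distorted = ReferenceTable(upd.reference.table.assign(
            ssc=alpha * y_hat + beta))
        upd = AnalysisSet(upd.spectra, distorted)
        state = fit_chain("none", cal)
        corr = mu.sbc_fit(model, upd, state)
        corrected = mu.sbc_apply(corr, predict(model, upd.X))
        np.testing.assert_allclose(corrected, upd.y("ssc"), atol=1e-10)

    def test_unbiased_predictions_give_identity_correction(self, rng):
        cal = _calibration(rng, n=200)
        model = fit_plsr(cal.X, cal.y("ssc"), 6)
        upd = _calibration(rng, n=100)
        state = fit_chain("none", cal)
        corr = mu.sbc_fit(model, upd, state)
        assert corr.slope == pytest.approx(1.0, abs=0.15)
        assert corr.bias == pytest.approx(0.0, abs=12 * 0.15)

    def test_needs_three_samples_and_prediction_variance(self, rng):
        cal = _calibration(rng)
        model = fit_plsr(cal.X, cal.y("ssc"), 3)
        state = fit_chain("none", cal)
        with pytest.raises(ParameterError):
            mu.sbc_fit(model, cal.subset(np.arange(2)), state)


class TestOSC:
    def test_removed_scores_orthogonal_to_response(self, rng):
        cal = _calibration(rng)
        y = cal.y("ssc")
        corr = mu.osc_fit(cal.X, y, n_osc=2)
        yc = y - y.mean()
        for comp in range(2):
            t = corr.osc_scores[:, comp]
            assert abs(np.corrcoef(t, yc)[0, 1]) <= 1e-8

    def test_y_aligned_principal_direction_leaves_nothing_to_remove(self, rng):
        # X rank 2: dominant component IS the response, second is tiny
        n, p = 40, 20
        t1 = rng.normal(size=n) * 10
        t2 = rng.normal(size=n) * 0.1
        p1, p2 = rng.normal(size=p), rng.normal(size=p)
        X = np.outer(t1, p1) + np.outer(t2, p2)
        y = t1 + 100
        corr = mu.osc_fit(X, y, n_osc=1)
        removed_var = np.sum((X - X.mean(0) - (mu.osc_apply(corr, X) - X.mean(0))) ** 2)
        total_var = np.sum((X - X.mean(0)) ** 2)
        assert removed_var / total_var < 0.01

    def test_removing_structured_interferent_restores_fit(self, rng):
        # low-rank spectra (as NIR data are) plus a strong y-orthogonal
        # structured interferent; one OSC component must restore the fit
        n, p, r = 60, 40, 6
        T = rng.normal(size=(n, r))
        X = T @ rng.normal(size=(p, r)).T + 0.05 * rng.normal(size=(n, p))
        y = 12 + T[:, 0] + 0.5 * T[:, 1] + 0.05 * rng.normal(size=n)
        yc = y - y.mean()
        clean_rmse = evaluate(predict(fit_plsr(X, y, 3), X), y).rmse
        direction = rng.normal(size=p)
        direction /= np.linalg.norm(direction)
        s = 8.0 * rng.normal(size=n)
        s -= yc * (yc @ s) / (yc @ yc)
        X_dirty = X + np.outer(s, direction)
        corr = mu.osc_fit(X_dirty, y, n_osc=1)
        X_corr = mu.osc_apply(corr, X_dirty)
        osc_rmse = evaluate(predict(fit_plsr(X_corr, y, 3), X_corr), y).rmse
        assert osc_rmse <= 1.1 * clean_rmse


class TestDOP:
    def test_single_direction_annihilated(self, rng):
        cal = _calibration(rng)
        d = rng.normal(size=cal.X.shape[1])
        d /= np.linalg.norm(d)
        alpha = 0.7
        upd = AnalysisSet(cal.spectra.with_absorbance(cal.X + alpha * d),
                          cal.reference)
        upd.spectra.meta["spectrum_id"] = [f"U{i}" for i in range(upd.n)]
        upd.reference.table["spectrum_id"] = upd.spectra.meta["spectrum_id"]
        state = fit_chain("none", cal)
        corr, _ = mu.dop_fit(cal, upd, state, n_lv=3, K_range=[1])
        v1 = corr.basis[:, 0]
        assert abs(abs(v1 @ d) - 1.0) < 1e-8
        x = rng.normal(size=cal.X.shape[1])
        np.testing.assert_allclose(mu.dop_apply(corr, x + alpha * d),
                                   mu.dop_apply(corr, x), atol=1e-8)

    def test_projector_idempotent_symmetric_contractive(self, rng):
        V, _ = np.linalg.qr(rng.normal(size=(30, 3)))
        corr = mu.UpdateCorrection(kind="DOP", basis=V, K=3)
        P = np.eye(30) - V @ V.T
        np.testing.assert_allclose(P @ P, P, atol=1e-10)
        np.testing.assert_allclose(P.T, P, atol=1e-10)
        for _ in range(5):
            x = rng.normal(size=30)
            assert np.linalg.norm(mu.dop_apply(corr, x)) <= np.linalg.norm(x) + 1e-12

    def test_two_dimensional_variety_shift_recovered(self):
        # planted 2-dim interference subspace on low-rank spectra: chosen K
        # stays small and the prediction RPD improves over no update
        def low_rank_batch(rng, n, p, b_y, Bf):
            y = 12 + rng.normal(size=n)
            X = (np.outer(y - 12, b_y) + 0.3 * rng.normal(size=(n, 2)) @ Bf.T
                 + 0.02 * rng.normal(size=(n, p)))
            return make_analysis(X, y)

        improved, small_k = 0, 0
        n_seeds = 10
        for seed in range(n_seeds):
            rng = np.random.default_rng(100 + seed)
            p = 40
            b_y = rng.normal(size=p)
            Bf = rng.normal(size=(p, 2))
            cal = low_rank_batch(rng, 60, p, b_y, Bf)
            d1 = rng.normal(size=p)
            d1 /= np.linalg.norm(d1)
            d2 = rng.normal(size=p)
            d2 -= d1 * (d1 @ d2)
            d2 /= np.linalg.norm(d2)
            shift = (np.outer(rng.normal(1.0, 0.3, size=60), d1)
                     + np.outer(rng.normal(0.5, 0.3, size=60), d2))
            new = low_rank_batch(rng, 60, p, b_y, Bf)
            new = AnalysisSet(new.spectra.with_absorbance(new.X + shift),
                              new.reference)
            upd, prd = new.subset(np.arange(20)), new.subset(np.arange(20, 60))
            state = fit_chain("none", cal)
            base = fit_plsr(cal.X, cal.y("ssc"), 4)
            rpd_none = evaluate(predict(base, prd.X), prd.y("ssc")).rpd
            corr, model = mu.dop_fit(cal, upd, state, n_lv=4, K_range=range(1, 8))
            rpd_dop = evaluate(predict(model, mu.dop_apply(corr, prd.X)),
                               prd.y("ssc")).rpd
            improved += rpd_dop > rpd_none
            small_k += corr.K in (1, 2, 3)
        assert improved >= 0.8 * n_seeds
        assert small_k >= 0.8 * n_seeds


class TestCoverage:
    def test_pca_scores_centered_and_orthogonal(self, rng):
        X = rng.normal(size=(40, 20))
        scores = mu.pca_scores(X, n_components=3)
        np.testing.assert_allclose(scores.mean(axis=0), 0.0, atol=1e-10)
        gram = scores.T @ scores
        np.testing.assert_allclose(gram - np.diag(np.diag(gram)), 0.0, atol=1e-8)

    def test_identical_sets_give_full_coverage(self, rng):
        pts = rng.normal(size=(30, 2))
        assert mu.coverage_index(pts, pts) == 1.0

    def test_disjoint_clusters_give_zero(self, rng):
        a = rng.normal(size=(20, 2))
        b = rng.normal(size=(20, 2)) + 100
        assert mu.coverage_index(a, b) == 0.0

    def test_negative_design_partial_and_lower_than_covering(self, rng):
        # bimodal prediction cloud; update set inside one mode only
        mode1 = rng.normal(size=(40, 2))
        mode2 = rng.normal(size=(40, 2)) + [6, 0]
        prediction = np.vstack([mode1, mode2])
        inside_one_mode = rng.normal(size=(25, 2)) * 1.2
        covering = np.vstack([rng.normal(size=(15, 2)) * 1.5,
                              rng.normal(size=(15, 2)) * 1.5 + [6, 0]])
        neg = mu.coverage_index(inside_one_mode, prediction)
        pos = mu.coverage_index(covering, prediction)
        assert 0.0 < neg < 1.0
        assert neg < pos

    def test_too_few_update_points_rejected(self, rng):
        with pytest.raises(ParameterError):
            mu.coverage_index(rng.normal(size=(2, 2)), rng.normal(size=(5, 2)))

    def test_batch_effect_separates_clusters_in_score_space(self, small_grid):
        cfg = sd.default_config(seed=1, n_fruit=10)
        data = sd.generate(cfg)
        scores = mu.pca_scores(data.X, n_components=2)
        newhall = data.spectra.meta["variety"].eq("Newhall").to_numpy()
        d_centroid = np.linalg.norm(scores[newhall].mean(0) - scores[~newhall].mean(0))
        within = max(scores[newhall].std(0).max(), scores[~newhall].std(0).max())
        assert d_centroid > within
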