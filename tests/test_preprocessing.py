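"""Pretreatment correctness: derivative exactness, scatter-correction
invariances, VSN's SNV limit, NSR anchoring, chain composition."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from citrusnir import preprocessing as pp
from citrusnir.errors import ParameterError, StateError, TransformError
from citrusnir.plsr_core import CVSpec

from conftest import make_analysis, make_spectra


class TestSGSecondDerivative:
    @pytest.mark.parametrize("coeffs", [(3.0, 0.0, 0.0), (1.0, -2.0, 0.0),
                                        (0.5, 1.5, 2.0)])
    def test_exact_on_degree_two_polynomials_including_edges(self, coeffs):
        a, b, c = coeffs
        j = np.arange(40, dtype=float)
        x = a + b * j + c * j**2
        out = pp.sg_second_derivative(x[None, :])
        # analytic 2nd derivative w.r.t. index is the constant 2c, everywhere
        np.testing.assert_allclose(out[0], np.full_like(j, 2 * c), atol=1e-9)

    def test_gaussian_band_sign_pattern(self):
        j = np.arange(101, dtype=float)
        x = np.exp(-0.5 * ((j - 50) / 8) ** 2)
        out = pp.sg_second_derivative(x[None, :])[0]
        assert out[50] < 0  # negative lobe at the band center
        assert out[35] > 0 and out[65] > 0  # flanking positive lobes

    def test_linearity(self, rng):
        x = rng.normal(size=(1, 60))
        y = rng.normal(size=(1, 60))
        lhs = pp.sg_second_derivative(2.5 * x - 1.5 * y)
        rhs = 2.5 * pp.sg_second_derivative(x) - 1.5 * pp.sg_second_derivative(y)
        np.testing.assert_allclose(lhs, rhs, atol=1e-10)

    @pytest.mark.parametrize("window,p", [(12, 60), (13, 10), (1, 60)])
    def test_bad_parameters_rejected(self, window, p):
        with pytest.raises(ParameterError):
            pp.sg_second_derivative(np.zeros((1, p)), window=window)

    def test_output_keeps_all_variables(self, rng):
        s = make_spectra(rng.normal(size=(4, 151)))
        assert pp.sg_second_derivative(s).absorbance.shape == (4, 151)


class TestSNV:
    def test_output_mean_zero_sd_one(self):
        out = pp.snv(np.array([[1.0, 2.0, 3.0]]))
        assert out[0].mean() == pytest.approx(0.0, abs=1e-12)
        assert out[0].std() == pytest.approx(1.0)  # population convention

    def test_idempotent(self, rng):
        x = rng.normal(size=(5, 30))
        np.testing.assert_allclose(pp.snv(pp.snv(x)), pp.snv(x), atol=1e-12)

    @given(a=st.floats(-5, 5), b=st.floats(0.1, 10))
    @settings(max_examples=25, deadline=None)
    def test_affine_invariance(self, a, b):
        x = np.linspace(0, 1, 20)[None, :] ** 2
        np.testing.assert_allclose(pp.snv(a + b * x), pp.snv(x), atol=1e-9)

    def test_constant_spectrum_names_offender(self):
        s = make_spectra(np.vstack([np.arange(10.0), np.full(10, 2.0)]))
        with pytest.raises(TransformError, match="S002"):
            pp.snv(s)


class TestMSC:
    def test_exact_descatter_of_affine_distortion(self, rng):
        ref = np.sin(np.linspace(0, 3, 50)) + 2
        state = pp.MSCState(reference=ref)
        distorted = 2.0 + 3.0 * ref
        out = pp.msc_apply(state, distorted[None, :])
        np.testing.assert_allclose(out[0], ref, atol=1e-10)

    def test_reference_is_fixed_point(self, rng):
        cal = rng.normal(size=(8, 40)) + np.linspace(1, 2, 40)
        state = pp.msc_fit(cal)
        out = pp.msc_apply(state, state.reference[None, :])
        np.testing.assert_allclose(out[0], state.reference, atol=1e-10)

    def test_reduces_between_spectrum_variance(self, rng):
        r = np.exp(-0.5 * ((np.arange(80) - 40) / 10.0) ** 2) + 1.0
        offsets = rng.normal(0, 0.3, size=12)
        slopes = 1 + rng.normal(0, 0.2, size=12)
        A = offsets[:, None] + slopes[:, None] * r
        state = pp.msc_fit(A)
        corrected = pp.msc_apply(state, A)
        assert np.all(corrected.var(axis=0) <= A.var(axis=0) + 1e-12)


class TestVSN:
    def test_uniform_weights_reproduce_snv(self, rng):
        x = rng.normal(size=(6, 40)) + 3
        state = pp.VSNState(weights=np.ones(40))
        np.testing.assert_allclose(pp.vsn_apply(state, x), pp.snv(x), atol=1e-10)

    def test_informative_band_gets_low_weight(self, rng):
        # shared shape plus a high-variance band at indices 20-30
        base = np.linspace(1, 2, 60)
        A = np.tile(base, (20, 1)) + 0.02 * rng.normal(size=(20, 60))
        A[:, 20:30] += rng.normal(0, 0.8, size=(20, 1))
        state = pp.vsn_fit(A)
        assert state.weights[20:30].mean() < state.weights[40:].mean()

    def test_weights_in_unit_interval(self, rng):
        state = pp.vsn_fit(rng.normal(size=(10, 30)) + 5)
        assert np.all(state.weights >= 0) and np.all(state.weights <= 1)
        assert state.weights.any()

    def test_apply_deterministic(self, rng):
        A = rng.normal(size=(5, 30)) + 4
        state = pp.vsn_fit(A)
        np.testing.assert_array_equal(pp.vsn_apply(state, A), pp.vsn_apply(state, A))

    def test_needs_three_spectra(self, rng):
        with pytest.raises(ParameterError):
            pp.vsn_fit(rng.normal(size=(2, 30)))


class TestNSR:
    def test_anchors_map_to_one_and_zero(self, rng):
        s = make_spectra(rng.normal(size=(5, 30)) + 5)
        g = s.grid.values
        out = pp.nsr_apply((float(g[4]), float(g[20])), s)
        np.testing.assert_allclose(out.absorbance[:, 4], 1.0, atol=1e-12)
        np.testing.assert_allclose(out.absorbance[:, 20], 0.0, atol=1e-12)

    def test_affine_invariance(self, rng):
        A = rng.normal(size=(4, 25)) + 3
        s = make_spectra(A)
        s2 = make_spectra(2.5 * A + 0.3)
        g = s.grid.values
        anchors = (float(g[2]), float(g[18]))
        np.testing.assert_allclose(pp.nsr_apply(anchors, s).absorbance,
                                   pp.nsr_apply(anchors, s2).absorbance, atol=1e-10)

    def test_selection_is_argmin_over_searched_pairs(self, rng):
        # 20-wavelength toy: exhaustively recompute the coarse-grid criterion
        n, p = 40, 20
        A = rng.normal(size=(n, p)) + 5
        y = 12 + A[:, 7] - A[:, 12] + 0.05 * rng.normal(size=n)
        data = make_analysis(A, y)
        cv = CVSpec(k=5, seed=0, max_lv=4)
        state = pp.nsr_select(data, cv_spec=cv, coarse_step=4)
        coarse = list(range(0, p, 4))
        oracle = min(
            (pp._nsr_criterion(A, y, i1, i2, cv), (i1, i2))
            for k, i1 in enumerate(coarse) for i2 in coarse[k + 1:]
        )
        i1 = data.spectra.grid.index_of(state.lambda1)
        i2 = data.spectra.grid.index_of(state.lambda2)
        # refinement can only improve on the coarse-grid optimum
        assert pp._nsr_criterion(A, y, i1, i2, cv) <= oracle[0] + 1e-12

    def test_zero_denominator_lists_spectra(self):
        A = np.ones((2, 10))
        A[0] = np.arange(10)
        s = make_spectra(A)
        g = s.grid.values
        with pytest.raises(TransformError, match="S002"):
            pp.nsr_apply((float(g[1]), float(g[5])), s)


class TestChains:
    def test_chain_2d_on_linear_spectra_is_zero(self):
        j = np.arange(40, dtype=float)
        data = make_analysis(np.vstack([1 + 2 * j, 3 - j]), [10.0, 12.0])
        state = pp.fit_chain("2D", data)
        out = pp.apply_chain(state, data.spectra)
        np.testing.assert_allclose(out.absorbance, 0.0, atol=1e-9)

    def test_chain_equals_manual_composition(self, rng):
        A = rng.normal(size=(6, 40)) + np.linspace(1, 3, 40)
        data = make_analysis(A, np.linspace(10, 14, 6))
        state = pp.fit_chain("2D+SNV", data)
        out = pp.apply_chain(state, data.spectra).absorbance
        manual = pp.snv(pp.sg_second_derivative(A))
        np.testing.assert_allclose(out, manual, atol=1e-12)

    def test_fitted_chain_is_deterministic(self, rng):
        A = rng.normal(size=(6, 40)) + 5
        data = make_analysis(A, np.linspace(10, 14, 6))
        state = pp.fit_chain("2D+VSN", data)
        a = pp.apply_chain(state, data.spectra).absorbance
        b = pp.apply_chain(state, data.spectra).absorbance
        np.testing.assert_array_equal(a, b)

    def test_row_permutation_permutes_outputs(self, rng):
        A = rng.normal(size=(8, 40)) + 5
        perm = rng.permutation(8)
        for fn in (pp.snv, pp.sg_second_derivative):
            np.testing.assert_allclose(fn(A)[perm], fn(A[perm]), atol=1e-12)

    def test_unknown_step_and_unfitted_chain_rejected(self):
        with pytest.raises(ParameterError):
            pp.parse_chain("2D+WAVELET")
        with pytest.raises(StateError):
            pp.apply_chain(None, np.zeros((1, 20)))
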