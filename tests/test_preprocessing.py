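"""Preprocessing operators against independent brute-force oracles."""

import numpy as np
import pytest

from oedftir import (
    PipelineConfig,
    Spectrum,
    apply_pipeline,
    excise_paraffin,
    fit_feature_pca,
    fit_scaler,
    make_axis,
    normalize,
    optimal_pipeline,
    rubberband,
    sg_derivative,
    sg_smooth,
)
from oedftir.preprocessing import PCADenoise, normalize_matrix


# ---------------------------------------------------------------------------
# Savitzky–Golay: brute-force local least-squares polynomial oracle
# ---------------------------------------------------------------------------


def brute_savgol(x, y, window, polyorder, deriv):
    """Independent SG oracle: at each interior point fit a polynomial to
    the surrounding window by ordinary least squares and evaluate (the
    derivative of) the fit at the centre."""
    half = window // 2
    out = np.full_like(y, np.nan)
    P = np.polynomial.polynomial
    for i in range(half, len(y) - half):
        xs = x[i - half : i + half + 1] - x[i]
        coef = P.polyfit(xs, y[i - half : i + half + 1], polyorder)
        coef = P.polyder(coef, deriv) if deriv else coef
        out[i] = P.polyval(0.0, coef)
    return out


@pytest.mark.parametrize("window,polyorder,deriv", [(15, 2, 0), (15, 2, 1), (9, 3, 2), (5, 2, 1)])
def test_sg_matches_brute_force_oracle(window, polyorder, deriv):
    ax = make_axis(1000, 1480, 4)
    rng = np.random.default_rng(12)
    half = window // 2
    for _ in range(100):
        y = rng.normal(size=len(ax))
        s = Spectrum(ax, y)
        got = (
            sg_smooth(s, window, polyorder)
            if deriv == 0
            else sg_derivative(s, window, polyorder, deriv)
        ).absorbance
        ref = brute_savgol(ax.values, y, window, polyorder, deriv)
        interior = slice(half, len(ax) - half)
        np.testing.assert_allclose(got[interior], ref[interior], rtol=1e-8, atol=1e-10)


def test_sg_reproduces_polynomial_exactly():
    ax = make_axis(1000, 1200, 4)
    y = 3.0 + 0.02 * ax.values + 1e-4 * ax.values**2
    out = sg_smooth(Spectrum(ax, y), 15, 2).absorbance
    np.testing.assert_allclose(out, y, rtol=1e-9)


def test_sg_constant_unchanged_and_derivative_zero():
    ax = make_axis(1000, 1200, 4)
    s = Spectrum(ax, np.full(len(ax), 2.5))
    np.testing.assert_allclose(sg_smooth(s, 9, 2).absorbance, 2.5)
    np.testing.assert_allclose(sg_derivative(s, 9, 2, 1).absorbance, 0.0, atol=1e-12)


def test_sg_first_derivative_of_linear_is_slope():
    ax = make_axis(1000, 1200, 4)
    s = Spectrum(ax, 0.37 * ax.values)
    np.testing.assert_allclose(sg_derivative(s, 11, 2, 1).absorbance, 0.37, rtol=1e-9)


def test_sg_parameter_validation():
    ax = make_axis(1000, 1100, 4)
    s = Spectrum(ax, np.zeros(len(ax)))
    with pytest.raises(ValueError, match="odd"):
        sg_smooth(s, 8, 2)
    with pytest.raises(ValueError, match="exceed"):
        sg_smooth(s, 3, 3)
    with pytest.raises(ValueError, match="order"):
        sg_derivative(s, 9, 2, 3)


# ---------------------------------------------------------------------------
# Rubberband: brute-force pairwise line-sweep hull oracle
# ---------------------------------------------------------------------------


def brute_lower_hull(x, y):
    """O(n^3) oracle: the lower hull baseline is the upper envelope of all
    chords that lie on or below every data point."""
    n = len(x)
    base = np.full(n, -np.inf)
    for i in range(n):
        for j in range(i + 1, n):
            slope = (y[j] - y[i]) / (x[j] - x[i])
            line = y[i] + slope * (x - x[i])
            if np.all(line <= y + 1e-9):
                base = np.maximum(base, line)
    return base


def test_rubberband_matches_brute_force_hull():
    ax = make_axis(1000, 1236, 4)
    rng = np.random.default_rng(3)
    for _ in range(5):
        y = rng.normal(size=len(ax)).cumsum() * 0.05 + rng.normal(size=len(ax)) * 0.1
        got = rubberband(Spectrum(ax, y)).absorbance
        ref = y - brute_lower_hull(ax.values, y)
        np.testing.assert_allclose(got, ref, atol=1e-8)


def test_rubberband_convex_input_gives_zero():
    ax = make_axis(1000, 1200, 4)
    y = (ax.values - 1100.0) ** 2 * 1e-4
    np.testing.assert_allclose(rubberband(Spectrum(ax, y)).absorbance, 0.0, atol=1e-10)


def test_rubberband_recovers_peak_on_sloped_line():
    ax = make_axis(1000, 1400, 4)
    wn = ax.values
    peak = 0.5 * np.exp(-0.5 * ((wn - 1200) / 15) ** 2)
    y = peak + 0.3 + 0.002 * wn
    out = rubberband(Spectrum(ax, y)).absorbance
    assert out[0] == pytest.approx(0.0, abs=1e-10)
    assert out[-1] == pytest.approx(0.0, abs=1e-10)
    assert np.all(out >= -1e-10)
    np.testing.assert_allclose(out, peak, atol=5e-3)


def test_rubberband_affine_invariance(rng):
    ax = make_axis(1000, 1200, 4)
    y = np.abs(rng.normal(size=len(ax)))
    a = rubberband(Spectrum(ax, y)).absorbance
    b = rubberband(Spectrum(ax, y + 3.1 - 0.01 * ax.values)).absorbance
    np.testing.assert_allclose(a, b, atol=1e-9)


# ---------------------------------------------------------------------------
# Paraffin excision
# ---------------------------------------------------------------------------


class TestExcision:
    def test_default_axis_removes_38_points(self, default_axis):
        s = Spectrum(default_axis, np.ones(len(default_axis)))
        reduced, keep = excise_paraffin(s)
        # oracle: enumerate grid points inside the closed window
        inside = [v for v in default_axis.values if 1340 <= v <= 1490]
        assert len(inside) == 38
        assert len(reduced.axis) == 726 - 38 == 688
        assert keep.sum() == 688
        assert not np.any((reduced.axis.values >= 1340) & (reduced.axis.values <= 1490))

    def test_window_without_grid_points_is_identity(self):
        ax = make_axis(1000, 1100, 10)
        s = Spectrum(ax, np.arange(len(ax), dtype=float))
        reduced, _ = excise_paraffin(s, 1001.0, 1004.0)
        np.testing.assert_array_equal(reduced.axis.values, ax.values)
        np.testing.assert_array_equal(reduced.absorbance, s.absorbance)

    def test_equal_reduced_axes_for_different_spectra(self, default_axis, rng):
        s1 = Spectrum(default_axis, rng.normal(size=len(default_axis)))
        s2 = Spectrum(default_axis, rng.normal(size=len(default_axis)))
        r1, _ = excise_paraffin(s1)
        r2, _ = excise_paraffin(s2)
        np.testing.assert_array_equal(r1.axis.values, r2.axis.values)

    def test_window_outside_axis_rejected(self):
        ax = make_axis(1000, 1100, 10)
        s = Spectrum(ax, np.zeros(len(ax)))
        with pytest.raises(ValueError, match="outside"):
            excise_paraffin(s, 2000.0, 2100.0)


# ---------------------------------------------------------------------------
# Normalization
# ---------------------------------------------------------------------------


class TestNormalize:
    def test_vector_three_four_five(self):
        ax = make_axis(1000, 1004, 4)
        out = normalize(Spectrum(ax, np.array([3.0, 4.0])), "vector")
        np.testing.assert_allclose(out.absorbance, [0.6, 0.8])

    def test_vector_unit_sum_of_squares(self, default_axis, rng):
        y = rng.normal(size=len(default_axis))
        out = normalize(Spectrum(default_axis, y), "vector")
        assert np.sum(out.absorbance**2) == pytest.approx(1.0)

    @pytest.mark.parametrize("method", ["vector", "minmax", "amide_i"])
    def test_scale_invariance(self, method, default_axis, rng):
        y = np.abs(rng.normal(size=len(default_axis))) + 0.1
        a = normalize(Spectrum(default_axis, y), method).absorbance
        b = normalize(Spectrum(default_axis, 2.7 * y), method).absorbance
        np.testing.assert_allclose(a, b, rtol=1e-10)

    def test_minmax_range(self, default_axis, rng):
        out = normalize(Spectrum(default_axis, rng.normal(size=len(default_axis))), "minmax")
        assert out.absorbance.min() == pytest.approx(0.0)
        assert out.absorbance.max() == pytest.approx(1.0)

    def test_degenerate_inputs_rejected_with_method_message(self, default_axis):
        zero = Spectrum(default_axis, np.zeros(len(default_axis)))
        with pytest.raises(ValueError, match="vector"):
            normalize(zero, "vector")
        const = Spectrum(default_axis, np.full(len(default_axis), 2.0))
        with pytest.raises(ValueError, match="min-max"):
            normalize(const, "minmax")

    def test_amide_i_window_must_overlap(self):
        ax = make_axis(2000, 2500, 4)
        with pytest.raises(ValueError, match="amide"):
            normalize(Spectrum(ax, np.ones(len(ax))), "amide_i")


# ---------------------------------------------------------------------------
# Fitted transforms
# ---------------------------------------------------------------------------


class TestScaler:
    def test_standard_training_columns(self, rng):
        X = rng.normal(3.0, 2.0, size=(50, 8))
        sc = fit_scaler(X, "standard")
        Z = sc.transform(X)
        np.testing.assert_allclose(Z.mean(axis=0), 0.0, atol=1e-10)
        np.testing.assert_allclose(Z.std(axis=0), 1.0, atol=1e-10)

    def test_constant_channel_maps_to_zero(self, rng):
        X = rng.normal(size=(20, 3))
        X[:, 1] = 7.0
        Z = fit_scaler(X, "standard").transform(X)
        np.testing.assert_allclose(Z[:, 1], 0.0, atol=1e-12)

    def test_invertibility(self, rng):
        X = rng.normal(size=(30, 5))
        sc = fit_scaler(X, "minmax")
        np.testing.assert_allclose(sc.inverse_transform(sc.transform(X)), X, atol=1e-12)


class TestPCADenoise:
    def test_full_variance_reconstructs_input(self, rng):
        X = rng.normal(size=(12, 8))
        den = PCADenoise(100.0).fit(X)
        np.testing.assert_allclose(den.transform(X), X, atol=1e-9)

    def test_rank_one_perfect_with_single_component(self, rng):
        u = rng.normal(size=20)
        v = rng.normal(size=15)
        X = np.outer(u, v)
        den = PCADenoise(50.0).fit(X)
        assert den.n_components_ == 1
        np.testing.assert_allclose(den.transform(X), X, atol=1e-9)

    def test_reconstruction_error_equals_discarded_eigenvalues(self, rng):
        X = rng.normal(size=(40, 10)) @ np.diag(np.linspace(3, 0.3, 10))
        den = PCADenoise(80.0).fit(X)
        k = den.n_components_
        Xr = den.transform(X)
        err = np.linalg.norm(X - Xr) ** 2
        eig = den._pca.explained_variance_  # sample eigenvalues (ddof=1)
        expected = eig[k:].sum() * (X.shape[0] - 1)
        assert err == pytest.approx(expected, rel=1e-8)

    def test_threshold_validation(self):
        with pytest.raises(ValueError, match="explained_variance"):
            PCADenoise(0.0)


class TestFeaturePCA:
    def test_rank_two_data_needs_at_most_two(self, rng):
        basis = rng.normal(size=(2, 30))
        X = rng.normal(size=(50, 2)) @ basis
        pca = fit_feature_pca(X, 90.0)
        assert pca.n_components_ <= 2

    def test_isotropic_limit(self, rng):
        d = 20
        X = rng.normal(size=(6000, d))
        pca = fit_feature_pca(X, 90.0)
        # equal-eigenvalue limit: k approx ceil(0.9 d), loosely
        assert 15 <= pca.n_components_ <= 20

    def test_reconstruction_error_identity(self, rng):
        X = rng.normal(size=(60, 12)) @ np.diag(np.linspace(2, 0.1, 12))
        pca = fit_feature_pca(X, 90.0)
        scores = pca.transform(X)
        err = np.linalg.norm(X - pca.inverse_transform(scores)) ** 2
        full = fit_feature_pca(X, 100.0)
        discarded = full.component_variances_[pca.n_components_ :].sum() * (X.shape[0] - 1)
        assert err == pytest.approx(discarded, rel=1e-6)


# ---------------------------------------------------------------------------
# Pipeline assembly
# ---------------------------------------------------------------------------


class TestApplyPipeline:
    def test_identity_pipeline_is_excision_only(self, default_axis, rng):
        cfg = PipelineConfig()  # all steps none except mandatory excision
        X = rng.normal(size=(4, len(default_axis)))
        tr, te, state = apply_pipeline(cfg, X, X[:2], default_axis)
        keep = (default_axis.values < 1340) | (default_axis.values > 1490)
        np.testing.assert_array_equal(tr, X[:, keep])
        np.testing.assert_array_equal(te, X[:2][:, keep])

    def test_optimal_preset_on_clean_spectrum(self, default_axis):
        cfg = optimal_pipeline()
        assert cfg.is_bound
        wn = default_axis.values
        X = np.exp(-0.5 * ((wn - 1650) / 30) ** 2)[None, :] * np.array([[1.0], [1.3]])
        tr, te, state = apply_pipeline(cfg, X, X, default_axis)
        # preprocessed spectra live on the 688-point excised grid before
        # PCA feature extraction collapses them to scores
        assert state.wn_out.size == 688
        assert np.all(np.isfinite(tr))
        # vector normalization after derivative cancels the thickness factor
        np.testing.assert_allclose(tr[0], tr[1], atol=1e-9)

    def test_row_permutation_equivariance(self, default_axis, rng):
        cfg = PipelineConfig(normalization="vector", scaling="standard")
        X = rng.normal(size=(10, len(default_axis)))
        T = rng.normal(size=(6, len(default_axis)))
        perm = rng.permutation(6)
        _, te1, _ = apply_pipeline(cfg, X, T, default_axis, seed=0)
        _, te2, _ = apply_pipeline(cfg, X, T[perm], default_axis, seed=0)
        np.testing.assert_allclose(te1[perm], te2, atol=1e-12)

    def test_no_test_set_leakage_into_fits(self, default_axis, rng):
        """Corrupting the test set never changes fitted state or train output."""
        cfg = PipelineConfig(
            smoothing="pca", denoise_variance=90.0,
            normalization="vector", scaling="standard",
            feature_extraction="pca", feature_variance=95.0,
        )
        X = rng.normal(size=(20, len(default_axis))) + 1.0
        T = rng.normal(size=(5, len(default_axis))) + 1.0
        tr1, _, st1 = apply_pipeline(cfg, X, T, default_axis, seed=0)
        tr2, _, st2 = apply_pipeline(cfg, X, 100.0 * T + 7, default_axis, seed=0)
        np.testing.assert_array_equal(tr1, tr2)
        np.testing.assert_array_equal(
            st1.feature_pca.loadings_, st2.feature_pca.loadings_
        )

    def test_errors_annotated_with_step_name(self, default_axis):
        cfg = PipelineConfig(normalization="vector")
        X = np.zeros((3, len(default_axis)))  # zero spectra: vector norm fails
        with pytest.raises(ValueError, match="normalization:vector"):
            apply_pipeline(cfg, X, None, default_axis)


class TestPipelineConfig:
    def test_out_of_range_hyperparameters_rejected(self):
        with pytest.raises(ValueError, match="sg_window"):
            PipelineConfig(smoothing="sg", sg_window=6, sg_polyorder=2)
        with pytest.raises(ValueError, match="logistic_c"):
            PipelineConfig(classifier="logistic", logistic_c=100.0)
        with pytest.raises(ValueError, match="smoothing"):
            PipelineConfig(smoothing="boxcar")

    def test_json_round_trip(self, tmp_path):
        cfg = optimal_pipeline()
        cfg.to_json(tmp_path / "p.json")
        back = PipelineConfig.from_json(tmp_path / "p.json")
        assert back == cfg

    def test_optimal_preset_matches_reported_best(self):
        cfg = optimal_pipeline()
        assert cfg.smoothing == "sg" and cfg.sg_window == 15 and cfg.sg_polyorder == 2
        assert cfg.baseline == "sg_diff" and cfg.diff_order == 1
        assert cfg.normalization == "vector"
        assert cfg.feature_extraction == "pca" and cfg.feature_variance == 90.0
        assert cfg.classifier == "lda"

    def test_bind_defaults_fills_all_free_hyperparameters(self):
        skel = PipelineConfig(
            smoothing="sg", baseline="sg_diff", classifier="random_forest"
        )
        assert not skel.is_bound
        bound = skel.bind_defaults()
        assert bound.is_bound
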