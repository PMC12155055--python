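import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from torreya_nirs import (
    SyntheticConfig,
    cross_validate,
    fit_plsr,
    one_se_choice,
    predict,
    simulate,
)
from torreya_nirs.plsr import PLSRModel

from conftest import quiet_config


def test_rank_one_signal_needs_one_component():
    rng = np.random.default_rng(0)
    direction = rng.normal(size=12)
    t = rng.normal(size=40)
    x = np.outer(t, direction)
    y = 2.0 * t + 5.0
    model = fit_plsr(x, y, n_components=1)
    resid = y - predict(model, x)
    assert np.max(np.abs(resid)) < 1e-8


def test_full_rank_plsr_matches_ols():
    rng = np.random.default_rng(1)
    x = rng.normal(size=(8, 5))
    y = rng.normal(size=8)
    model = fit_plsr(x, y, n_components=5)
    design = np.column_stack([np.ones(8), x])
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    np.testing.assert_allclose(predict(model, x), design @ beta, atol=1e-6)


def test_sklearn_oracle_agreement():
    """NIPALS coefficients agree with an independent PLS implementation."""
    cross_decomposition = pytest.importorskip("sklearn.cross_decomposition")
    rng = np.random.default_rng(2)
    x = rng.normal(size=(30, 12))
    y = x[:, 0] - 0.5 * x[:, 3] + rng.normal(0, 0.05, 30)
    mine = fit_plsr(x, y, n_components=4)
    ref = cross_decomposition.PLSRegression(n_components=4, scale=False).fit(x, y)
    np.testing.assert_allclose(
        predict(mine, x), ref.predict(x).ravel(), atol=1e-8
    )


def test_permutation_invariance():
    rng = np.random.default_rng(3)
    x = rng.normal(size=(25, 10))
    y = rng.normal(size=25)
    perm = rng.permutation(25)
    a = fit_plsr(x, y, n_components=3)
    b = fit_plsr(x[perm], y[perm], n_components=3)
    np.testing.assert_allclose(
        a.regression_coefficients, b.regression_coefficients, atol=1e-10
    )


def test_predict_on_training_mean_returns_y_mean():
    rng = np.random.default_rng(4)
    x = rng.normal(size=(20, 6))
    y = rng.normal(size=20)
    model = fit_plsr(x, y, n_components=2)
    assert predict(model, x.mean(axis=0))[0] == pytest.approx(model.y_mean)


def test_factor_and_coefficient_forms_agree():
    """Score-path predictions equal the collapsed-coefficient predictions."""
    rng = np.random.default_rng(5)
    x = rng.normal(size=(18, 7))
    y = rng.normal(size=18)
    model = fit_plsr(x, y, n_components=4)
    xc = x - model.x_mean
    # factor recursion: t_k = deflated X w_k, yhat = y_mean + sum q_k t_k
    xd = xc.copy()
    yhat = np.full(18, model.y_mean)
    for k in range(model.n_latent):
        t = xd @ model.weights[:, k]
        yhat += model.y_loadings[k] * t
        xd -= np.outer(t, model.x_loadings[:, k])
    np.testing.assert_allclose(yhat, predict(model, x), atol=1e-8)


def test_rmsec_nonincreasing_in_components(default_dataset):
    from torreya_nirs import snv

    x = snv(default_dataset.spectra).absorbance
    y = default_dataset.samples.protein_pct
    rmsec = []
    for a in range(1, 9):
        model = fit_plsr(x, y, n_components=a)
        rmsec.append(float(np.sqrt(np.mean((y - predict(model, x)) ** 2))))
    assert np.all(np.diff(rmsec) <= 1e-10)


def test_noiseless_synthetic_recovery():
    """Distortion-free spectra: protein recovered to numerical precision."""
    ds = simulate(quiet_config(n_samples=40, seed=6))
    x = ds.spectra.absorbance
    y = ds.samples.protein_pct
    model = fit_plsr(x, y, n_components=5)
    assert np.max(np.abs(predict(model, x) - y)) < 1e-6


def test_multivariate_calibration_beats_univariate(default_dataset):
    """Interferent overlap defeats a single-wavelength regression but not PLSR."""
    x = default_dataset.spectra.absorbance
    wl = default_dataset.spectra.wavelengths_nm
    y = default_dataset.samples.protein_pct
    model = fit_plsr(x, y, n_components=8)
    r2_pls = 1 - np.sum((y - predict(model, x)) ** 2) / np.sum((y - y.mean()) ** 2)
    col = x[:, wl == 1450.0].ravel()
    design = np.column_stack([np.ones_like(col), col])
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    r2_uni = 1 - np.sum((y - design @ beta) ** 2) / np.sum((y - y.mean()) ** 2)
    assert r2_pls >= 0.9
    assert r2_uni < 0.5


def test_zero_variance_response_rejected():
    rng = np.random.default_rng(7)
    with pytest.raises(ValueError, match="zero-variance"):
        fit_plsr(rng.normal(size=(10, 4)), np.full(10, 9.6), 2)


def test_axis_mismatch_error_names_axes():
    rng = np.random.default_rng(8)
    x = rng.normal(size=(12, 6))
    y = rng.normal(size=12)
    model = fit_plsr(x, y, 2, wavelengths_nm=1000.0 + np.arange(6))
    with pytest.raises(ValueError, match="axis mismatch"):
        predict(model, x[:, :5], wavelengths_nm=1000.0 + np.arange(5))


def test_model_json_roundtrip():
    rng = np.random.default_rng(9)
    x = rng.normal(size=(15, 5))
    y = rng.normal(size=15)
    model = fit_plsr(x, y, 3, chain_label="SNV")
    clone = PLSRModel.from_dict(model.to_dict())
    np.testing.assert_allclose(predict(clone, x), predict(model, x), atol=1e-12)


# ---------------------------------------------------------------- CV / one-SE

def brute_force_one_se(rmsecv, se):
    a_star = int(np.argmin(rmsecv))
    cutoff = rmsecv[a_star] + se[a_star]
    for a in range(len(rmsecv)):
        if rmsecv[a] <= cutoff:
            return a + 1
    raise AssertionError("unreachable")


def test_one_se_worked_example():
    """RMSECV [0.50, 0.30, 0.28, 0.27] with SE(argmin)=0.02 selects A=3."""
    rmsecv = np.array([0.50, 0.30, 0.28, 0.27])
    se = np.array([0.05, 0.03, 0.02, 0.02])
    assert one_se_choice(rmsecv, se) == 3


def test_one_se_monotone_increasing_curve_picks_one():
    rmsecv = np.array([0.2, 0.3, 0.4, 0.5])
    se = np.full(4, 0.01)
    assert one_se_choice(rmsecv, se) == 1


@settings(derandomize=True, deadline=None, max_examples=1000)
@given(seed=st.integers(0, 10**6))
def test_one_se_matches_brute_force_enumeration(seed):
    rng = np.random.default_rng(seed)
    n = rng.integers(2, 15)
    rmsecv = rng.uniform(0.1, 1.0, size=n)
    se = rng.uniform(0.0, 0.2, size=n)
    assert one_se_choice(rmsecv, se) == brute_force_one_se(rmsecv, se)


def test_cross_validate_deterministic_under_seed():
    rng = np.random.default_rng(10)
    x = rng.normal(size=(40, 8))
    y = rng.normal(size=40)
    a = cross_validate(x, y, a_max=5, folds=5, seed=3)
    b = cross_validate(x, y, a_max=5, folds=5, seed=3)
    np.testing.assert_array_equal(a.fold_assignment, b.fold_assignment)
    np.testing.assert_allclose(a.rmsecv, b.rmsecv, atol=0)
    assert a.chosen_a == b.chosen_a


def test_cross_validate_caps_a_max():
    rng = np.random.default_rng(11)
    x = rng.normal(size=(12, 30))
    y = rng.normal(size=12)
    with pytest.warns(RuntimeWarning, match="capped"):
        result = cross_validate(x, y, a_max=20, folds=4, seed=0)
    assert result.rmsecv.size < 20
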