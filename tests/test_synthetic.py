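import numpy as np
import pytest
from scipy import stats

from torreya_nirs import (
    SyntheticConfig,
    draw_protein_values,
    generate_spectra,
    inject_outliers,
    simulate,
)
from torreya_nirs.synthetic import STATE_ATTENUATION, clean_spectra

from conftest import quiet_config


def test_default_axis_has_651_points():
    cfg = SyntheticConfig(seed=0)
    wl = cfg.wavelengths_nm
    assert wl.size == 651
    assert wl[0] == 1000.0 and wl[-1] == 1650.0


def test_protein_values_respect_range():
    cfg = SyntheticConfig(n_samples=124, seed=1)
    p = draw_protein_values(cfg)
    assert p.size == 124
    assert p.min() >= cfg.protein_min_pct
    assert p.max() <= cfg.protein_max_pct


def test_protein_sd_zero_collapses_to_mean():
    cfg = SyntheticConfig(protein_sd_pct=0.0, seed=3)
    p = draw_protein_values(cfg)
    np.testing.assert_array_equal(p, np.full(cfg.n_samples, cfg.protein_mean_pct))


def test_degenerate_range_rejected():
    with pytest.raises(ValueError, match="zero-variance"):
        SyntheticConfig(protein_min_pct=9.0, protein_max_pct=9.0, seed=0)


def test_protein_moments_match_truncated_normal():
    """Monte-Carlo mean agrees with the analytic truncated-normal mean."""
    cfg = SyntheticConfig(n_samples=10_000, seed=11)
    a = (cfg.protein_min_pct - cfg.protein_mean_pct) / cfg.protein_sd_pct
    b = (cfg.protein_max_pct - cfg.protein_mean_pct) / cfg.protein_sd_pct
    exact_mean, exact_var = stats.truncnorm.stats(
        a, b, loc=cfg.protein_mean_pct, scale=cfg.protein_sd_pct, moments="mv"
    )
    p = draw_protein_values(cfg)
    tol = 3.0 * np.sqrt(float(exact_var) / cfg.n_samples)
    assert abs(p.mean() - float(exact_mean)) < tol


def test_clean_model_is_proportional_in_protein():
    """Single band, no interferents/noise: spectrum scales linearly with protein."""
    cfg = quiet_config(
        n_samples=2,
        band_centers_nm=(1200.0,),
        band_widths_nm=(30.0,),
        band_amplitudes=(0.01,),
        interferent_bands=(),
    )
    ds = generate_spectra(cfg, np.array([1.0, 2.0]))
    np.testing.assert_allclose(
        ds.spectra.absorbance[1], 2.0 * ds.spectra.absorbance[0], atol=1e-12
    )


def test_generation_is_deterministic():
    cfg = SyntheticConfig(seed=21)
    a = simulate(cfg)
    b = simulate(cfg)
    np.testing.assert_array_equal(a.spectra.absorbance, b.spectra.absorbance)
    np.testing.assert_array_equal(a.samples.protein_pct, b.samples.protein_pct)


def test_water_band_forms_local_maximum(default_dataset):
    """Band placement forces mean absorbance at 1450 nm above 1350 nm."""
    wl = default_dataset.spectra.wavelengths_nm
    mean = default_dataset.spectra.absorbance.mean(axis=0)
    assert mean[wl == 1450.0][0] > mean[wl == 1350.0][0]


def test_state_ordering_pointwise():
    """Granule spectra sit above deshelled above shelled, on average."""
    means = {}
    for state in ("shell", "deshelled", "granules"):
        cfg = SyntheticConfig(state=state, seed=5, scatter_offset_sd=0.0,
                              baseline_drift_amplitude=0.0)
        means[state] = simulate(cfg).spectra.absorbance.mean(axis=0)
    assert np.all(means["granules"] >= means["deshelled"] - 1e-3)
    assert np.all(means["deshelled"] >= means["shell"] - 1e-3)
    assert (
        STATE_ATTENUATION["shell"]
        < STATE_ATTENUATION["deshelled"]
        < STATE_ATTENUATION["granules"]
    )


def test_protein_length_mismatch_rejected():
    cfg = SyntheticConfig(seed=0)
    with pytest.raises(ValueError, match="n_samples"):
        generate_spectra(cfg, np.ones(3))


def test_inject_outliers_empty_is_noop(default_dataset):
    ds = inject_outliers(default_dataset)
    np.testing.assert_array_equal(
        ds.spectra.absorbance, default_dataset.spectra.absorbance
    )
    np.testing.assert_array_equal(
        ds.samples.protein_pct, default_dataset.samples.protein_pct
    )
    assert ds.outliers == []


def test_inject_outliers_records_provenance(default_dataset):
    ds = inject_outliers(default_dataset, spectral_idx=[3], chemical_idx=[10, 20])
    assert sorted(ds.outliers) == [(3, "spectral"), (10, "chemical"), (20, "chemical")]
    # chemical shift magnitude is exactly +/- 2 % by default
    delta = ds.samples.protein_pct - default_dataset.samples.protein_pct
    assert abs(delta[10]) == pytest.approx(2.0)
    assert abs(delta[20]) == pytest.approx(2.0)
    # spectral artifact leaves the recorded protein untouched
    assert delta[3] == 0.0
    # spike peak ~= +1.0 AU (center falls between 1-nm grid points)
    assert np.max(np.abs(
        ds.spectra.absorbance[3] - default_dataset.spectra.absorbance[3]
    )) == pytest.approx(1.0, abs=0.01)


def test_inject_outliers_validates_indices(default_dataset):
    with pytest.raises(ValueError, match="disjoint"):
        inject_outliers(default_dataset, spectral_idx=[1], chemical_idx=[1])
    with pytest.raises(ValueError, match="out of range"):
        inject_outliers(default_dataset, spectral_idx=[999])


def test_rank_one_regression_recovers_affine_map():
    """With distortions off and interferent concentrations fixed, absorbance
    at any wavelength is an affine function of protein."""
    from torreya_nirs import InterferentBand

    fixed_bands = tuple(
        InterferentBand(b.center_nm, b.width_nm, b.amplitude, b.conc_mean, 0.0)
        for b in SyntheticConfig(seed=0).interferent_bands
    )
    cfg = quiet_config(n_samples=30, seed=9, interferent_bands=fixed_bands)
    ds = simulate(cfg)
    wl = ds.spectra.wavelengths_nm
    col = ds.spectra.absorbance[:, wl == 1450.0].ravel()
    p = ds.samples.protein_pct
    design = np.column_stack([np.ones_like(p), p])
    coef, res, *_ = np.linalg.lstsq(design, col, rcond=None)
    fitted = design @ coef
    assert np.max(np.abs(fitted - col)) < 1e-10
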