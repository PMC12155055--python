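import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from torreya_nirs import (
    SpectraMatrix,
    apply_chain,
    baseline_correct,
    msc,
    normalize,
    parse_chain,
    savitzky_golay,
    snv,
)


def make(rows, wl=None):
    rows = np.atleast_2d(np.asarray(rows, dtype=float))
    if wl is None:
        wl = 1000.0 + np.arange(rows.shape[1])
    return SpectraMatrix(wl, rows, np.arange(1, rows.shape[0] + 1))


# ---------------------------------------------------------------- SNV

def test_snv_small_example():
    out = snv(make([[1.0, 2.0, 3.0]]))
    np.testing.assert_allclose(out.absorbance[0], [-1.0, 0.0, 1.0], atol=1e-12)


def test_snv_output_standardized_and_idempotent(tiny_spectra):
    out = snv(tiny_spectra)
    np.testing.assert_allclose(out.absorbance.mean(axis=1), 0.0, atol=1e-12)
    np.testing.assert_allclose(out.absorbance.std(axis=1, ddof=1), 1.0, atol=1e-12)
    again = snv(out)
    np.testing.assert_allclose(again.absorbance, out.absorbance, atol=1e-12)


def test_snv_constant_row_names_sample():
    with pytest.raises(ValueError, match=r"\b2\b"):
        snv(make([[1.0, 2.0, 3.0], [5.0, 5.0, 5.0]]))


@settings(derandomize=True, deadline=None, max_examples=50)
@given(
    scale=st.floats(0.1, 10.0, allow_nan=False),
    offset=st.floats(-5.0, 5.0, allow_nan=False),
    seed=st.integers(0, 1000),
)
def test_snv_affine_invariance(scale, offset, seed):
    """SNV(a + b*x) == SNV(x): the scatter model is removed exactly."""
    rng = np.random.default_rng(seed)
    row = rng.normal(size=32)
    row = row - row.mean() + 1.0  # keep it nonconstant
    base = snv(make([row])).absorbance
    distorted = snv(make([offset + scale * row])).absorbance
    np.testing.assert_allclose(distorted, base, atol=1e-8)


# ---------------------------------------------------------------- MSC

def test_msc_inverts_known_distortion():
    ref = np.sin(np.arange(20) / 3.0) + 2.0
    out = msc(make([2.0 * ref + 1.0]), reference=ref)
    np.testing.assert_allclose(out.absorbance[0], ref, atol=1e-10)


def test_msc_self_reference_is_identity():
    ref = np.sin(np.arange(20) / 3.0) + 2.0
    out = msc(make([ref]), reference=ref)
    np.testing.assert_allclose(out.absorbance[0], ref, atol=1e-10)


def test_msc_collapses_scatter_family():
    """Rows a_i + b_i * shape all map onto (nearly) the same spectrum."""
    shape = np.cos(np.arange(40) / 5.0) + 3.0
    rng = np.random.default_rng(1)
    rows = [
        rng.uniform(-0.5, 0.5) + rng.uniform(0.5, 2.0) * shape for _ in range(6)
    ]
    out = msc(make(rows)).absorbance
    spread = out.max(axis=0) - out.min(axis=0)
    assert spread.max() < 1e-8


def test_msc_orthogonal_spectrum_rejected():
    ref = np.array([1.0, -1.0, 1.0, -1.0])
    flat = np.array([1.0, 1.0, -1.0, -1.0])  # zero covariance with ref
    with pytest.raises(ValueError, match="orthogonal"):
        msc(make([flat]), reference=ref)


# ---------------------------------------------------------------- SG

def test_sg_first_derivative_of_line_is_slope():
    wl = 1000.0 + np.arange(51)
    out = savitzky_golay(make([3.0 * wl + 7.0], wl=wl), 15, 2, deriv_order=1)
    np.testing.assert_allclose(out.absorbance, 3.0, atol=1e-10)
    # axis shrank by half a window on each side
    assert out.wavelengths_nm[0] == wl[7] and out.wavelengths_nm[-1] == wl[-8]


def test_sg_derivative_kills_offsets(tiny_spectra):
    shifted = tiny_spectra.with_absorbance(tiny_spectra.absorbance + 5.0)
    a = savitzky_golay(tiny_spectra, 5, 2, deriv_order=1)
    b = savitzky_golay(shifted, 5, 2, deriv_order=1)
    np.testing.assert_allclose(a.absorbance, b.absorbance, atol=1e-10)


def test_sg_second_derivative_of_quadratic():
    wl = 1000.0 + np.arange(61)
    coef = 0.04
    out = savitzky_golay(make([coef * wl**2 - wl + 2.0], wl=wl), 11, 3,
                         deriv_order=2)
    np.testing.assert_allclose(out.absorbance, 2.0 * coef, atol=1e-8)


def test_sg_window_one_is_identity(tiny_spectra):
    out = savitzky_golay(tiny_spectra, 1, 0, deriv_order=0)
    np.testing.assert_allclose(out.absorbance, tiny_spectra.absorbance, atol=1e-12)


def test_sg_parameter_validation(tiny_spectra):
    with pytest.raises(ValueError, match="odd"):
        savitzky_golay(tiny_spectra, 4, 2)
    with pytest.raises(ValueError, match="exceed"):
        savitzky_golay(tiny_spectra, 3, 1, deriv_order=2)
    with pytest.raises(ValueError, match="length"):
        savitzky_golay(tiny_spectra, 101, 2)


# ---------------------------------------------------------------- Normalize

def test_normalize_minmax_example():
    out = normalize(make([[2.0, 4.0, 6.0]]), method="minmax")
    np.testing.assert_allclose(out.absorbance[0], [0.0, 0.5, 1.0], atol=1e-12)


def test_normalize_vector_example():
    out = normalize(make([[3.0, 4.0]]), method="vector")
    np.testing.assert_allclose(out.absorbance[0], [0.6, 0.8], atol=1e-12)


def test_normalize_minmax_idempotent(tiny_spectra):
    once = normalize(tiny_spectra, method="minmax")
    twice = normalize(once, method="minmax")
    np.testing.assert_allclose(twice.absorbance, once.absorbance, atol=1e-12)


def test_normalize_degenerate_row():
    with pytest.raises(ValueError, match="constant"):
        normalize(make([[1.0, 1.0, 1.0]]), method="minmax")


# ---------------------------------------------------------------- Baseline

def test_baseline_zeroes_exact_line():
    wl = 1000.0 + np.arange(30)
    out = baseline_correct(make([0.5 * wl - 3.0], wl=wl))
    np.testing.assert_allclose(out.absorbance, 0.0, atol=1e-9)


def test_baseline_removes_linear_trend_and_idempotent(tiny_spectra):
    out = baseline_correct(tiny_spectra)
    wl = out.wavelengths_nm
    design = np.column_stack([np.ones_like(wl), wl])
    coef, *_ = np.linalg.lstsq(design, out.absorbance.T, rcond=None)
    assert np.max(np.abs(coef[1])) < 1e-10  # zero residual slope
    again = baseline_correct(out)
    np.testing.assert_allclose(again.absorbance, out.absorbance, atol=1e-10)


# ---------------------------------------------------------------- chains

def test_empty_chain_is_identity(tiny_spectra):
    out = apply_chain("Original", tiny_spectra)
    np.testing.assert_array_equal(out.absorbance, tiny_spectra.absorbance)
    assert out.chain_label == "Original"


@pytest.mark.parametrize(
    "label",
    ["SNV", "1Der+SNV", "SG+SNV", "SG(window=15,poly=2)+SNV", "2Der", "Baseline+MSC"],
)
def test_chain_label_roundtrip(label):
    chain = parse_chain(label)
    assert parse_chain(chain.label).label == chain.label


def test_chain_order_is_left_to_right(tiny_spectra):
    via_chain = apply_chain("1Der(window=5,poly=2)+SNV", tiny_spectra)
    manual = snv(savitzky_golay(tiny_spectra, 5, 2, deriv_order=1))
    np.testing.assert_allclose(via_chain.absorbance, manual.absorbance, atol=1e-12)


def test_chain_errors_carry_step_index():
    flat = make([[1.0, 1.0, 1.0, 1.0]])
    with pytest.raises(ValueError, match="step 0 \\(SNV\\)"):
        apply_chain("SNV+Baseline", flat)


def test_hyphenated_aliases_accepted():
    assert parse_chain("1-Der+SNV").label == "1Der+SNV"
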