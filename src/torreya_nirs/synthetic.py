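"""Synthetic portable-NIR spectra with known ground truth.

Emulates diffuse-reflectance absorbance spectra of Torreya grandis kernels
in the 1000-1650 nm range: protein-linked Gaussian absorption bands near
1200 nm (C-H stretch) and 1450 nm (N-H stretch), broad oil and water
interferent bands overlapping them, a state-dependent signal attenuation
(shelled < deshelled < granules), per-sample multiplicative scatter
(1 + b) * A + a, a smooth low-order polynomial baseline drift, and i.i.d.
Gaussian measurement noise.  Spectral and chemical outliers can be injected
with their indices recorded, so outlier-screening stages can be scored
against truth.

The clean (pre-distortion) model is linear Beer-Lambert mixing:

    A(lambda) = attenuation * ( p * sum_k amp_k G(lambda; c_k, s_k)
                                + sum_j conc_j amp_j G(lambda; c_j, s_j) )

with p the protein mass fraction (%), G a unit-height Gaussian, and conc_j
interferent concentrations drawn independently of p.  Interferent overlap is
what forces a multivariate calibration: no single wavelength isolates
protein.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import stats

from .spectra import SpectraMatrix, SampleTable

__all__ = [
    "InterferentBand",
    "SyntheticConfig",
    "SyntheticDataset",
    "draw_protein_values",
    "generate_spectra",
    "inject_outliers",
    "simulate",
    "load_config",
    "STATE_ATTENUATION",
]

# Signal attenuation by kernel state: the shell and pseudotesta mask the
# kernel, so less protein-related signal reaches the detector.
STATE_ATTENUATION = {"shell": 0.4, "deshelled": 0.7, "granules": 1.0}


@dataclass(frozen=True)
class InterferentBand:
    """A non-protein constituent band (oil, water) with its own concentration."""

    center_nm: float
    width_nm: float          # Gaussian sigma
    amplitude: float         # absorbance per concentration unit
    conc_mean: float
    conc_sd: float


def _default_interferents() -> tuple[InterferentBand, ...]:
    # Oil C-H combination band near 1210 nm and water O-H first overtone near
    # 1440 nm, both overlapping the protein bands; concentrations in mass %
    # (torreya kernels are oil-rich, granules hold a few % moisture).  A very
    # broad carbohydrate/matrix band centred mid-range supplies the smooth
    # background absorbance level (~0.5 AU) real diffuse-reflectance kernel
    # spectra sit on, which is what gives multiplicative scatter its leverage.
    return (
        InterferentBand(1210.0, 60.0, 0.008, 50.0, 1.5),
        InterferentBand(1440.0, 50.0, 0.020, 5.0, 0.5),
        InterferentBand(1350.0, 300.0, 0.010, 40.0, 1.5),
    )


@dataclass
class SyntheticConfig:
    """Parameters of the synthetic kernel-spectra generator.

    Defaults emulate the study conditions: 124 kernels, protein mass
    fraction spanning 6.46-12.44 % around a 9.64 % mean, absorbance
    measured from 1000 to 1650 nm in 1 nm steps.
    """

    n_samples: int = 124
    wavelength_start_nm: float = 1000.0
    wavelength_end_nm: float = 1650.0
    step_nm: float = 1.0
    protein_min_pct: float = 6.46
    protein_max_pct: float = 12.44
    protein_mean_pct: float = 9.64
    protein_sd_pct: float = 0.90
    band_centers_nm: tuple[float, ...] = (1200.0, 1450.0)
    band_widths_nm: tuple[float, ...] = (30.0, 30.0)
    band_amplitudes: tuple[float, ...] = (0.012, 0.015)  # absorbance per % protein
    interferent_bands: tuple[InterferentBand, ...] = field(
        default_factory=_default_interferents
    )
    state: str = "granules"
    scatter_slope_sd: float = 0.20
    scatter_offset_sd: float = 0.05
    baseline_drift_amplitude: float = 0.02
    noise_sd: float = 5e-4  # AU; 50 accumulated scans on an InGaAs array
    signal_attenuation: float | None = None  # None -> STATE_ATTENUATION[state]
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 2:
            raise ValueError("n_samples must be at least 2")
        if self.protein_min_pct >= self.protein_max_pct:
            raise ValueError(
                "degenerate protein range: min must be strictly below max "
                "(zero-variance response cannot be calibrated)"
            )
        if self.state not in STATE_ATTENUATION:
            raise ValueError(f"unknown state {self.state!r}")
        for name in (
            "protein_sd_pct",
            "scatter_slope_sd",
            "scatter_offset_sd",
            "baseline_drift_amplitude",
            "noise_sd",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not (
            len(self.band_centers_nm)
            == len(self.band_widths_nm)
            == len(self.band_amplitudes)
        ):
            raise ValueError("protein band parameter lists must share a length")
        self.interferent_bands = tuple(
            b if isinstance(b, InterferentBand) else InterferentBand(*b)
            for b in self.interferent_bands
        )

    @property
    def attenuation(self) -> float:
        if self.signal_attenuation is not None:
            return float(self.signal_attenuation)
        return STATE_ATTENUATION[self.state]

    @property
    def wavelengths_nm(self) -> np.ndarray:
        n_pts = int(np.floor(
            (self.wavelength_end_nm - self.wavelength_start_nm) / self.step_nm
        )) + 1
        return self.wavelength_start_nm + self.step_nm * np.arange(n_pts)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["interferent_bands"] = [asdict(b) for b in self.interferent_bands]
        return d


@dataclass
class SyntheticDataset:
    """Spectra plus ground truth and a record of injected outliers."""

    spectra: SpectraMatrix
    samples: SampleTable
    config: SyntheticConfig
    outliers: list[tuple[int, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.spectra.n_samples != self.samples.n_samples:
            raise ValueError("spectra and sample table row counts differ")
        for idx, kind in self.outliers:
            if not 0 <= idx < self.samples.n_samples:
                raise ValueError(f"outlier index {idx} out of range")
            if kind not in ("spectral", "chemical"):
                raise ValueError(f"unknown outlier kind {kind!r}")

    def outlier_indices(self, kind: str) -> np.ndarray:
        return np.array(sorted(i for i, k in self.outliers if k == kind), dtype=int)


def draw_protein_values(config: SyntheticConfig) -> np.ndarray:
    """Draw protein mass fractions (%) from a truncated normal.

    The distribution is Normal(mean, sd) truncated to
    [protein_min_pct, protein_max_pct]; sd = 0 collapses to the mean.
    """
    rng = np.random.default_rng((config.seed, 0))
    if config.protein_sd_pct == 0.0:
        return np.full(config.n_samples, config.protein_mean_pct)
    a = (config.protein_min_pct - config.protein_mean_pct) / config.protein_sd_pct
    b = (config.protein_max_pct - config.protein_mean_pct) / config.protein_sd_pct
    return stats.truncnorm.rvs(
        a,
        b,
        loc=config.protein_mean_pct,
        scale=config.protein_sd_pct,
        size=config.n_samples,
        random_state=rng,
    )


def _gaussian(wl: np.ndarray, center: float, sigma: float) -> np.ndarray:
    return np.exp(-0.5 * ((wl - center) / sigma) ** 2)


def clean_spectra(config: SyntheticConfig, protein: np.ndarray,
                  interferent_conc: np.ndarray | None = None) -> np.ndarray:
    """Noise-, scatter- and drift-free absorbance matrix.

    ``interferent_conc`` is (n, n_bands); when omitted the band means are
    used, which keeps the map from protein to absorbance exactly affine.
    """
    wl = config.wavelengths_nm
    protein = np.asarray(protein, dtype=float)
    signature = np.zeros_like(wl)
    for c, s, amp in zip(
        config.band_centers_nm, config.band_widths_nm, config.band_amplitudes
    ):
        signature += amp * _gaussian(wl, c, s)
    clean = protein[:, None] * signature[None, :]
    for j, band in enumerate(config.interferent_bands):
        shape = band.amplitude * _gaussian(wl, band.center_nm, band.width_nm)
        conc = (
            np.full(protein.size, band.conc_mean)
            if interferent_conc is None
            else interferent_conc[:, j]
        )
        clean += conc[:, None] * shape[None, :]
    return config.attenuation * clean


def generate_spectra(config: SyntheticConfig, protein: np.ndarray) -> SyntheticDataset:
    """Build a full synthetic dataset from protein values.

    Applies, in order: Beer-Lambert mixing with state attenuation,
    per-sample multiplicative scatter (1 + b) * A + a, a random quadratic
    baseline drift, and i.i.d. Gaussian noise.  Deterministic for a fixed
    config (seed included).
    """
    protein = np.asarray(protein, dtype=float)
    if protein.size != config.n_samples:
        raise ValueError(
            f"protein vector has {protein.size} values but config.n_samples is "
            f"{config.n_samples}"
        )
    if not np.all(np.isfinite(protein)) or np.any(protein <= 0):
        raise ValueError("protein values must be finite and positive")

    rng = np.random.default_rng((config.seed, 1))
    n = config.n_samples
    wl = config.wavelengths_nm

    conc = np.empty((n, len(config.interferent_bands)))
    for j, band in enumerate(config.interferent_bands):
        conc[:, j] = np.clip(
            rng.normal(band.conc_mean, band.conc_sd, size=n), 0.0, None
        )
    absorbance = clean_spectra(config, protein, conc)

    # multiplicative scatter: the distortion MSC/SNV are built to remove
    slope = rng.normal(0.0, config.scatter_slope_sd, size=n)
    offset = rng.normal(0.0, config.scatter_offset_sd, size=n)
    absorbance = (1.0 + slope)[:, None] * absorbance + offset[:, None]

    # smooth quadratic baseline drift on a normalized axis
    u = 2.0 * (wl - wl[0]) / (wl[-1] - wl[0]) - 1.0
    drift_coef = rng.normal(0.0, config.baseline_drift_amplitude, size=(n, 3))
    absorbance += (
        drift_coef[:, [0]] + drift_coef[:, [1]] * u[None, :]
        + drift_coef[:, [2]] * u[None, :] ** 2
    )

    absorbance += rng.normal(0.0, config.noise_sd, size=absorbance.shape)

    ids = np.arange(1, n + 1)
    spectra = SpectraMatrix(wl, absorbance, ids)
    samples = SampleTable(ids, protein, config.state)
    return SyntheticDataset(spectra, samples, config)


def inject_outliers(
    dataset: SyntheticDataset,
    spectral_idx=(),
    chemical_idx=(),
    spectral_magnitude: float = 1.0,
    chemical_magnitude: float = 2.0,
    spectral_kind: str = "spike",
    spike_width_nm: float = 5.0,
) -> SyntheticDataset:
    """Return a copy of ``dataset`` with outliers injected and recorded.

    Spectral outliers receive a large additive artifact: a narrow Gaussian
    spike of ``spectral_magnitude`` absorbance at a random wavelength
    (``spectral_kind="spike"``, default) or a flat offset
    (``spectral_kind="offset"``; note a flat offset is removed exactly by
    SNV and is therefore invisible to an SNV-based screen).  Chemical
    outliers have their *recorded* protein value shifted by
    ±``chemical_magnitude`` % (alternating sign), leaving the spectrum
    untouched, which mimics a reference-method blunder.
    """
    spectral_idx = np.asarray(sorted(spectral_idx), dtype=int)
    chemical_idx = np.asarray(sorted(chemical_idx), dtype=int)
    if np.intersect1d(spectral_idx, chemical_idx).size:
        raise ValueError("spectral and chemical outlier index sets must be disjoint")
    n = dataset.samples.n_samples
    for idx in np.concatenate([spectral_idx, chemical_idx]):
        if not 0 <= idx < n:
            raise ValueError(f"outlier index {idx} out of range for {n} samples")
    if spectral_kind not in ("spike", "offset"):
        raise ValueError(f"unknown spectral_kind {spectral_kind!r}")

    rng = np.random.default_rng((dataset.config.seed, 2))
    absorbance = dataset.spectra.absorbance.copy()
    protein = dataset.samples.protein_pct.copy()
    wl = dataset.spectra.wavelengths_nm

    for idx in spectral_idx:
        if spectral_kind == "offset":
            absorbance[idx] += spectral_magnitude
        else:
            center = rng.uniform(wl[0] + 50.0, wl[-1] - 50.0)
            absorbance[idx] += spectral_magnitude * _gaussian(
                wl, center, spike_width_nm
            )
    for pos, idx in enumerate(chemical_idx):
        sign = 1.0 if pos % 2 == 0 else -1.0
        protein[idx] += sign * chemical_magnitude

    outliers = list(dataset.outliers)
    outliers += [(int(i), "spectral") for i in spectral_idx]
    outliers += [(int(i), "chemical") for i in chemical_idx]
    spectra = SpectraMatrix(wl.copy(), absorbance, dataset.spectra.sample_ids.copy())
    samples = SampleTable(
        dataset.samples.sample_ids.copy(), protein, dataset.samples.state
    )
    return SyntheticDataset(spectra, samples, dataset.config, outliers)


def simulate(config: SyntheticConfig) -> SyntheticDataset:
    """Draw protein values and generate the matching spectra in one call."""
    return generate_spectra(config, draw_protein_values(config))


def load_config(path) -> SyntheticConfig:
    """Read a SyntheticConfig from a JSON or YAML file (field names 1:1)."""
    text = open(path, encoding="utf-8").read()
    if str(path).endswith((".yaml", ".yml")):
        import yaml

        raw = yaml.safe_load(text)
    else:
        raw = json.loads(text)
    if "seed" not in raw:
        raise ValueError("config must set an explicit seed")
    if "interferent_bands" in raw:
        raw["interferent_bands"] = tuple(
            InterferentBand(**b) if isinstance(b, dict) else InterferentBand(*b)
            for b in raw["interferent_bands"]
        )
    for key in ("band_centers_nm", "band_widths_nm", "band_amplitudes"):
        if key in raw:
            raw[key] = tuple(raw[key])
    return SyntheticConfig(**raw)
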