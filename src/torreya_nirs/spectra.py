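"""In-memory containers and CSV I/O for NIR spectra tables.

The on-disk interchange format is a wide CSV: one row per sample, columns
``sample_id``, ``protein_pct``, then one column per wavelength named by the
integer wavelength in nm ("1000" ... "1650").
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["SpectraMatrix", "SampleTable", "read_wide_csv", "write_wide_csv"]


@dataclass
class SpectraMatrix:
    """Absorbance matrix with an explicit wavelength axis.

    Parameters
    ----------
    wavelengths_nm : (m,) strictly increasing wavelength axis in nm.
    absorbance : (n, m) absorbance values, one row per sample.
    sample_ids : (n,) sample identifiers.
    """

    wavelengths_nm: np.ndarray
    absorbance: np.ndarray
    sample_ids: np.ndarray

    def __post_init__(self) -> None:
        self.wavelengths_nm = np.asarray(self.wavelengths_nm, dtype=float)
        self.absorbance = np.atleast_2d(np.asarray(self.absorbance, dtype=float))
        self.sample_ids = np.asarray(self.sample_ids)
        if self.wavelengths_nm.ndim != 1:
            raise ValueError("wavelength axis must be 1-D")
        if np.any(np.diff(self.wavelengths_nm) <= 0):
            raise ValueError("wavelength axis must be strictly increasing")
        n, m = self.absorbance.shape
        if m != self.wavelengths_nm.size:
            raise ValueError(
                f"absorbance has {m} columns but wavelength axis has "
                f"{self.wavelengths_nm.size} points"
            )
        if self.sample_ids.size != n:
            raise ValueError(
                f"{n} spectra but {self.sample_ids.size} sample ids"
            )
        if not np.all(np.isfinite(self.absorbance)):
            raise ValueError("absorbance contains NaN or Inf")

    @property
    def n_samples(self) -> int:
        return self.absorbance.shape[0]

    @property
    def n_wavelengths(self) -> int:
        return self.absorbance.shape[1]

    def copy(self) -> "SpectraMatrix":
        return SpectraMatrix(
            self.wavelengths_nm.copy(),
            self.absorbance.copy(),
            self.sample_ids.copy(),
        )

    def take(self, indices) -> "SpectraMatrix":
        """Row subset preserving order of ``indices``."""
        idx = np.asarray(indices, dtype=int)
        return SpectraMatrix(
            self.wavelengths_nm.copy(),
            self.absorbance[idx],
            self.sample_ids[idx],
        )

    def with_absorbance(
        self, absorbance: np.ndarray, wavelengths_nm: np.ndarray | None = None
    ) -> "SpectraMatrix":
        """New matrix with replaced values (and optionally a new axis)."""
        axis = self.wavelengths_nm if wavelengths_nm is None else wavelengths_nm
        return SpectraMatrix(np.asarray(axis), absorbance, self.sample_ids.copy())


@dataclass
class SampleTable:
    """Per-sample reference data: id, measured protein mass fraction (%), state."""

    sample_ids: np.ndarray
    protein_pct: np.ndarray
    state: str = "granules"

    def __post_init__(self) -> None:
        self.sample_ids = np.asarray(self.sample_ids)
        self.protein_pct = np.asarray(self.protein_pct, dtype=float)
        if self.sample_ids.size != self.protein_pct.size:
            raise ValueError("sample_ids and protein_pct lengths differ")

    @property
    def n_samples(self) -> int:
        return self.sample_ids.size

    def take(self, indices) -> "SampleTable":
        idx = np.asarray(indices, dtype=int)
        return SampleTable(self.sample_ids[idx], self.protein_pct[idx], self.state)


def write_wide_csv(path, spectra: SpectraMatrix, protein_pct: np.ndarray) -> None:
    """Write the wide interchange CSV (UTF-8, '.' decimal, header row)."""
    protein = np.asarray(protein_pct, dtype=float)
    if protein.size != spectra.n_samples:
        raise ValueError("protein vector length does not match spectra")
    cols = {"sample_id": spectra.sample_ids, "protein_pct": protein}
    frame = pd.DataFrame(cols)
    wl_names = [str(int(round(w))) for w in spectra.wavelengths_nm]
    spec_frame = pd.DataFrame(spectra.absorbance, columns=wl_names)
    pd.concat([frame, spec_frame], axis=1).to_csv(path, index=False, encoding="utf-8")


def read_wide_csv(path, state: str = "granules") -> tuple[SpectraMatrix, SampleTable]:
    """Read the wide interchange CSV back into containers."""
    frame = pd.read_csv(path, encoding="utf-8")
    required = {"sample_id", "protein_pct"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"missing required columns: {sorted(missing)}")
    wl_cols = [c for c in frame.columns if c not in required]
    wavelengths = np.array([float(c) for c in wl_cols])
    order = np.argsort(wavelengths)
    spectra = SpectraMatrix(
        wavelengths[order],
        frame[wl_cols].to_numpy(dtype=float)[:, order],
        frame["sample_id"].to_numpy(),
    )
    samples = SampleTable(
        frame["sample_id"].to_numpy(),
        frame["protein_pct"].to_numpy(dtype=float),
        state,
    )
    return spectra, samples
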