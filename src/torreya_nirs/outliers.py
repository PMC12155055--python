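"""Two-stage outlier screening for NIR calibration sets.

Stage 1 (spectral): PCA scores of the state-appropriate preprocessed spectra
are reduced to a Mahalanobis distance (MD) from the score centroid, and
samples beyond a robust gate — median(MD) + 3 x MAD(MD) — are flagged as
spectral outliers (instrument artifacts, bad presentation).

Stage 2 (chemical): on the survivors, a preliminary PLSR is cross-validated
(LVs by the one-SE rule) and samples whose out-of-fold concentration
residual |measured - predicted| exceeds 0.4 % protein are flagged as
chemical outliers (reference-method blunders, atypical composition).

Default PCA preprocessing per kernel state mirrors the workflow this
pipeline reproduces: Normalize for shelled kernels, MSC for deshelled,
SNV for granules.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .plsr import cross_validate
from .preprocess import apply_chain
from .spectra import SpectraMatrix
from .synthetic import SyntheticDataset

__all__ = [
    "PCAScores",
    "OutlierReport",
    "pca_scores",
    "mahalanobis_distances",
    "md_gate",
    "residual_gate",
    "screen",
    "STATE_PCA_PREPROCESSING",
    "RESIDUAL_THRESHOLD_PCT",
]

STATE_PCA_PREPROCESSING = {
    "shell": "Normalize",
    "deshelled": "MSC",
    "granules": "SNV",
}
RESIDUAL_THRESHOLD_PCT = 0.4
DEFAULT_PCA_COMPONENTS = 4


@dataclass
class PCAScores:
    scores: np.ndarray                   # n x k
    explained_variance_ratio: np.ndarray
    preprocessing_label: str = ""


@dataclass
class OutlierReport:
    """Both screening stages, kept separate so the report mirrors the
    two-row-per-state layout of published outlier tables."""

    md_values: np.ndarray
    md_threshold: float
    md_flagged: np.ndarray               # positions in the input
    residuals: np.ndarray                # per survivor, measured - predicted
    residual_threshold: float
    residual_flagged: np.ndarray         # positions in the input
    sample_ids: np.ndarray
    state: str = ""

    @property
    def removed(self) -> np.ndarray:
        return np.unique(np.concatenate([self.md_flagged, self.residual_flagged]))

    def retained(self, n: int) -> np.ndarray:
        return np.setdiff1d(np.arange(n), self.removed)

    def to_frame(self) -> pd.DataFrame:
        rows = [("PCA-MD", self.sample_ids[i]) for i in self.md_flagged]
        rows += [
            ("Concentration residual", self.sample_ids[i])
            for i in self.residual_flagged
        ]
        return pd.DataFrame(rows, columns=["stage", "sample_id"])

    def to_json(self) -> str:
        return json.dumps(
            {
                "state": self.state,
                "md_threshold": float(self.md_threshold),
                "md_flagged_ids": self.sample_ids[self.md_flagged].tolist(),
                "residual_threshold": float(self.residual_threshold),
                "residual_flagged_ids": self.sample_ids[
                    self.residual_flagged
                ].tolist(),
                "n_removed": int(self.removed.size),
            },
            indent=2,
        )


def pca_scores(spectra: SpectraMatrix, k: int = DEFAULT_PCA_COMPONENTS) -> PCAScores:
    """Column-mean-centered PCA via SVD; top-k scores and variance ratios.

    Sign convention: within each component, the loading element with the
    largest magnitude is made positive, so scores are reproducible across
    platforms.
    """
    x = spectra.absorbance
    n, m = x.shape
    if k < 1:
        raise ValueError("k must be >= 1")
    if k >= min(n, m):
        raise ValueError(f"k={k} must be below min(n, m) = {min(n, m)}")
    xc = x - x.mean(axis=0)
    u, s, vt = np.linalg.svd(xc, full_matrices=False)
    flip = np.sign(vt[np.arange(vt.shape[0]), np.abs(vt).argmax(axis=1)])
    flip[flip == 0] = 1.0
    vt = vt * flip[:, None]
    u = u * flip[None, :]  # flip U columns in step with V so U S V' = Xc
    scores = u[:, :k] * s[:k]
    var = s**2
    ratio = var[:k] / var.sum() if var.sum() > 0 else np.zeros(k)
    return PCAScores(scores=scores, explained_variance_ratio=ratio)


def mahalanobis_distances(scores: PCAScores, reg_scale: float = 1e-10) -> np.ndarray:
    """MD of each score row from the centroid under the sample covariance.

    A singular covariance is regularized once by adding
    ``reg_scale * trace / k`` to the diagonal; if still singular, an error is
    raised.
    """
    s = np.atleast_2d(scores.scores if isinstance(scores, PCAScores) else scores)
    centered = s - s.mean(axis=0)
    k = s.shape[1]
    cov = np.cov(centered, rowvar=False, ddof=1).reshape(k, k)
    try:
        solved = np.linalg.solve(cov, centered.T)
    except np.linalg.LinAlgError:
        ridge = reg_scale * np.trace(cov) / k
        warnings.warn(
            f"singular score covariance: regularized with ridge {ridge:.3e}",
            RuntimeWarning,
            stacklevel=2,
        )
        try:
            solved = np.linalg.solve(cov + ridge * np.eye(k), centered.T)
        except np.linalg.LinAlgError as err:
            raise np.linalg.LinAlgError(
                "score covariance singular even after regularization"
            ) from err
    return np.sqrt(np.einsum("ij,ji->i", centered, solved))


def md_gate(md: np.ndarray) -> tuple[float, np.ndarray]:
    """Robust gate: flag MD above median(MD) + 3 x MAD(MD).

    MAD is the raw median absolute deviation (no normal-consistency
    scaling).  A zero MAD (all distances equal) flags nothing and warns.
    """
    md = np.asarray(md, dtype=float)
    if md.size < 4:
        raise ValueError("need at least 4 samples to gate on MAD")
    med = float(np.median(md))
    mad = float(np.median(np.abs(md - med)))
    threshold = med + 3.0 * mad
    if mad == 0.0:
        warnings.warn(
            "MAD of Mahalanobis distances is zero; gate is degenerate and "
            "flags nothing",
            RuntimeWarning,
            stacklevel=2,
        )
        return threshold, np.array([], dtype=int)
    return threshold, np.flatnonzero(md > threshold)


def residual_gate(
    measured: np.ndarray,
    predicted: np.ndarray,
    threshold: float = RESIDUAL_THRESHOLD_PCT,
) -> np.ndarray:
    """Flag samples with |measured - predicted| strictly above threshold (%)."""
    measured = np.asarray(measured, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    if measured.shape != predicted.shape:
        raise ValueError("measured and predicted lengths differ")
    return np.flatnonzero(np.abs(measured - predicted) > threshold)


def screen(
    dataset: SyntheticDataset,
    pca_preprocessing: str | None = None,
    k: int = DEFAULT_PCA_COMPONENTS,
    residual_threshold: float = RESIDUAL_THRESHOLD_PCT,
    cv_folds: int = 10,
    cv_a_max: int = 12,
    seed: int = 0,
) -> OutlierReport:
    """Run both gates in order and report stage membership separately.

    The residual stage uses out-of-fold predictions from a preliminary
    cross-validated PLSR (LVs by the one-SE rule) fitted on the MD-stage
    survivors, so residuals are not biased by self-fitting.
    """
    state = dataset.samples.state
    label = pca_preprocessing or STATE_PCA_PREPROCESSING.get(state, "SNV")

    pre = apply_chain(label, dataset.spectra)
    scores = pca_scores(pre, k=k)
    scores.preprocessing_label = label
    md = mahalanobis_distances(scores)
    threshold, md_flagged = md_gate(md)

    survivors = np.setdiff1d(np.arange(dataset.samples.n_samples), md_flagged)
    surv_spectra = apply_chain(label, dataset.spectra.take(survivors))
    y = dataset.samples.protein_pct[survivors]
    cv = cross_validate(
        surv_spectra.absorbance, y, a_max=cv_a_max, folds=cv_folds, seed=seed
    )
    residuals = y - cv.chosen_predictions()
    res_flagged_local = residual_gate(
        y, cv.chosen_predictions(), threshold=residual_threshold
    )
    return OutlierReport(
        md_values=md,
        md_threshold=threshold,
        md_flagged=md_flagged,
        residuals=residuals,
        residual_threshold=residual_threshold,
        residual_flagged=survivors[res_flagged_local],
        sample_ids=dataset.samples.sample_ids,
        state=state,
    )
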