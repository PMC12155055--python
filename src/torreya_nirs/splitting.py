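"""SPXY calibration/prediction partitioning.

SPXY (sample-set partitioning based on joint X-Y distances) runs the
Kennard-Stone algorithm on a combined metric

    d(i, j) = d_x(i, j) / max d_x + d_y(i, j) / max d_y

with Euclidean d_x on spectra and |y_i - y_j| on the response, so the
calibration set covers both spectral and concentration space.  Selection is
fully deterministic; ties break to the lowest index.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import squareform, pdist

from .spectra import SpectraMatrix

__all__ = ["SplitResult", "spxy_split", "random_split"]


@dataclass
class SplitResult:
    calibration_indices: np.ndarray
    prediction_indices: np.ndarray
    ratio: float

    def __post_init__(self) -> None:
        cal = np.asarray(self.calibration_indices, dtype=int)
        pred = np.asarray(self.prediction_indices, dtype=int)
        if np.intersect1d(cal, pred).size:
            raise ValueError("calibration and prediction sets overlap")
        self.calibration_indices = np.sort(cal)
        self.prediction_indices = np.sort(pred)

    @property
    def n_total(self) -> int:
        return self.calibration_indices.size + self.prediction_indices.size

    def to_frame(self, sample_ids: np.ndarray) -> pd.DataFrame:
        rows = [(sample_ids[i], "calibration") for i in self.calibration_indices]
        rows += [(sample_ids[i], "prediction") for i in self.prediction_indices]
        frame = pd.DataFrame(rows, columns=["sample_id", "set"])
        return frame.sort_values("sample_id", kind="stable").reset_index(drop=True)


def calibration_size(n: int, ratio: float) -> int:
    """Nearest-integer size with halves rounding up (113 * 0.75 -> 85)."""
    return int(np.floor(n * ratio + 0.5))


def spxy_split(
    spectra: SpectraMatrix | np.ndarray,
    y: np.ndarray,
    ratio: float = 0.75,
) -> SplitResult:
    """Deterministic SPXY split at the given calibration fraction.

    Kennard-Stone on the joint distance: seed with the pair at maximal d,
    then repeatedly add the sample whose minimum distance to the selected
    set is largest, until the calibration size is reached.  The response
    extremes are guaranteed to end up in the calibration set (they are
    swapped in if the selection missed them), so the calibration range
    brackets the prediction range.
    """
    x = spectra.absorbance if isinstance(spectra, SpectraMatrix) else np.asarray(spectra)
    y = np.asarray(y, dtype=float).ravel()
    n = y.size
    if x.shape[0] != n:
        raise ValueError("spectra and response have different sample counts")
    if n < 4:
        raise ValueError("need at least 4 samples to split")
    if np.allclose(y, y[0]):
        raise ValueError("degenerate response: y is constant")
    if not 0.0 < ratio < 1.0:
        raise ValueError("ratio must be in (0, 1)")

    dx = squareform(pdist(x, metric="euclidean"))
    dy = np.abs(y[:, None] - y[None, :])
    if dx.max() == 0:
        raise ValueError("degenerate spectra: all rows identical")
    d = dx / dx.max() + dy / dy.max()

    n_cal = calibration_size(n, ratio)
    n_cal = min(max(n_cal, 2), n - 1)

    # seed with the maximal-distance pair; ties -> lexicographically lowest
    flat = np.argmax(d)  # argmax scans row-major, so first max wins
    i, j = divmod(flat, n)
    selected = [min(i, j), max(i, j)]
    in_set = np.zeros(n, dtype=bool)
    in_set[selected] = True
    min_dist = np.minimum(d[selected[0]], d[selected[1]])
    while len(selected) < n_cal:
        min_dist[in_set] = -np.inf
        nxt = int(np.argmax(min_dist))  # argmax returns the lowest tied index
        selected.append(nxt)
        in_set[nxt] = True
        min_dist = np.minimum(min_dist, d[nxt])

    # guarantee the y extremes are calibrated on
    for extreme in (int(np.argmin(y)), int(np.argmax(y))):
        if not in_set[extreme]:
            order = [s for s in selected if s not in
                     (int(np.argmin(y)), int(np.argmax(y)))]
            swap_out = order[-1]
            selected.remove(swap_out)
            in_set[swap_out] = False
            selected.append(extreme)
            in_set[extreme] = True

    cal = np.array(sorted(selected), dtype=int)
    pred = np.setdiff1d(np.arange(n), cal)
    return SplitResult(cal, pred, ratio)


def random_split(
    n: int, ratio: float = 0.75, seed: int = 0
) -> SplitResult:
    """Seeded uniform split, for comparison experiments only."""
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    n_cal = calibration_size(n, ratio)
    return SplitResult(perm[:n_cal], perm[n_cal:], ratio)
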