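"""Partial least squares regression (PLS1, NIPALS) with one-SE model selection.

The regression links preprocessed absorbance spectra (n samples x m
wavelengths, heavily collinear) to protein mass fraction (%).  Components
("latent variables", LVs) are extracted by NIPALS with deflation; the number
of LVs is chosen by cross-validation with the one-standard-error rule: take
the fewest LVs whose RMSECV is within one standard error of the minimum.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = ["PLSRModel", "CVResult", "fit_plsr", "predict", "cross_validate",
           "one_se_choice"]

CONVERGENCE_TOL = 1e-10
MAX_INNER_ITER = 500


@dataclass
class PLSRModel:
    """Fitted PLS1 model in both factor and collapsed-coefficient form."""

    wavelengths_nm: np.ndarray
    x_mean: np.ndarray
    y_mean: float
    weights: np.ndarray        # m x A
    x_loadings: np.ndarray     # m x A
    y_loadings: np.ndarray     # A
    regression_coefficients: np.ndarray  # m, for mean-centered X
    n_latent: int
    chain_label: str = ""
    split_id: str = ""

    def to_dict(self) -> dict:
        return {
            "wavelengths_nm": self.wavelengths_nm.tolist(),
            "x_mean": self.x_mean.tolist(),
            "y_mean": float(self.y_mean),
            "regression_coefficients": self.regression_coefficients.tolist(),
            "n_latent": int(self.n_latent),
            "chain_label": self.chain_label,
            "split_id": self.split_id,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PLSRModel":
        m = len(d["x_mean"])
        a = int(d["n_latent"])
        return cls(
            wavelengths_nm=np.asarray(d["wavelengths_nm"], dtype=float),
            x_mean=np.asarray(d["x_mean"], dtype=float),
            y_mean=float(d["y_mean"]),
            weights=np.zeros((m, a)),
            x_loadings=np.zeros((m, a)),
            y_loadings=np.zeros(a),
            regression_coefficients=np.asarray(
                d["regression_coefficients"], dtype=float
            ),
            n_latent=a,
            chain_label=d.get("chain_label", ""),
            split_id=d.get("split_id", ""),
        )


@dataclass
class CVResult:
    """Cross-validation curve and the one-SE choice."""

    rmsecv: np.ndarray         # indexed by A-1 for A = 1..A_max
    se: np.ndarray             # per-A standard error across folds
    chosen_a: int
    fold_assignment: np.ndarray
    oof_predictions: np.ndarray | None = None  # (A_max, n) out-of-fold

    def chosen_predictions(self) -> np.ndarray:
        """Out-of-fold predictions at the one-SE-chosen A."""
        if self.oof_predictions is None:
            raise ValueError("out-of-fold predictions were not stored")
        return self.oof_predictions[self.chosen_a - 1]


def _nipals(x: np.ndarray, y: np.ndarray, n_components: int):
    """NIPALS with deflation on centered data; returns W, P (m x A), q (A)."""
    n, m = x.shape
    xd = x.copy()
    yd = y.copy()
    weights, loadings, yloads = [], [], []
    for _ in range(n_components):
        w = xd.T @ yd
        # generic NIPALS inner loop; converges in one pass for univariate y
        for _ in range(MAX_INNER_ITER):
            norm = np.linalg.norm(w)
            if norm < np.finfo(float).eps * 100:
                break
            w = w / norm
            t = xd @ w
            tt = t @ t
            if tt == 0:
                break
            q = (yd @ t) / tt
            w_new = xd.T @ (yd * q)
            nn = np.linalg.norm(w_new)
            if nn == 0 or np.linalg.norm(w_new / nn - w) < CONVERGENCE_TOL:
                w = w_new / nn if nn > 0 else w
                break
            w = w_new
        norm = np.linalg.norm(w)
        if norm < np.finfo(float).eps * 100:
            warnings.warn(
                "vanishing weight norm: stopping early with "
                f"{len(weights)} component(s)",
                RuntimeWarning,
                stacklevel=3,
            )
            break
        w = w / norm
        t = xd @ w
        tt = t @ t
        if tt == 0:
            warnings.warn(
                "degenerate score vector: stopping early with "
                f"{len(weights)} component(s)",
                RuntimeWarning,
                stacklevel=3,
            )
            break
        p = xd.T @ t / tt
        q = (yd @ t) / tt
        xd = xd - np.outer(t, p)
        yd = yd - q * t
        weights.append(w)
        loadings.append(p)
        yloads.append(q)
    wmat = np.column_stack(weights) if weights else np.zeros((m, 0))
    pmat = np.column_stack(loadings) if loadings else np.zeros((m, 0))
    return wmat, pmat, np.asarray(yloads)


def _coefficients(w: np.ndarray, p: np.ndarray, q: np.ndarray) -> np.ndarray:
    if w.shape[1] == 0:
        return np.zeros(w.shape[0])
    # B = W (P' W)^-1 q
    return w @ np.linalg.solve(p.T @ w, q)


def fit_plsr(
    x: np.ndarray,
    y: np.ndarray,
    n_components: int,
    wavelengths_nm: np.ndarray | None = None,
    chain_label: str = "",
) -> PLSRModel:
    """Fit PLS1 by NIPALS on mean-centered data.

    ``n_components`` may be reduced if a weight vector degenerates (rank
    exhausted); a warning is emitted in that case.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, m = x.shape
    if y.size != n:
        raise ValueError("X and y have different sample counts")
    if n < n_components + 1:
        raise ValueError(
            f"need at least n_components + 1 = {n_components + 1} samples, got {n}"
        )
    if np.allclose(y, y[0]):
        raise ValueError("zero-variance response: nothing to regress on")
    x_mean = x.mean(axis=0)
    y_mean = float(y.mean())
    w, p, q = _nipals(x - x_mean, y - y_mean, n_components)
    coef = _coefficients(w, p, q)
    if wavelengths_nm is None:
        wavelengths_nm = np.arange(m, dtype=float)
    return PLSRModel(
        wavelengths_nm=np.asarray(wavelengths_nm, dtype=float),
        x_mean=x_mean,
        y_mean=y_mean,
        weights=w,
        x_loadings=p,
        y_loadings=q,
        regression_coefficients=coef,
        n_latent=w.shape[1],
        chain_label=chain_label,
    )


def predict(model: PLSRModel, x: np.ndarray,
            wavelengths_nm: np.ndarray | None = None) -> np.ndarray:
    """Predict protein (%) as y_mean + (X - x_mean) B."""
    x = np.atleast_2d(np.asarray(x, dtype=float))
    if wavelengths_nm is not None:
        wl = np.asarray(wavelengths_nm, dtype=float)
        if wl.size != model.wavelengths_nm.size or not np.allclose(
            wl, model.wavelengths_nm
        ):
            raise ValueError(
                f"wavelength axis mismatch: model axis "
                f"[{model.wavelengths_nm[0]}..{model.wavelengths_nm[-1]}] "
                f"({model.wavelengths_nm.size} pts) vs input "
                f"[{wl[0]}..{wl[-1]}] ({wl.size} pts)"
            )
    if x.shape[1] != model.x_mean.size:
        raise ValueError(
            f"input has {x.shape[1]} wavelengths, model expects {model.x_mean.size}"
        )
    return model.y_mean + (x - model.x_mean) @ model.regression_coefficients


def _prediction_path(x_train, y_train, x_test, a_max) -> np.ndarray:
    """Test-set predictions for every A = 1..a_max from one NIPALS pass."""
    x_mean = x_train.mean(axis=0)
    y_mean = y_train.mean()
    w, p, q = _nipals(x_train - x_mean, y_train - y_mean, a_max)
    a_fit = w.shape[1]
    preds = np.empty((a_max, x_test.shape[0]))
    xc = x_test - x_mean
    for a in range(1, a_max + 1):
        a_eff = min(a, a_fit)
        if a_eff == 0:
            preds[a - 1] = y_mean
        else:
            coef = _coefficients(w[:, :a_eff], p[:, :a_eff], q[:a_eff])
            preds[a - 1] = y_mean + xc @ coef
    return preds


def one_se_choice(rmsecv: np.ndarray, se: np.ndarray) -> int:
    """Fewest LVs with RMSECV within one SE of the minimum (1-based A)."""
    rmsecv = np.asarray(rmsecv, dtype=float)
    se = np.asarray(se, dtype=float)
    a_star = int(np.argmin(rmsecv))
    cutoff = rmsecv[a_star] + se[a_star]
    return int(np.flatnonzero(rmsecv <= cutoff)[0]) + 1


def cross_validate(
    x: np.ndarray,
    y: np.ndarray,
    a_max: int,
    folds: int = 10,
    seed: int = 0,
) -> CVResult:
    """K-fold CV over A = 1..a_max with venetian-blind folds after a shuffle.

    RMSECV(A) pools out-of-fold residuals; SE(A) is the standard deviation of
    per-fold RMSEs divided by sqrt(folds).  The chosen A follows the one-SE
    rule.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n = y.size
    if not 2 <= folds <= n:
        raise ValueError(f"folds must be in [2, n={n}]")
    max_train = n - int(np.ceil(n / folds))
    if a_max > max_train - 1:
        warnings.warn(
            f"a_max={a_max} too large for fold size; capped at {max_train - 1}",
            RuntimeWarning,
            stacklevel=2,
        )
        a_max = max_train - 1
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    fold_of = np.empty(n, dtype=int)
    fold_of[perm] = np.arange(n) % folds  # venetian blinds on shuffled order

    oof = np.empty((a_max, n))
    fold_rmse = np.empty((a_max, folds))
    for f in range(folds):
        test = fold_of == f
        preds = _prediction_path(x[~test], y[~test], x[test], a_max)
        oof[:, test] = preds
        fold_rmse[:, f] = np.sqrt(((preds - y[test]) ** 2).mean(axis=1))
    rmsecv = np.sqrt(((oof - y) ** 2).mean(axis=1))
    se = fold_rmse.std(axis=1, ddof=1) / np.sqrt(folds)
    return CVResult(
        rmsecv=rmsecv,
        se=se,
        chosen_a=one_se_choice(rmsecv, se),
        fold_assignment=fold_of,
        oof_predictions=oof,
    )
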