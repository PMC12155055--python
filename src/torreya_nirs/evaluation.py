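"""Model evaluation metrics and the Kjeldahl protein formula.

Metrics follow the standard chemometrics definitions:

* R² = 1 - SS_res / SS_tot, computed on the calibration set (Rc²) or the
  prediction set (Rp²) with that set's own measured mean in the denominator.
* RMSEC / RMSEP = sqrt(mean squared residual) on the respective set
  (divide by n, not n - 1).
* RPD = SD / RMSEP, with SD the sample standard deviation (n - 1) of the
  measured prediction-set values.  Above ~2.5 is considered good.
* RER = (max - min of measured prediction-set values) / RMSEP.  Above ~15
  is considered good.
* prediction_fit: slope of the least-squares line predicted ~ measured and
  bias = mean(predicted - measured), the usual validation-scatter summary.

The Kjeldahl conversion turns titration volumes into protein mass fraction:
W (%) = (v1 - v2) * N * 0.014 * F / m * 100, where 0.014 g/mmol is the
millimolar mass of nitrogen and F the nitrogen-to-protein coefficient.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "KjeldahlInputs",
    "kjeldahl_protein",
    "r_squared",
    "rmse",
    "rpd",
    "rer",
    "prediction_fit",
    "EvalReport",
    "evaluate_sets",
]


@dataclass(frozen=True)
class KjeldahlInputs:
    """Titration quantities for one Kjeldahl determination."""

    v1_ml: float          # blank titration volume (mL)
    v2_ml: float          # sample titration volume (mL)
    hcl_molarity: float   # N (mol/L)
    protein_factor: float  # F, nitrogen-to-protein conversion
    sample_mass_g: float

    def __post_init__(self) -> None:
        if self.sample_mass_g <= 0:
            raise ValueError("sample mass must be positive")
        if self.hcl_molarity <= 0:
            raise ValueError("HCl molarity must be positive")
        if self.v1_ml < 0 or self.v2_ml < 0:
            raise ValueError("titration volumes cannot be negative")


def kjeldahl_protein(inp: KjeldahlInputs) -> float:
    """Protein mass fraction (%) from Kjeldahl titration volumes."""
    w = (
        (inp.v1_ml - inp.v2_ml)
        * inp.hcl_molarity
        * 0.014
        * inp.protein_factor
        / inp.sample_mass_g
        * 100.0
    )
    if w < 0:
        warnings.warn(
            "negative protein fraction: blank consumed less titrant than the "
            "sample (titration inversion?)",
            RuntimeWarning,
            stacklevel=2,
        )
    return w


def _pair(measured, predicted, min_n: int):
    measured = np.asarray(measured, dtype=float).ravel()
    predicted = np.asarray(predicted, dtype=float).ravel()
    if measured.size != predicted.size:
        raise ValueError("measured and predicted lengths differ")
    if measured.size < min_n:
        raise ValueError(f"need at least {min_n} samples")
    return measured, predicted


def r_squared(measured, predicted, reference_mean: float | None = None) -> float:
    """Coefficient of determination 1 - SS_res / SS_tot.

    ``reference_mean`` defaults to the mean of ``measured`` (the evaluated
    set's own mean).
    """
    measured, predicted = _pair(measured, predicted, 2)
    mean = float(np.mean(measured)) if reference_mean is None else reference_mean
    ss_tot = float(np.sum((measured - mean) ** 2))
    if ss_tot == 0:
        raise ValueError("zero total sum of squares: measured values constant")
    return 1.0 - float(np.sum((measured - predicted) ** 2)) / ss_tot


def rmse(measured, predicted) -> float:
    """Root mean square error with an n denominator."""
    measured, predicted = _pair(measured, predicted, 1)
    return float(np.sqrt(np.mean((measured - predicted) ** 2)))


def rpd(measured_prediction_set, rmsep: float) -> float:
    """Ratio of performance to deviation: prediction-set SD / RMSEP."""
    m = np.asarray(measured_prediction_set, dtype=float).ravel()
    if m.size < 2:
        raise ValueError("need at least 2 prediction-set samples")
    if rmsep <= 0:
        raise ValueError("RMSEP must be positive")
    return float(m.std(ddof=1)) / rmsep


def rer(measured_prediction_set, rmsep: float) -> float:
    """Ratio of error range: prediction-set (max - min) / RMSEP."""
    m = np.asarray(measured_prediction_set, dtype=float).ravel()
    if m.size < 2:
        raise ValueError("need at least 2 prediction-set samples")
    if rmsep <= 0:
        raise ValueError("RMSEP must be positive")
    return float(m.max() - m.min()) / rmsep


def prediction_fit(measured, predicted) -> tuple[float, float]:
    """(slope, bias) of the validation scatter.

    Slope from the least-squares line predicted ~ measured; bias is the mean
    signed error mean(predicted - measured).
    """
    measured, predicted = _pair(measured, predicted, 2)
    if np.allclose(measured, measured[0]):
        raise ValueError("constant measured values: slope undefined")
    mc = measured - measured.mean()
    slope = float(mc @ (predicted - predicted.mean()) / (mc @ mc))
    bias = float(np.mean(predicted - measured))
    return slope, bias


@dataclass
class EvalReport:
    """Full metric panel for one (state x preprocessing chain) model."""

    chain_label: str
    n_latent: int
    r2_cal: float
    rmsec: float
    r2_pred: float
    rmsep: float
    rpd: float
    rer: float
    n_cal: int
    n_pred: int
    sd_pred_measured: float
    range_pred_measured: float
    slope: float
    bias: float
    state: str = ""

    def to_row(self) -> dict:
        """Table row matching the published report layout (2 dp)."""
        return {
            "state": self.state,
            "chain": self.chain_label,
            "n_latent": self.n_latent,
            "Rc2": round(self.r2_cal, 2),
            "RMSEC": round(self.rmsec, 2),
            "Rp2": round(self.r2_pred, 2),
            "RMSEP": round(self.rmsep, 2),
            "RPD": round(self.rpd, 2),
            "RER": round(self.rer, 2),
        }


def evaluate_sets(
    y_cal,
    yhat_cal,
    y_pred,
    yhat_pred,
    chain_label: str = "",
    n_latent: int = 0,
    state: str = "",
) -> EvalReport:
    """Assemble the metric panel from calibration and prediction residuals."""
    y_cal = np.asarray(y_cal, dtype=float).ravel()
    y_pred = np.asarray(y_pred, dtype=float).ravel()
    rmsec_v = rmse(y_cal, yhat_cal)
    rmsep_v = rmse(y_pred, yhat_pred)
    slope, bias = prediction_fit(y_pred, yhat_pred)
    return EvalReport(
        chain_label=chain_label,
        n_latent=n_latent,
        r2_cal=r_squared(y_cal, yhat_cal),
        rmsec=rmsec_v,
        r2_pred=r_squared(y_pred, yhat_pred),
        rmsep=rmsep_v,
        rpd=rpd(y_pred, rmsep_v),
        rer=rer(y_pred, rmsep_v),
        n_cal=y_cal.size,
        n_pred=y_pred.size,
        sd_pred_measured=float(y_pred.std(ddof=1)),
        range_pred_measured=float(y_pred.max() - y_pred.min()),
        slope=slope,
        bias=bias,
        state=state,
    )
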