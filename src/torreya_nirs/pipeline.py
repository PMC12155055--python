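"""End-to-end calibration pipeline: data -> screen -> split -> chain grid.

Stages run in the order of the underlying workflow: (1) load or simulate a
spectra table, (2) two-stage outlier screening, (3) SPXY 3:1 split of the
survivors, (4) for each preprocessing chain in the grid, fit a PLSR with
one-SE latent-variable selection on the calibration set and evaluate on the
prediction set.  Every run is deterministic under its seed and writes a
manifest from which the tables can be regenerated.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import plsr
from .evaluation import EvalReport, evaluate_sets
from .outliers import (
    OutlierReport,
    RESIDUAL_THRESHOLD_PCT,
    STATE_PCA_PREPROCESSING,
    screen,
)
from .preprocess import apply_chain, parse_chain
from .spectra import SampleTable, SpectraMatrix, read_wide_csv
from .splitting import SplitResult, spxy_split
from .synthetic import SyntheticConfig, SyntheticDataset, load_config, simulate

__all__ = ["RunConfig", "PipelineResult", "run_pipeline", "grid_report",
           "model_label", "DEFAULT_CHAIN_GRID"]

logger = logging.getLogger("torreya_nirs")

# the 11 chains of the published modeling grid
DEFAULT_CHAIN_GRID = (
    "Original",
    "1Der",
    "2Der",
    "SG",
    "Normalize",
    "Baseline",
    "SNV",
    "MSC",
    "1Der+SNV",
    "2Der+SNV",
    "SG+SNV",
)

STATE_CODES = {"shell": "S", "deshelled": "WS", "granules": "G"}


@dataclass
class RunConfig:
    """Resolved configuration of one pipeline run (echoed to the manifest)."""

    seed: int
    synthetic: SyntheticConfig | None = None
    input_csv: str | None = None
    state: str = "granules"
    pca_k: int = 4
    pca_preprocessing: str | None = None   # None -> per-state default
    residual_threshold: float = RESIDUAL_THRESHOLD_PCT
    split_ratio: float = 0.75
    chains: tuple[str, ...] = DEFAULT_CHAIN_GRID
    cv_folds: int = 10
    a_max: int = 12
    n_latent_fixed: int | None = None      # override the one-SE rule
    output_dir: str | None = None

    def resolved_pca_preprocessing(self) -> str:
        return self.pca_preprocessing or STATE_PCA_PREPROCESSING.get(
            self.state, "SNV"
        )

    def to_dict(self) -> dict:
        d = {
            "seed": self.seed,
            "input_csv": self.input_csv,
            "state": self.state,
            "pca_k": self.pca_k,
            "pca_preprocessing": self.resolved_pca_preprocessing(),
            "residual_threshold": self.residual_threshold,
            "split_ratio": self.split_ratio,
            "chains": list(self.chains),
            "cv_folds": self.cv_folds,
            "a_max": self.a_max,
            "n_latent_fixed": self.n_latent_fixed,
        }
        if self.synthetic is not None:
            d["synthetic"] = self.synthetic.to_dict()
        return d


@dataclass
class PipelineResult:
    config: RunConfig
    dataset: SyntheticDataset
    outlier_report: OutlierReport
    retained: np.ndarray
    split: SplitResult
    reports: list[EvalReport]

    def metrics_frame(self) -> pd.DataFrame:
        return grid_report(self.reports)

    def best(self) -> EvalReport:
        return max(self.reports, key=lambda r: r.r2_pred)


def model_label(chain_label: str, state: str) -> str:
    """Published naming scheme: chain "1Der+SNV" + granules -> 1Der-SNV-PLSR-G."""
    code = STATE_CODES.get(state)
    if code is None:
        raise ValueError(f"unknown state {state!r}")
    chain = chain_label.replace("+", "-") if chain_label else "Original"
    return f"{chain}-PLSR-{code}"


def grid_report(reports: list[EvalReport]) -> pd.DataFrame:
    """Metric table sorted by prediction-set R², best chain first."""
    if not reports:
        raise ValueError("no chain results to report")
    rows = []
    for rep in reports:
        row = rep.to_row()
        row["model"] = model_label(rep.chain_label, rep.state)
        rows.append(row)
    frame = pd.DataFrame(rows)
    return frame.sort_values(
        "Rp2", ascending=False, kind="stable"
    ).reset_index(drop=True)


def _load_dataset(config: RunConfig) -> SyntheticDataset:
    if config.input_csv is not None:
        spectra, samples = read_wide_csv(config.input_csv, state=config.state)
        synth = config.synthetic or SyntheticConfig(
            n_samples=samples.n_samples, state=config.state, seed=config.seed
        )
        return SyntheticDataset(spectra, samples, synth)
    synth = config.synthetic or SyntheticConfig(state=config.state, seed=config.seed)
    return simulate(synth)


def fit_chain(
    chain_label: str,
    spectra: SpectraMatrix,
    samples: SampleTable,
    split: SplitResult,
    cv_folds: int = 10,
    a_max: int = 12,
    n_latent_fixed: int | None = None,
    seed: int = 0,
) -> tuple[EvalReport, plsr.PLSRModel]:
    """Preprocess with one chain, fit PLSR on the calibration set, evaluate.

    MSC references are fitted on the calibration set and replayed on the
    prediction set so no prediction-set information enters the model.
    """
    chain = parse_chain(chain_label)
    cal_raw = spectra.take(split.calibration_indices)
    pred_raw = spectra.take(split.prediction_indices)
    cal = apply_chain(chain, cal_raw)
    pred = apply_chain(chain, pred_raw, msc_references=cal.msc_references_used or None)

    y_cal = samples.protein_pct[split.calibration_indices]
    y_pred = samples.protein_pct[split.prediction_indices]

    if n_latent_fixed is not None:
        a = n_latent_fixed
    else:
        cv = plsr.cross_validate(
            cal.absorbance, y_cal, a_max=a_max, folds=cv_folds, seed=seed
        )
        a = cv.chosen_a
    model = plsr.fit_plsr(
        cal.absorbance,
        y_cal,
        n_components=a,
        wavelengths_nm=cal.wavelengths_nm,
        chain_label=chain.label,
    )
    report = evaluate_sets(
        y_cal,
        plsr.predict(model, cal.absorbance),
        y_pred,
        plsr.predict(model, pred.absorbance),
        chain_label=chain.label,
        n_latent=model.n_latent,
        state=samples.state,
    )
    return report, model


def split_summary(samples: SampleTable, split: SplitResult) -> pd.DataFrame:
    """Per-set n, range, mean and SD of the measured protein values."""
    rows = []
    for name, idx in (
        ("calibration", split.calibration_indices),
        ("prediction", split.prediction_indices),
    ):
        y = samples.protein_pct[idx]
        rows.append(
            {
                "set": name,
                "n": idx.size,
                "min_pct": round(float(y.min()), 2),
                "max_pct": round(float(y.max()), 2),
                "mean_pct": round(float(y.mean()), 2),
                "sd_pct": round(float(y.std(ddof=1)), 2),
            }
        )
    return pd.DataFrame(rows)


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Execute all stages; write reports when ``config.output_dir`` is set."""
    dataset = _load_dataset(config)
    n = dataset.samples.n_samples
    logger.info("loaded %d samples (state=%s)", n, dataset.samples.state)

    try:
        outlier_report = screen(
            dataset,
            pca_preprocessing=config.resolved_pca_preprocessing(),
            k=config.pca_k,
            residual_threshold=config.residual_threshold,
            cv_folds=config.cv_folds,
            cv_a_max=config.a_max,
            seed=config.seed,
        )
    except Exception as err:
        raise RuntimeError(f"outlier screening failed: {err}") from err
    retained = outlier_report.retained(n)
    logger.info(
        "screening removed %d samples (%d spectral, %d chemical); %d retained",
        outlier_report.removed.size,
        outlier_report.md_flagged.size,
        outlier_report.residual_flagged.size,
        retained.size,
    )

    kept_spectra = dataset.spectra.take(retained)
    kept_samples = dataset.samples.take(retained)

    try:
        split_spectra = apply_chain(
            config.resolved_pca_preprocessing(), kept_spectra
        )
        split = spxy_split(
            split_spectra, kept_samples.protein_pct, ratio=config.split_ratio
        )
    except Exception as err:
        raise RuntimeError(f"SPXY split failed: {err}") from err
    logger.info(
        "SPXY split: %d calibration / %d prediction",
        split.calibration_indices.size,
        split.prediction_indices.size,
    )

    reports = []
    for chain_label in config.chains:
        try:
            report, _ = fit_chain(
                chain_label,
                kept_spectra,
                kept_samples,
                split,
                cv_folds=config.cv_folds,
                a_max=config.a_max,
                n_latent_fixed=config.n_latent_fixed,
                seed=config.seed,
            )
        except Exception as err:
            raise RuntimeError(f"chain {chain_label!r} failed: {err}") from err
        reports.append(report)
        logger.info(
            "chain %-10s A=%d Rc2=%.3f Rp2=%.3f",
            chain_label,
            report.n_latent,
            report.r2_cal,
            report.r2_pred,
        )

    result = PipelineResult(config, dataset, outlier_report, retained, split, reports)
    if config.output_dir is not None:
        _write_outputs(result)
    return result


def _write_outputs(result: PipelineResult) -> None:
    out = Path(result.config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    result.outlier_report.to_frame().to_csv(out / "outliers.csv", index=False)
    (out / "outliers.json").write_text(result.outlier_report.to_json())
    kept = result.dataset.samples.take(result.retained)
    result.split.to_frame(kept.sample_ids).to_csv(out / "split.csv", index=False)
    split_summary(kept, result.split).to_csv(out / "split_summary.csv", index=False)
    result.metrics_frame().to_csv(
        out / "metrics.csv", index=False, float_format="%.2f"
    )
    manifest = {
        "config": result.config.to_dict(),
        "n_samples": int(result.dataset.samples.n_samples),
        "n_removed": int(result.outlier_report.removed.size),
        "n_calibration": int(result.split.calibration_indices.size),
        "n_prediction": int(result.split.prediction_indices.size),
        "best_model": model_label(
            result.best().chain_label, result.best().state
        ),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))


def run_config_from_file(path, seed: int | None = None,
                         output_dir: str | None = None) -> RunConfig:
    """Build a RunConfig from a YAML/JSON file; CLI seed overrides the file."""
    import yaml

    raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
    synth = None
    if "synthetic" in raw:
        s = dict(raw.pop("synthetic"))
        s.setdefault("seed", raw.get("seed", seed))
        from .synthetic import InterferentBand

        if "interferent_bands" in s:
            s["interferent_bands"] = tuple(
                InterferentBand(**b) if isinstance(b, dict) else InterferentBand(*b)
                for b in s["interferent_bands"]
            )
        synth = SyntheticConfig(**s)
    if seed is not None:
        raw["seed"] = seed
    if "seed" not in raw:
        raise ValueError("run config must set a seed")
    if "chains" in raw:
        raw["chains"] = tuple(raw["chains"])
    if output_dir is not None:
        raw["output_dir"] = output_dir
    return RunConfig(synthetic=synth, **raw)
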