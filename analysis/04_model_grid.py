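#!/usr/bin/env python
"""Preprocessing-chain grid of PLSR models for each sample state.

Runs the full pipeline (screen, SPXY split, 11-chain grid with one-SE
latent-variable selection) for the three states and writes one ranked metric
table per state plus a cross-state comparison of the best models.
"""

import argparse
from pathlib import Path

import pandas as pd

from torreya_nirs import RunConfig, SyntheticConfig, run_pipeline
from torreya_nirs.pipeline import model_label

STATES = ("shell", "deshelled", "granules")


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--out", type=Path, default=Path("results/models"))
    args = parser.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    best_rows = []
    for state in STATES:
        config = RunConfig(
            seed=args.seed,
            state=state,
            synthetic=SyntheticConfig(state=state, seed=args.seed),
            output_dir=str(args.out / state),
        )
        result = run_pipeline(config)
        best = result.best()
        best_rows.append(
            {
                "state": state,
                "model": model_label(best.chain_label, state),
                "n_latent": best.n_latent,
                "Rc2": round(best.r2_cal, 2),
                "RMSEC": round(best.rmsec, 2),
                "Rp2": round(best.r2_pred, 2),
                "RMSEP": round(best.rmsep, 2),
                "RPD": round(best.rpd, 2),
                "RER": round(best.rer, 2),
                "slope": round(best.slope, 2),
                "bias": round(best.bias, 2),
            }
        )
        print(f"\n=== {state} ===")
        print(result.metrics_frame().to_string(index=False))
    table = pd.DataFrame(best_rows)
    table.to_csv(args.out / "best_models.csv", index=False)
    print("\n=== best model per state ===")
    print(table.to_string(index=False))
    print(
        "\nGranule spectra give the strongest calibration (least signal "
        "masking); scatter-correcting chains dominate the rankings."
    )


if __name__ == "__main__":
    main()
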