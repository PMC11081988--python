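#!/usr/bin/env python
"""Compare batch-only, IS, and PQN normalization on the simulated cohort.

Writes the side-by-side overall paired median changes per mode and reports
the PQN attenuation ratio: with a majority of the panel drifting in time,
the quotient normalization absorbs part of the temporal effect into its
"dilution" factor and shrinks the recovered change.
"""

from pathlib import Path

import pandas as pd

from pmmetab.interpret import compare_normalization_modes
from pmmetab.pipeline import cohort_from_tables

COHORT = Path("results/cohort")
OUT = Path("results/normalization")


def main() -> None:
    cohort = cohort_from_tables(
        pd.read_csv(COHORT / "areas.csv"), pd.read_csv(COHORT / "samples.csv")
    )
    result = compare_normalization_modes(cohort)

    OUT.mkdir(parents=True, exist_ok=True)
    result["comparison"].rename_axis("analyte").to_csv(
        OUT / "mode_comparison.csv"
    )
    comparison = result["comparison"]
    print("overall paired median %change by normalization mode "
          "(first 10 analytes):")
    print(comparison.head(10).round(1).to_string())
    print(f"\nPQN attenuation ratio over drifting analytes: "
          f"{result['pqn_attenuation_ratio']:.2f} "
          "(<1: PQN shrinks the recovered temporal change)")


if __name__ == "__main__":
    main()
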