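"""Allometric scaling of peak feeding performance against body size.

Aggregates the per-bout kinematics to per-individual peak performance,
fits log10-log10 regressions on snout-vent length for all 25 variables,
compares each slope's 95% CI with the geometric-similarity (Hill)
prediction, and writes the classified scaling table.
"""

import pathlib

import pandas as pd

from axokin.scaling_analysis import scaling_table_frame

ROOT = pathlib.Path(__file__).resolve().parents[1] / "results"
OUT = ROOT / "scaling_table.csv"


def main() -> None:
    records = pd.read_csv(ROOT / "kinematics.csv")
    table = scaling_table_frame(records)
    table.to_csv(OUT, index=False, float_format="%.6g")
    print(f"scaling table ({len(table)} variables) -> {OUT}")
    print(table[["variable", "slope", "ci_low", "ci_high",
                 "hill_prediction", "allometry"]].to_string(index=False))
    counts = table.groupby("allometry")["variable"].count()
    print("\nclass counts:", dict(counts))


if __name__ == "__main__":
    main()
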