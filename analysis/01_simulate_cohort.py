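"""Simulate the study-shaped cohort and export it as pose-tracker CSVs.

Generates 25 axolotls (16 larvae, 4 juveniles, 5 adults) with 1-8 feeding
bouts each at 1000 frames/s, under the default scaling laws and noise
model, and writes the cohort in the exact CSV dialect the extraction stage
consumes, plus the ground-truth tables used by the later scripts.
"""

import pathlib

from axokin.synthetic_data import SimConfig, export_cohort, simulate_cohort

SEED = 20250901
OUT = pathlib.Path(__file__).resolve().parents[1] / "results" / "cohort"


def main() -> None:
    config = SimConfig()
    bouts, individuals = simulate_cohort(config, SEED)
    export_cohort(bouts, OUT, config=config, seed=SEED)
    by_stage = {}
    for ind in individuals:
        by_stage.setdefault(ind.stage, []).append(ind.svl)
    print(f"cohort: {len(individuals)} individuals, {len(bouts)} bouts -> {OUT}")
    for stage, svls in by_stage.items():
        print(f"  {stage:9s} n={len(svls):2d}  mean SVL {sum(svls)/len(svls):.2f} cm")


if __name__ == "__main__":
    main()
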