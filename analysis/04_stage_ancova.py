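"""Stage/size mixed-model ANCOVA cascade on the extracted kinematics.

Runs the full inference workflow: size ANOVA across stages, interaction
screening of all 25 variables, main-effect ANCOVAs for the no-interaction
set, pairwise-stage ANCOVAs for the interaction set, and Tukey post-hoc
stage contrasts; writes every table under results/ancova/.
"""

import pathlib

import pandas as pd

from axokin.stage_stats import (
    main_effects_ancova,
    pairwise_stage_ancova,
    posthoc_stage,
    screen_interactions,
    size_anova,
)

ROOT = pathlib.Path(__file__).resolve().parents[1] / "results"
OUT = ROOT / "ancova"


def main() -> None:
    records = pd.read_csv(ROOT / "kinematics.csv")
    OUT.mkdir(parents=True, exist_ok=True)

    meta = records.groupby("individual_id").first().reset_index()
    row, contrasts = size_anova(meta)
    print(f"size ANOVA: F={row.f:.2f}, p={row.p:.2g}")
    for c in contrasts:
        print(f"  {c.pair}: t={c.t:.2f}, adjusted p={c.adjusted_p:.3g}")
    pd.DataFrame(
        [{"term": "stage", "F": row.f, "p": row.p}]
        + [{"term": c.pair, "estimate": c.estimate, "t": c.t,
            "p": c.adjusted_p} for c in contrasts]
    ).to_csv(OUT / "size_anova.csv", index=False)

    part = screen_interactions(records)
    print(f"\ninteraction screen: {sorted(part.interaction)} show a "
          f"size-by-stage interaction; {len(part.no_interaction)} variables "
          "do not")
    pd.DataFrame([
        {"variable": v, "F": t.f, "p": t.p,
         "interaction": v in part.interaction}
        for v, t in part.tests.items()
    ]).to_csv(OUT / "interaction_screen.csv", index=False)

    rows = []
    for v in part.no_interaction:
        for r in main_effects_ancova(records, v):
            rows.append({"variable": v, "term": r.term, "F": r.f, "p": r.p})
    main_df = pd.DataFrame(rows)
    main_df.to_csv(OUT / "main_effects.csv", index=False)
    sig_size = main_df.query("term == 'size' and p < 0.05")["variable"]
    print(f"size significant (no-interaction set): {sorted(sig_size)}")

    rows = []
    for v in part.interaction:
        for pair in ("L-A", "J-A", "L-J", "I-A"):
            try:
                tests = pairwise_stage_ancova(records, v, pair)
            except ValueError:
                continue
            for r in tests:
                rows.append({"variable": v, "pair": pair, "term": r.term,
                             "F": r.f, "p": r.p})
    pd.DataFrame(rows).to_csv(OUT / "pairwise_stage.csv", index=False)

    rows = []
    for v in part.no_interaction:
        for c in posthoc_stage(records, v):
            rows.append({"variable": v, "pair": c.pair, "estimate": c.estimate,
                         "t": c.t, "p_adj": c.adjusted_p})
    pd.DataFrame(rows).to_csv(OUT / "posthoc_tukey.csv", index=False)
    print(f"\nall ANCOVA tables -> {OUT}")


if __name__ == "__main__":
    main()
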