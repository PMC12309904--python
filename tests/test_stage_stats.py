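import numpy as np
import pandas as pd
import pytest

from axokin.synthetic_data import (
    INTERACTION_VARIABLES,
    SimConfig,
    sample_records,
    sample_null_records,
)
from axokin.stage_stats import (
    main_effects_ancova,
    pairwise_stage_ancova,
    posthoc_stage,
    screen_interactions,
    size_anova,
)


def _meta(svls_by_stage, seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    for stage, (mean, sd, n) in svls_by_stage.items():
        for i in range(n):
            rows.append({"individual_id": f"{stage}{i}", "stage": stage,
                         "svl": mean + sd * rng.standard_normal()})
    return pd.DataFrame(rows)


class TestSizeAnova:
    def test_zero_between_group_variance(self):
        meta = _meta({"larva": (3.0, 0.2, 8), "adult": (3.0, 0.2, 8)}, seed=1)
        meta["svl"] = np.tile(meta["svl"][:8].to_numpy(), 2)  # identical groups
        row, _ = size_anova(meta)
        assert row.f == pytest.approx(0.0, abs=1e-12)

    def test_study_sized_effect_structure(self):
        """Adults 3x larvae with overlap between larvae and juveniles:
        adult contrasts significant, larva-juvenile not."""
        meta = _meta({"larva": (2.8, 0.5, 16), "juvenile": (3.3, 0.5, 4),
                      "adult": (8.4, 0.8, 5)}, seed=3)
        row, contrasts = size_anova(meta)
        assert row.p < 0.001
        by_pair = {c.pair: c for c in contrasts}
        assert by_pair["L-A"].adjusted_p < 0.01
        assert by_pair["J-A"].adjusted_p < 0.01
        assert by_pair["L-J"].adjusted_p > 0.05

    def test_single_stage_raises(self):
        with pytest.raises(ValueError):
            size_anova(_meta({"larva": (3.0, 0.2, 10)}))

    def test_null_type_one_error_near_alpha(self):
        rng = np.random.default_rng(10)
        reps, hits = 400, 0
        for _ in range(reps):
            meta = pd.DataFrame({
                "individual_id": range(25),
                "stage": ["larva"] * 16 + ["juvenile"] * 4 + ["adult"] * 5,
                "svl": rng.lognormal(1.0, 0.3, 25),
            })
            hits += size_anova(meta)[0].p < 0.05
        assert 0.02 <= hits / reps <= 0.09

    def test_bonferroni_never_below_raw(self):
        meta = _meta({"larva": (2.8, 0.5, 8), "juvenile": (3.3, 0.5, 4),
                      "adult": (8.4, 0.8, 5)}, seed=4)
        for c in size_anova(meta)[1]:
            assert c.adjusted_p >= c.p_raw - 1e-15


class TestScreenInteractions:
    def test_partition_covers_all_variables(self, record_table):
        part = screen_interactions(record_table)
        assert sorted(part.no_interaction + part.interaction
                      + part.excluded) == sorted(
            v for v in record_table.columns
            if v not in ("bout_id", "individual_id", "stage", "svl"))

    def test_threshold_is_strict_inequality(self, record_table):
        """A p exactly at alpha is treated as not significant."""
        part = screen_interactions(record_table, variables=("MSGC",))
        p = part.tests["MSGC"].p
        at_alpha = screen_interactions(record_table, alpha=p,
                                       variables=("MSGC",))
        assert "MSGC" in at_alpha.no_interaction

    def test_positive_control_flags_interaction_variables(self):
        """Stage-specific slopes on the flagged speed/acceleration set are
        detected in most replicates; common-slope variables are not."""
        controls = ("MG", "Mhd1", "MSGO", "DG", "TMhd1")
        flagged = {v: 0 for v in INTERACTION_VARIABLES + controls}
        reps = 40
        for i in range(reps):
            records = sample_records(SimConfig(), seed=1000 + i)
            part = screen_interactions(
                records, variables=INTERACTION_VARIABLES + controls)
            for v in part.interaction:
                flagged[v] += 1
        for v in INTERACTION_VARIABLES:
            if v == "Thd2":   # slope 0 baseline: weakest imposed contrast
                continue
            assert flagged[v] > reps / 2, (v, flagged)
        for v in controls:
            assert flagged[v] < reps / 4, (v, flagged)


class TestMainEffectsAncova:
    def test_detects_strong_size_effect_without_stage_effect(self):
        hits_size, hits_stage, reps = 0, 0, 40
        for i in range(reps):
            records = sample_records(SimConfig(), seed=2000 + i)
            rows = {r.term: r for r in main_effects_ancova(records, "MG")}
            hits_size += rows["size"].p < 0.05
            hits_stage += rows["stage"].p < 0.05
        assert hits_size >= 0.9 * reps
        assert hits_stage <= 0.3 * reps

    def test_null_response_rarely_significant(self):
        rng = np.random.default_rng(77)
        hits, reps = 0, 60
        for _ in range(reps):
            d = sample_null_records(rng)
            d["resp"] = 10 ** d["y"]
            rows = main_effects_ancova(d, "resp")
            hits += any(r.p < 0.05 for r in rows)
        assert hits <= 0.3 * reps


class TestPairwiseStageAncova:
    def test_interaction_found_in_adult_contrasts_not_immature(self):
        la, lj, reps = 0, 0, 30
        for i in range(reps):
            records = sample_records(SimConfig(), seed=3000 + i)
            t_la = {r.term: r for r in
                    pairwise_stage_ancova(records, "MSGC", "L-A")}
            t_lj = {r.term: r for r in
                    pairwise_stage_ancova(records, "MSGC", "L-J")}
            la += t_la["size:stage"].p < 0.05
            lj += t_lj["size:stage"].p < 0.05
        assert la > reps / 2
        assert lj < reps / 4

    def test_immature_adult_pair_recodes(self, record_table):
        rows = pairwise_stage_ancova(record_table, "MSGC", "I-A")
        assert [r.term for r in rows] == ["size", "stage", "size:stage"]

    def test_missing_group_raises(self, record_table):
        larvae_only = record_table[record_table["stage"] == "larva"]
        with pytest.raises(ValueError, match="absent|at least 2"):
            pairwise_stage_ancova(larvae_only, "MSGC", "L-A")

    def test_unknown_pair_raises(self, record_table):
        with pytest.raises(ValueError, match="unknown pair"):
            pairwise_stage_ancova(record_table, "MSGC", "A-L")


class TestPosthocStage:
    def test_two_stages_tukey_equals_unadjusted(self, record_table):
        sub = record_table[record_table["stage"] != "juvenile"]
        for c in posthoc_stage(sub, "MG"):
            assert c.adjusted_p == pytest.approx(c.p_raw, rel=1e-9)

    def test_adjusted_at_least_raw(self, record_table):
        for c in posthoc_stage(record_table, "MSGC"):
            assert c.adjusted_p >= c.p_raw - 1e-12

    def test_identical_groups_large_p(self):
        rng = np.random.default_rng(9)
        mean_p = []
        for _ in range(20):
            d = sample_null_records(rng)
            d["resp"] = 10 ** d["y"]
            mean_p.extend(c.adjusted_p for c in posthoc_stage(d, "resp"))
        assert np.mean(mean_p) > 0.4

    def test_stage_only_model_supported(self, record_table):
        out = posthoc_stage(record_table, "MG", include_size=False)
        assert {c.pair for c in out} == {"L-J", "L-A", "J-A"}
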